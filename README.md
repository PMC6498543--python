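# wavegrn

Wave-based iterative inference of **executable gene regulatory networks
(GRNs)** from time-stamped single-cell transcriptomic data, with optional
bulk proteomic and mRNA-decay inputs.

`wavegrn` is aimed at systems biologists who have single-cell mRNA count
snapshots along a stimulus-response time course (e.g. a differentiation
induced at t = 0) and want *explicit, simulatable* network candidates —
signed regulator→target interactions with calibrated efficiencies — rather
than a correlation matrix.

## The model

Each gene *i* is a piecewise-deterministic Markov process: a two-state
(telegraph) promoter coupled to deterministic mRNA/protein kinetics,

```
E_i : 0 --kon--> 1,   1 --koff--> 0        (random promoter state)
M_i' = s0_i E_i − d0_i M_i                 (mRNA)
P_i' = s1_i M_i − d1_i P_i                 (protein)
```

Regulation acts on the switching rates through a product of Hill-type
factors over incoming edges (stimulus level Q, regulator proteins P_j,
thresholds H_j, efficiencies θ):

```
kon(P,Q) = (kon_min + kon_max·β·Φ) / (1 + β·Φ),     koff: same form with θ → −θ
Φ_i(P,Q) = (1+e^{θ_i0}Q)/(1+Q) · ∏_j (1+e^{θ_ij}(P_j/H_j)^γ)/(1+(P_j/H_j)^γ)
```

θ > 0 activates (raises kon, lowers koff), θ < 0 represses; β is solved at
initialization so each gene starts at its basal switching rates.

## The inference idea: waves

Causes precede consequences. A stimulus applied at t = 0 reaches genes
one by one — a *wave* front whose arrival at a gene is the inflection of
its promoter activity `kon/(kon+koff)` (reconstructed from mean mRNA with
a degradation-delay correction) or of its mean protein. Sorting genes by
promoter wave time turns network inference into an iterative process:

1. genes with a promoter wave **< 5 h** can only be stimulus-regulated
   (*early genes*) and seed the network;
2. each later wave adds one gene, proposing only regulators whose protein
   wave is compatible in time (target promoter wave minus regulator
   protein wave in **[−20, 30] h**, widened to [−30, 50] h for genes with
   auto-positive feedback);
3. each proposed edge's θ is calibrated by matching simulated to observed
   marginal mRNA distributions (Kantorovitch/1-Wasserstein distance);
   poorly fitting candidates are pruned and the survivor list is kept to a
   configurable beam width.

Running the calibration with the *true* edges supplied ("directed"
replicates) measures the fit distance a correct network shows from
stochasticity alone; its 95th percentile is the acceptance threshold for
candidates.

## Worked example

`examples/04_infer_cascade_network.py` builds a known 3-gene cascade
(stimulus → g1a → g2a → g3a), simulates 500 cells at nine time points,
estimates waves, and runs the inference end to end:

```
true network: {'stimulus->g1a': 2.64, 'g1a->g2a': 3.09, 'g2a->g3a': 2.93}

1 candidate network(s) returned:
  fit distance 0.289  quality 100.0%  {'stimulus->g1a': 2.62, 'g1a->g2a': 3.1, 'g2a->g3a': 5.0}

acceptance threshold (95th pct of 20 directed replicates): 0.339
```

The single returned candidate has the true topology (quality 100% = all
true signed edges recovered), its calibrated stimulus and first-level θ
are close to the truth, and its fit distance 0.289 is below the 0.339
threshold — i.e. it fits the data as well as the true network does under
resimulation noise. The other examples cover the simulator against the
telegraph closed form, the per-gene estimators, and wave analysis on a
6-gene cascade.

There is also a thin CLI mirroring the pipeline stages:

```bash
wavegrn benchmark --levels 3 --per-level 2 --seed 7 --out bench/
wavegrn waves --data bench/ --params bench/params.csv --out waves.csv
wavegrn infer --data bench/ --params bench/params.csv --waves waves.csv \
              --truth bench/truth_topology.json --out candidates/
```

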