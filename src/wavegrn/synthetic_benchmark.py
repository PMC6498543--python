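"""In-silico benchmark networks and datasets.

Builds the standard evaluation setting for the inference pipeline:
stimulus-rooted cascade networks (several levels, several genes per
level), optional auto-positive or negative feedback variants, and
simulated "experimental" datasets — time-stamped single-cell mRNA
matrices plus bulk protein means at the benchmark time points — together
with the ground-truth topology and true wave times for scoring.

Gene kinetic parameters are sampled from declared surrogate ranges
chosen to respect the bursty-regime ordering
``kon_min < kon_max < d0 <= koff_min <= koff_max < 1/dt`` and to give
realistic single-cell count distributions (zero-inflated, dynamic range
of tens to hundreds of molecules).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .model_core import GeneParams, NetworkTopology, PiecewiseRate, STIMULUS_ID
from .simulator import SimulationConfig, SnapshotDataset, simulate_population
from .wave_analysis import WaveTable, estimate_waves

__all__ = [
    "BenchmarkSpec",
    "sample_gene_params",
    "generate_cascade",
    "add_feedback",
    "generate_dataset",
    "true_wave_table",
]

#: Benchmark sampling time points (hours after stimulation).
DEFAULT_TIMEPOINTS = (0.0, 2.0, 4.0, 8.0, 24.0, 33.0, 48.0, 72.0, 100.0)


@dataclass
class BenchmarkSpec:
    """Shape and conditions of one benchmark instance."""

    levels: int = 4
    genes_per_level: int = 5
    variant: str = "cascade"  # 'cascade' | 'auto_positive' | 'negative_feedback'
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    n_cells: int = 500
    dt: float = 0.5
    seed: int = 0
    # surrogate parameter sampling ranges (per hour unless noted)
    d0_range: tuple[float, float] = (0.1, 0.5)
    d0_range_level1: tuple[float, float] = (0.25, 0.5)
    max_count_range: tuple[float, float] = (30.0, 300.0)
    s1_range: tuple[float, float] = (0.2, 1.0)
    d1_range: tuple[float, float] = (0.05, 0.12)
    theta_magnitude: tuple[float, float] = (2.5, 4.0)
    activation_prob: float = 0.75

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("need at least 2 network levels")
        if self.genes_per_level < 1:
            raise ValueError("need at least one gene per level")
        self.timepoints = tuple(float(t) for t in self.timepoints)


def _loguniform(rng, lo, hi):
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_gene_params(
    gene_id: str, spec: BenchmarkSpec, rng: np.random.Generator, *, level: int = 2
) -> GeneParams:
    """Draw one gene's kinetics from the surrogate ranges.

    Level-1 (stimulus-regulated) genes are drawn with fast mRNA turnover
    so their response is resolvable on the sampling grid — the premise
    that early genes are identifiable from their promoter wave times.
    The basal (pre-stimulus) switching rates sit at the geometric center
    of their admissible intervals so an incoming activation or
    inhibition has room to move them either way.  The interaction
    threshold H is placed a quarter of the way between the basal and the
    fully-activated steady-state protein level, which keeps regulation
    effective whichever direction the regulator moves.
    """
    d0_range = spec.d0_range_level1 if level == 1 else spec.d0_range
    d0 = _loguniform(rng, *d0_range)
    kon_min = 0.001
    kon_max = min(0.1, 0.5 * d0)
    koff_min = d0
    koff_max = min(5.0, 0.95 / spec.dt)
    kon_init = float(np.sqrt(kon_min * kon_max))
    koff_init = float(np.sqrt(koff_min * koff_max))
    s0 = rng.uniform(*spec.max_count_range) * d0
    s1 = _loguniform(rng, *spec.s1_range)
    d1 = _loguniform(rng, *spec.d1_range)
    gp = GeneParams(
        gene_id=gene_id,
        s0=s0,
        d0=PiecewiseRate.constant(d0),
        s1=PiecewiseRate.constant(s1),
        d1=PiecewiseRate.constant(d1),
        kon_min=kon_min,
        kon_max=kon_max,
        koff_min=koff_min,
        koff_max=koff_max,
        kon_init=kon_init,
        koff_init=koff_init,
        H=1.0,  # provisional; placed by _orient_gene once wiring is known
    )
    _orient_gene(gp, +1)
    return gp


def _steady_protein(gp: GeneParams, occ: float) -> float:
    d0 = gp.d0.max()
    return gp.s0 * occ / d0 * gp.s1.max() / gp.d1.max()


def _orient_gene(gp: GeneParams, direction: int) -> None:
    """Place basal state and threshold so the gene's response is observable.

    The benchmark mimics a panel of *responsive* genes (real panels are
    selected for differential expression): a gene whose activity will
    rise starts near its low state, one that will fall starts expressed,
    and its regulator threshold H sits a quarter of the way into the
    protein excursion it will actually traverse.
    """
    if direction >= 0:
        gp.kon_init = max(2.0 * gp.kon_min, 0.1 * gp.kon_max)
        gp.koff_init = float(np.sqrt(gp.koff_min * gp.koff_max))
        occ0 = gp.kon_init / (gp.kon_init + gp.koff_init)
        occ_hi = gp.kon_max / (gp.kon_max + gp.koff_min)
        p0, p1 = _steady_protein(gp, occ0), _steady_protein(gp, occ_hi)
        gp.H = p0 + 0.25 * (p1 - p0)
    else:
        gp.kon_init = 0.7 * gp.kon_max
        gp.koff_init = gp.koff_min * (gp.koff_max / gp.koff_min) ** 0.25
        occ0 = gp.kon_init / (gp.kon_init + gp.koff_init)
        occ_lo = gp.kon_min / (gp.kon_min + gp.koff_max)
        p0, p1 = _steady_protein(gp, occ0), _steady_protein(gp, occ_lo)
        gp.H = p1 + 0.25 * (p0 - p1)


def _sample_theta(rng, spec: BenchmarkSpec, *, force_sign: int | None = None) -> float:
    mag = rng.uniform(*spec.theta_magnitude)
    if force_sign is not None:
        return force_sign * mag
    return mag if rng.random() < spec.activation_prob else -mag

def generate_cascade(spec: BenchmarkSpec) -> NetworkTopology:
    """Stimulus-rooted cascade with ``levels × genes_per_level`` genes.

    The stimulus activates every level-1 gene; every deeper gene
    receives exactly one regulator drawn at random from the previous
    level, with a signed interaction of sampled magnitude.  The
    resulting graph is acyclic.  Gene ids are ``g<level><index>``.
    """
    rng = np.random.default_rng(spec.seed)
    genes: list[GeneParams] = []
    theta: dict[tuple[str, str], float] = {}
    by_level: list[list[str]] = []
    direction: dict[str, int] = {}
    gene_of: dict[str, GeneParams] = {}
    for lvl in range(1, spec.levels + 1):
        ids = [f"g{lvl}{chr(ord('a') + k)}" for k in range(spec.genes_per_level)]
        by_level.append(ids)
        for gid in ids:
            gp = sample_gene_params(gid, spec, rng, level=lvl)
            genes.append(gp)
            gene_of[gid] = gp
            if lvl == 1:
                th = _sample_theta(rng, spec)
                theta[(STIMULUS_ID, gid)] = th
                direction[gid] = int(np.sign(th))
            else:
                reg = by_level[lvl - 2][rng.integers(spec.genes_per_level)]
                th = _sample_theta(rng, spec)
                theta[(reg, gid)] = th
                direction[gid] = direction[reg] * int(np.sign(th))
            _orient_gene(gp, direction[gid])
    return NetworkTopology(genes=genes, theta=theta)


def add_feedback(
    topology: NetworkTopology,
    kind: str,
    target: str,
    *,
    source: str | None = None,
    theta_magnitude: float = 3.0,
    gamma_auto: float = 4.0,
    seed: int = 0,
) -> NetworkTopology:
    """Add an auto-positive self-edge or a negative feedback edge.

    ``auto_positive`` adds a self-edge with θ > 0 and a sharper Hill
    exponent ``gamma_auto`` on ``target``.  ``negative`` adds an edge
    ``source → target`` with θ < 0 where ``target`` must lie upstream of
    ``source`` (the feedback closes exactly one cycle); if ``source`` is
    omitted, a downstream descendant of ``target`` is chosen at random.
    """
    topo = topology.copy()
    if target not in topo.gene_ids:
        raise ValueError(f"unknown target {target!r}")
    if kind == "auto_positive":
        topo.theta[(target, target)] = abs(theta_magnitude)
        topo.auto_edges.add(target)
        topo.gene(target).gamma_auto = gamma_auto
        return topo
    if kind != "negative":
        raise ValueError("kind must be 'auto_positive' or 'negative'")
    g = nx.DiGraph()
    g.add_nodes_from(topo.gene_ids)
    g.add_edges_from(
        (reg, tgt) for (reg, tgt) in topo.theta if reg != topo.stimulus_id
    )
    descendants = nx.descendants(g, target)
    if source is None:
        if not descendants:
            raise ValueError(f"{target!r} has no downstream genes to feed back from")
        source = sorted(descendants)[np.random.default_rng(seed).integers(len(descendants))]
    elif source not in descendants:
        raise ValueError(f"feedback source {source!r} is not downstream of {target!r}")
    topo.theta[(source, target)] = -abs(theta_magnitude)
    return topo


def generate_dataset(
    topology: NetworkTopology, spec: BenchmarkSpec
) -> tuple[SnapshotDataset, WaveTable]:
    """Simulated benchmark data plus the ground-truth wave table.

    Simulates ``n_cells`` cells at the benchmark time points, recording
    per-cell mRNA, per-cell protein and per-cell promoter activity.
    True wave times are estimated directly from the simulated mean
    promoter-activity and mean protein traces — these are observable in
    silico, so scoring does not run through the mRNA-based estimators.
    """
    config = SimulationConfig(
        n_cells=spec.n_cells,
        timepoints=list(spec.timepoints),
        seed=spec.seed,
        dt=spec.dt,
        record_protein=True,
        record_promoter=True,
    )
    dataset = simulate_population(topology, config)
    return dataset, true_wave_table(dataset)


def true_wave_table(dataset: SnapshotDataset) -> WaveTable:
    """Wave table from the simulation's own promoter/protein mean traces."""
    table = WaveTable()
    times = np.asarray(dataset.timepoints, dtype=float)
    mean_prom = dataset.mean_promoter()
    for gene_id in mean_prom.index:
        trace = mean_prom.loc[gene_id].to_numpy()
        table.waves.extend(
            estimate_waves(times, trace, gene_id=gene_id, kind="promoter")
        )
    if dataset.mean_protein is not None:
        for gene_id in dataset.mean_protein.index:
            trace = dataset.mean_protein.loc[gene_id].to_numpy()
            table.waves.extend(
                estimate_waves(times, trace, gene_id=gene_id, kind="protein")
            )
    from .wave_analysis import classify_genes

    classify_genes(table)
    return table
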