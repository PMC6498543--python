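"""Stochastic simulation of cell populations under the hybrid GRN model.

Each cell is an independent realization of the piecewise-deterministic
process: promoter states flip at random with exact two-state transition
probabilities over each step, while mRNA and protein levels follow their
ODEs under a fixed-step explicit Euler scheme.  The stimulus is a step
function (0 before t=0, ``stimulus_amplitude`` after) and simulations
start at a negative burn-in time so the population reaches its
pre-stimulus steady state before stimulation.

Populations are simulated with one independent RNG stream per cell
(spawned from the master seed), so results are reproducible and
independent of any batching of cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import (
    CellState,
    NetworkTopology,
    initialize_basal_factors,
    interaction_phi,
    switching_rate,
)

__all__ = [
    "SimulationConfig",
    "SnapshotDataset",
    "promoter_transition_prob",
    "step_cell",
    "simulate_population",
]


@dataclass
class SimulationConfig:
    """Settings of a population simulation.

    ``dt`` is the Euler step in hours; every gene's ``koff_max`` must be
    below ``1/dt`` (anti-aliasing of the promoter dynamics).  The burn-in
    runs from ``burn_in_start`` (default −60 h) to t=0, when the stimulus
    steps from 0 to ``stimulus_amplitude``.
    """

    n_cells: int
    timepoints: Sequence[float]
    seed: int = 0
    dt: float = 0.5
    burn_in_start: float = -60.0
    stimulus_amplitude: float = 1000.0
    record_protein: bool = True
    record_promoter: bool = False

    def __post_init__(self):
        self.timepoints = [float(t) for t in self.timepoints]
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if not self.timepoints:
            raise ValueError("at least one time point is required")
        if not (self.burn_in_start < 0 <= min(self.timepoints)):
            raise ValueError("need burn_in_start < 0 <= min(timepoints)")

    def validate_against(self, topology: NetworkTopology) -> None:
        for g in topology.genes:
            g.validate_ordering(dt=self.dt)


@dataclass
class SnapshotDataset:
    """Time-stamped population data: one cells×genes matrix per time point.

    ``rna[t]`` (and optionally ``protein[t]``, ``promoter[t]``) are
    DataFrames with one row per cell and one column per gene;
    ``mean_rna``/``mean_protein`` are genes×timepoints tables.  The
    promoter matrices hold the per-cell activity ratio
    ``kon/(kon+koff)`` and exist only for simulated data.
    """

    timepoints: list[float]
    rna: dict[float, pd.DataFrame]
    protein: dict[float, pd.DataFrame] | None = None
    promoter: dict[float, pd.DataFrame] | None = None
    mean_rna: pd.DataFrame | None = None
    mean_protein: pd.DataFrame | None = None

    def __post_init__(self):
        genes = None
        for t in self.timepoints:
            if t not in self.rna:
                raise ValueError(f"missing RNA matrix for time point {t}")
            cols = list(self.rna[t].columns)
            if genes is None:
                genes = cols
            elif cols != genes:
                raise ValueError("gene columns differ across time points")
        if self.mean_rna is None and genes is not None:
            self.mean_rna = self._means(self.rna)
        if self.mean_protein is None and self.protein:
            self.mean_protein = self._means(self.protein)

    def _means(self, mats: dict[float, pd.DataFrame]) -> pd.DataFrame:
        cols = {t: mats[t].mean(axis=0) for t in self.timepoints}
        return pd.DataFrame(cols)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.rna[self.timepoints[0]].columns)

    @property
    def n_cells(self) -> int:
        return len(self.rna[self.timepoints[0]])

    def mean_promoter(self) -> pd.DataFrame:
        if not self.promoter:
            raise ValueError("promoter activity was not recorded")
        return self._means(self.promoter)


def promoter_transition_prob(E: int, kon: float, koff: float, dt: float):
    """Probability that the promoter is ON after a step of length ``dt``.

    This is the exact two-state solution
    ``p = E e^{−dt(kon+koff)} + kon/(kon+koff) (1 − e^{−dt(kon+koff)})``;
    the next state is Bernoulli(p).  Accepts scalars or arrays.
    """
    ktot = kon + koff
    decay = np.exp(-dt * ktot)
    return E * decay + (kon / ktot) * (1.0 - decay)


def step_cell(
    state: CellState,
    topology: NetworkTopology,
    Q: float,
    dt: float,
    rng: np.random.Generator,
) -> CellState:
    """Advance a single cell one step (scalar reference implementation).

    The promoter state for the coming interval is drawn from the exact
    two-state transition probability at rates computed from the cell's
    current protein vector; mRNA then protein are advanced one explicit
    Euler step.  Negative Euler excursions are clipped to zero.

    :func:`simulate_population` uses an equivalent vectorized kernel;
    this function is the readable single-cell form used for testing.
    """
    genes = topology.genes
    G = len(genes)
    P_map = dict(zip(topology.gene_ids, state.P))
    E_new = np.empty(G)
    kon = np.empty(G)
    koff = np.empty(G)
    for i, g in enumerate(genes):
        phi_on = interaction_phi(P_map, Q, g.gene_id, topology)
        phi_off = interaction_phi(P_map, Q, g.gene_id, topology, negate=True)
        kon[i] = switching_rate(phi_on, g, "on")
        koff[i] = switching_rate(phi_off, g, "off")
    p = promoter_transition_prob(state.E, kon, koff, dt)
    E_new = (rng.random(G) < p).astype(float)
    t = state.t
    s0 = np.array([g.s0 for g in genes])
    d0 = np.array([g.d0(t) for g in genes])
    s1 = np.array([g.s1(t) for g in genes])
    d1 = np.array([g.d1(t) for g in genes])
    M_new = np.clip(state.M + dt * (s0 * E_new - d0 * state.M), 0.0, None)
    P_new = np.clip(state.P + dt * (s1 * state.M - d1 * state.P), 0.0, None)
    return CellState(E=E_new, M=M_new, P=P_new, t=t + dt)


# ---------------------------------------------------------------------------
# Vectorized population simulation
# ---------------------------------------------------------------------------


def _compile_edges(topology: NetworkTopology):
    """Flatten the sparse edge map into index/θ/γ/H arrays for the kernel."""
    idx = {g: i for i, g in enumerate(topology.gene_ids)}
    stim_edges = []  # (target_idx, theta)
    gene_edges = []  # (target_idx, reg_idx, theta, gamma, H)
    for (reg, tgt), th in sorted(topology.theta.items()):
        ti = idx[tgt]
        if reg == topology.stimulus_id:
            stim_edges.append((ti, th))
        else:
            gt = topology.gene(tgt)
            gamma = (
                gt.gamma_auto
                if (reg == tgt and gt.gamma_auto is not None)
                else gt.gamma
            )
            gene_edges.append((ti, idx[reg], th, gamma, topology.gene(reg).H))
    return stim_edges, gene_edges


def _phi_matrices(P, Q, G, stim_edges, gene_edges):
    """Φ for kon and koff (θ negated) for all cells at once; shape (n, G)."""
    n = P.shape[0]
    phi_on = np.ones((n, G))
    phi_off = np.ones((n, G))
    for ti, th in stim_edges:
        phi_on[:, ti] *= (1.0 + math.exp(th) * Q) / (1.0 + Q)
        phi_off[:, ti] *= (1.0 + math.exp(-th) * Q) / (1.0 + Q)
    for ti, ri, th, gamma, H in gene_edges:
        x = (P[:, ri] / H) ** gamma
        phi_on[:, ti] *= (1.0 + math.exp(th) * x) / (1.0 + x)
        phi_off[:, ti] *= (1.0 + math.exp(-th) * x) / (1.0 + x)
    return phi_on, phi_off


def simulate_population(
    topology: NetworkTopology, config: SimulationConfig
) -> SnapshotDataset:
    """Simulate ``n_cells`` independent cells and collect snapshots.

    Basal factors β_on/β_off are solved at entry from each gene's
    ``kon_init``/``koff_init`` at the pre-stimulus state, cells are
    initialized at ``burn_in_start`` (promoter ~ Bernoulli of the initial
    occupancy, mRNA and protein at their implied expectations), evolved
    through burn-in and stimulation, and mRNA/protein/promoter-activity
    matrices are recorded at each requested time point.  Time points not
    on the dt grid are snapped to the nearest grid time with a warning.
    """
    config.validate_against(topology)
    topo = initialize_basal_factors(topology, Q0=0.0)
    genes = topo.genes
    G = len(genes)
    gids = topo.gene_ids
    dt = config.dt

    # snap requested timepoints onto the simulation grid
    grid_of = {}
    for t in config.timepoints:
        k = round((t - config.burn_in_start) / dt)
        t_snap = config.burn_in_start + k * dt
        if abs(t_snap - t) > 1e-9:
            warnings.warn(
                f"time point {t} h is not on the dt grid; snapped to {t_snap} h"
            )
        grid_of[t] = k
    n_steps = max(grid_of.values())

    stim_edges, gene_edges = _compile_edges(topo)
    kon_min = np.array([g.kon_min for g in genes])
    kon_max = np.array([g.kon_max for g in genes])
    koff_min = np.array([g.koff_min for g in genes])
    koff_max = np.array([g.koff_max for g in genes])
    beta_on = np.array([g.beta_on for g in genes])
    beta_off = np.array([g.beta_off for g in genes])
    s0 = np.array([g.s0 for g in genes])
    # time-varying rates evaluated on the step grid
    tgrid = config.burn_in_start + dt * np.arange(n_steps + 1)
    d0_t = np.stack([g.d0(tgrid) for g in genes], axis=1)  # (n_steps+1, G)
    s1_t = np.stack([g.s1(tgrid) for g in genes], axis=1)
    d1_t = np.stack([g.d1(tgrid) for g in genes], axis=1)

    n = config.n_cells
    empty = n == 0
    # one independent stream per cell; uniforms pre-drawn for all steps
    ss = np.random.SeedSequence(config.seed)
    if not empty:
        streams = [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(n)]
        U = np.stack([g.random((n_steps + 1, G)) for g in streams], axis=0)
    else:
        U = np.zeros((0, n_steps + 1, G))

    occ0 = np.array([g.kon_init / (g.kon_init + g.koff_init) for g in genes])
    m0 = s0 * occ0 / d0_t[0]
    p0 = m0 * s1_t[0] / d1_t[0]
    E = (U[:, 0, :] < occ0).astype(float)
    M = np.tile(m0, (n, 1))
    P = np.tile(p0, (n, 1))

    records: dict[int, dict[str, np.ndarray]] = {}
    step_for = {}
    for t, k in grid_of.items():
        step_for.setdefault(k, []).append(t)

    def record(k):
        # the t=0 snapshot is the sample drawn just before stimulation
        Q_rec = config.stimulus_amplitude if tgrid[k] > 0 else 0.0
        phi_on, phi_off = _phi_matrices(P, Q_rec, G, stim_edges, gene_edges)
        bon = beta_on * phi_on
        boff = beta_off * phi_off
        kon = (kon_min + kon_max * bon) / (1.0 + bon)
        koff = (koff_min + koff_max * boff) / (1.0 + boff)
        records[k] = {
            "rna": M.copy(),
            "protein": P.copy(),
            "promoter": kon / (kon + koff),
        }

    if 0 in step_for:
        record(0)
    for k in range(n_steps):
        t_now = tgrid[k]
        Q_now = config.stimulus_amplitude if t_now >= 0 else 0.0
        phi_on, phi_off = _phi_matrices(P, Q_now, G, stim_edges, gene_edges)
        bon = beta_on * phi_on
        boff = beta_off * phi_off
        kon = (kon_min + kon_max * bon) / (1.0 + bon)
        koff = (koff_min + koff_max * boff) / (1.0 + boff)
        p = promoter_transition_prob(E, kon, koff, dt)
        E = (U[:, k + 1, :] < p).astype(float)
        M_next = np.clip(M + dt * (s0 * E - d0_t[k] * M), 0.0, None)
        P_next = np.clip(P + dt * (s1_t[k] * M - d1_t[k] * P), 0.0, None)
        M, P = M_next, P_next
        if (k + 1) in step_for:
            record(k + 1)

    rna, prot, prom = {}, {}, {}
    for t, k in grid_of.items():
        rec = records[k]
        rna[t] = pd.DataFrame(rec["rna"], columns=gids)
        prot[t] = pd.DataFrame(rec["protein"], columns=gids)
        prom[t] = pd.DataFrame(rec["promoter"], columns=gids)
    return SnapshotDataset(
        timepoints=list(config.timepoints),
        rna=rna,
        protein=prot if config.record_protein else None,
        promoter=prom if config.record_promoter else None,
        mean_rna=None,
        mean_protein=_mean_table(prot, config.timepoints),
    )


def _mean_table(mats: dict[float, pd.DataFrame], timepoints) -> pd.DataFrame:
    return pd.DataFrame({t: mats[t].mean(axis=0) for t in timepoints})
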