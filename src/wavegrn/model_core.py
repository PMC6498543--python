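"""Core mechanistic model: types and deterministic interaction functions.

The model couples, for each gene *i*, a two-state random promoter
``E_i ∈ {0, 1}`` with deterministic mRNA/protein kinetics::

    E_i : 0 --kon--> 1,  1 --koff--> 0
    M_i' = s0_i E_i - d0_i M_i
    P_i' = s1_i M_i - d1_i P_i

Regulation enters through the promoter switching rates: ``kon`` (and,
with all interaction signs flipped, ``koff``) is a saturating function of
an interaction term Φ that aggregates the protein levels of regulators
and the external stimulus through Hill-type factors.  This module houses
the parameter containers and the deterministic pieces (Φ, the switching
rates, and the basal-influence solve); stochastic simulation lives in
:mod:`wavegrn.simulator`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "STIMULUS_ID",
    "PiecewiseRate",
    "GeneParams",
    "NetworkTopology",
    "CellState",
    "interaction_phi",
    "switching_rate",
    "solve_basal",
]

#: Reserved identifier of the stimulus node (node 0 of the network).
STIMULUS_ID = "stimulus"


class PiecewiseRate:
    """A nonnegative rate that varies piecewise-linearly in time.

    Values between knots are linearly interpolated; outside the knot
    range the rate is held constant at the nearest knot value.  A plain
    float is accepted anywhere a ``PiecewiseRate`` is expected and is
    treated as a constant rate.

    Parameters
    ----------
    times : array-like of float
        Knot times in hours, strictly increasing.
    values : array-like of float
        Rate value at each knot, strictly positive.
    """

    __slots__ = ("times", "values")

    def __init__(self, times: Sequence[float], values: Sequence[float]):
        t = np.atleast_1d(np.asarray(times, dtype=float))
        v = np.atleast_1d(np.asarray(values, dtype=float))
        if t.shape != v.shape:
            raise ValueError("times and values must have the same length")
        if t.size == 0:
            raise ValueError("at least one knot is required")
        if np.any(np.diff(t) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("rates must be strictly positive")
        self.times = t
        self.values = v

    @classmethod
    def constant(cls, value: float) -> "PiecewiseRate":
        return cls([0.0], [float(value)])

    @classmethod
    def coerce(cls, value) -> "PiecewiseRate":
        if isinstance(value, cls):
            return value
        return cls.constant(float(value))

    def __call__(self, t):
        return np.interp(t, self.times, self.values)

    def max(self) -> float:
        return float(self.values.max())

    def min(self) -> float:
        return float(self.values.min())

    def is_constant(self) -> bool:
        return bool(np.all(self.values == self.values[0]))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_constant():
            return f"PiecewiseRate({self.values[0]:g})"
        pairs = ", ".join(f"{t:g}h:{v:g}" for t, v in zip(self.times, self.values))
        return f"PiecewiseRate({pairs})"

    def to_dict(self) -> dict:
        if self.is_constant():
            return {"constant": float(self.values[0])}
        return {"times": self.times.tolist(), "values": self.values.tolist()}

    @classmethod
    def from_dict(cls, d) -> "PiecewiseRate":
        if isinstance(d, (int, float)):
            return cls.constant(d)
        if "constant" in d:
            return cls.constant(d["constant"])
        return cls(d["times"], d["values"])


@dataclass
class GeneParams:
    """Kinetic constants of a single gene.

    Rates are per hour; mRNA/protein levels are in molecule units.
    ``d0`` is the *total* mRNA removal rate (active decay plus division
    dilution) and, like ``s1`` and ``d1``, may vary piecewise-linearly
    in time.  The switching-rate bounds must respect the bursty-regime
    ordering ``kon_min < kon_max < max_t d0(t) <= koff_min <= koff_max``
    and ``koff_max`` must stay below ``1/dt`` of the simulation step to
    avoid aliasing the promoter dynamics.

    ``kon_init``/``koff_init`` are the pre-stimulus switching rates the
    basal factors ``beta_on``/``beta_off`` are solved to reproduce.
    ``gamma`` is the Hill exponent of ordinary interaction factors;
    ``gamma_auto``, when set, replaces it on the gene's self-edge.
    ``H`` is the half-effect threshold of *this gene's protein* when it
    acts as a regulator.
    """

    gene_id: str
    s0: float
    d0: PiecewiseRate
    s1: PiecewiseRate
    d1: PiecewiseRate
    kon_min: float
    kon_max: float
    koff_min: float
    koff_max: float
    kon_init: float
    koff_init: float
    H: float
    gamma: float = 2.0
    gamma_auto: float | None = None
    beta_on: float = 1.0
    beta_off: float = 1.0

    def __post_init__(self):
        self.d0 = PiecewiseRate.coerce(self.d0)
        self.s1 = PiecewiseRate.coerce(self.s1)
        self.d1 = PiecewiseRate.coerce(self.d1)
        if self.s0 <= 0:
            raise ValueError(f"{self.gene_id}: s0 must be positive")
        if self.gamma < 1:
            raise ValueError(f"{self.gene_id}: gamma must be >= 1")
        if self.H <= 0:
            raise ValueError(f"{self.gene_id}: H must be positive")
        for name in ("kon_min", "kon_max", "koff_min", "koff_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.gene_id}: {name} must be positive")
        if not (self.kon_min < self.kon_max):
            raise ValueError(f"{self.gene_id}: need kon_min < kon_max")
        if not (self.koff_min <= self.koff_max):
            raise ValueError(f"{self.gene_id}: need koff_min <= koff_max")

    def validate_ordering(self, dt: float | None = None) -> None:
        """Check the full bursty-regime rate ordering, optionally vs ``dt``."""
        d0max = self.d0.max()
        if not (self.kon_max < d0max):
            raise ValueError(f"{self.gene_id}: kon_max must be < max_t d0(t)")
        if self.koff_min < d0max * (1 - 1e-12):
            raise ValueError(f"{self.gene_id}: koff_min must be >= max_t d0(t)")
        if dt is not None and not (self.koff_max < 1.0 / dt):
            raise ValueError(f"{self.gene_id}: koff_max must be < 1/dt")

    def to_dict(self) -> dict:
        d = {
            "gene_id": self.gene_id,
            "s0": self.s0,
            "d0": self.d0.to_dict(),
            "s1": self.s1.to_dict(),
            "d1": self.d1.to_dict(),
            "kon_min": self.kon_min,
            "kon_max": self.kon_max,
            "koff_min": self.koff_min,
            "koff_max": self.koff_max,
            "kon_init": self.kon_init,
            "koff_init": self.koff_init,
            "H": self.H,
            "gamma": self.gamma,
            "beta_on": self.beta_on,
            "beta_off": self.beta_off,
        }
        if self.gamma_auto is not None:
            d["gamma_auto"] = self.gamma_auto
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneParams":
        d = dict(d)
        for key in ("d0", "s1", "d1"):
            d[key] = PiecewiseRate.from_dict(d[key])
        return cls(**d)


@dataclass
class NetworkTopology:
    """An executable GRN: genes, a stimulus node and signed interactions.

    ``theta`` maps ordered pairs ``(regulator_id, target_id)`` to the
    interaction efficiency θ; the regulator may be :data:`STIMULUS_ID`.
    Positive θ means activation (raises ``kon``, lowers ``koff``),
    negative θ the reverse.  Self-edges in ``auto_edges`` model an
    effective auto-positive feedback and use the gene's ``gamma_auto``
    Hill exponent.
    """

    genes: list[GeneParams]
    theta: dict[tuple[str, str], float] = field(default_factory=dict)
    auto_edges: set[str] = field(default_factory=set)
    stimulus_id: str = STIMULUS_ID

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids")
        if self.stimulus_id in ids:
            raise ValueError("stimulus id collides with a gene id")
        self.theta = {tuple(k): float(v) for k, v in self.theta.items()}
        for (reg, tgt), th in self.theta.items():
            if tgt not in ids:
                raise ValueError(f"edge target {tgt!r} is not a gene")
            if reg != self.stimulus_id and reg not in ids:
                raise ValueError(f"edge regulator {reg!r} is not a gene")
            if not math.isfinite(th) or th == 0.0:
                raise ValueError(f"theta for ({reg}, {tgt}) must be finite and nonzero")
        for g in self.auto_edges:
            if (g, g) not in self.theta:
                raise ValueError(f"auto edge {g!r} has no (self, self) theta entry")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def gene(self, gene_id: str) -> GeneParams:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def regulators_of(self, target: str) -> list[str]:
        return [reg for (reg, tgt) in self.theta if tgt == target]

    def copy(self) -> "NetworkTopology":
        return NetworkTopology(
            genes=[replace(g) for g in self.genes],
            theta=dict(self.theta),
            auto_edges=set(self.auto_edges),
            stimulus_id=self.stimulus_id,
        )

    def subnetwork(self, gene_ids: Iterable[str]) -> "NetworkTopology":
        """Restriction to ``gene_ids``; edges from outside genes are dropped."""
        keep = list(gene_ids)
        kset = set(keep)
        genes = [replace(self.gene(g)) for g in keep]
        theta = {
            (reg, tgt): th
            for (reg, tgt), th in self.theta.items()
            if tgt in kset and (reg == self.stimulus_id or reg in kset)
        }
        return NetworkTopology(
            genes=genes,
            theta=theta,
            auto_edges={g for g in self.auto_edges if g in kset},
            stimulus_id=self.stimulus_id,
        )

    # -- JSON serialization -------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "stimulus_id": self.stimulus_id,
            "genes": [g.to_dict() for g in self.genes],
            "edges": [
                {"from": reg, "to": tgt, "theta": th}
                for (reg, tgt), th in sorted(self.theta.items())
            ],
            "auto_edges": sorted(self.auto_edges),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "NetworkTopology":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            genes=[GeneParams.from_dict(g) for g in doc["genes"]],
            theta={(e["from"], e["to"]): e["theta"] for e in doc["edges"]},
            auto_edges=set(doc.get("auto_edges", [])),
            stimulus_id=doc.get("stimulus_id", STIMULUS_ID),
        )


@dataclass
class CellState:
    """State of one cell: promoter states, mRNA and protein levels."""

    E: np.ndarray  # per-gene promoter state in {0, 1}
    M: np.ndarray  # per-gene mRNA level (molecules)
    P: np.ndarray  # per-gene protein level (molecules)
    t: float  # hours

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if np.any(self.M < 0) or np.any(self.P < 0):
            raise ValueError("mRNA and protein levels must be nonnegative")


# ---------------------------------------------------------------------------
# Deterministic model functions
# ---------------------------------------------------------------------------


def interaction_phi(
    P: Mapping[str, float] | Sequence[float],
    Q: float,
    target: str,
    topology: NetworkTopology,
    *,
    negate: bool = False,
) -> float:
    """Interaction term Φ of the target gene's switching rates.

    Φ multiplies one saturating factor per incoming edge::

        Φ_i(P, Q) = (1 + e^{θ_{i,0}} Q) / (1 + Q)
                    · ∏_j (1 + e^{θ_{i,j}} (P_j/H_j)^γ) / (1 + (P_j/H_j)^γ)

    where the product runs over regulators with an edge to the target
    (absent edges contribute a factor 1) and the self-edge factor uses
    the target's ``gamma_auto`` exponent when set.  With ``negate=True``
    every θ is replaced by −θ, which is the Φ entering ``koff``.

    Parameters
    ----------
    P : mapping gene_id -> protein level, or sequence ordered as topology.genes
    Q : stimulus level (>= 0)
    target : id of the regulated gene
    negate : evaluate with all θ signs flipped (the ``koff`` form)
    """
    if Q < 0:
        raise ValueError("stimulus level must be nonnegative")
    if not isinstance(P, Mapping):
        P = dict(zip(topology.gene_ids, P))
    sign = -1.0 if negate else 1.0
    tgt_params = topology.gene(target)
    phi = 1.0
    for (reg, tgt), th in topology.theta.items():
        if tgt != target:
            continue
        th = sign * th
        if reg == topology.stimulus_id:
            phi *= (1.0 + math.exp(th) * Q) / (1.0 + Q)
        else:
            pj = P[reg]
            if pj < 0:
                raise ValueError("protein levels must be nonnegative")
            if reg == target and tgt_params.gamma_auto is not None:
                gamma = tgt_params.gamma_auto
            else:
                gamma = tgt_params.gamma
            x = (pj / topology.gene(reg).H) ** gamma
            phi *= (1.0 + math.exp(th) * x) / (1.0 + x)
    return phi


def switching_rate(phi: float, params: GeneParams, which: str) -> float:
    """Promoter switching rate from an interaction term Φ.

    ``kon = (kon_min + kon_max · β_on Φ) / (1 + β_on Φ)``; the ``off``
    form is identical on the koff bounds with ``β_off`` and a Φ that was
    computed with negated θ values.  The result always lies strictly
    inside the open interval ``(k_min, k_max)``.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if which == "on":
        kmin, kmax, beta = params.kon_min, params.kon_max, params.beta_on
    elif which == "off":
        kmin, kmax, beta = params.koff_min, params.koff_max, params.beta_off
    else:
        raise ValueError("which must be 'on' or 'off'")
    bphi = beta * phi
    return (kmin + kmax * bphi) / (1.0 + bphi)


def solve_basal(
    initial_kon: float,
    initial_koff: float,
    phi0_on: float,
    phi0_off: float,
    params: GeneParams,
) -> tuple[float, float]:
    """Solve the basal factors β_on, β_off from the initial switching rates.

    Inverts the saturating rate form at the pre-stimulus state:
    ``β Φ0 = (k_target − k_min) / (k_max − k_target)``, independently for
    the on and off rates, so that :func:`switching_rate` evaluated at the
    initial protein/stimulus state returns exactly the requested value.

    Raises
    ------
    ValueError
        If a target rate lies outside the open interval of its bounds.
    """
    out = []
    for k, kmin, kmax, phi0, label in (
        (initial_kon, params.kon_min, params.kon_max, phi0_on, "kon"),
        (initial_koff, params.koff_min, params.koff_max, phi0_off, "koff"),
    ):
        if not (kmin < k < kmax):
            raise ValueError(
                f"{params.gene_id}: initial {label}={k:g} outside open bounds "
                f"({kmin:g}, {kmax:g})"
            )
        if phi0 <= 0:
            raise ValueError("phi0 must be positive")
        out.append((k - kmin) / ((kmax - k) * phi0))
    return out[0], out[1]


def initialize_basal_factors(
    topology: NetworkTopology, Q0: float = 0.0
) -> NetworkTopology:
    """Solve every gene's β_on/β_off at the pre-stimulus steady state.

    The pre-stimulus protein level of each gene is taken at the
    expectation implied by its initial switching rates,
    ``P0 = (s0/d0)(s1/d1) · kon_init/(kon_init+koff_init)`` with rates
    evaluated at the burn-in start, then β factors are solved in place
    so the network starts exactly at its declared basal rates.
    """
    topo = topology.copy()
    P0 = {}
    for g in topo.genes:
        occ = g.kon_init / (g.kon_init + g.koff_init)
        t0 = min(g.d0.times.min(), g.s1.times.min(), g.d1.times.min(), 0.0)
        m0 = g.s0 * occ / g.d0(t0)
        P0[g.gene_id] = m0 * g.s1(t0) / g.d1(t0)
    for g in topo.genes:
        phi_on = interaction_phi(P0, Q0, g.gene_id, topo)
        phi_off = interaction_phi(P0, Q0, g.gene_id, topo, negate=True)
        g.beta_on, g.beta_off = solve_basal(
            g.kon_init, g.koff_init, phi_on, phi_off, g
        )
    return topo
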