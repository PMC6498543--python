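"""Fit-distance and quality metrics for candidate networks.

Calibration compares simulated and observed marginal mRNA distributions
per gene and time point with the Kantorovitch (1-Wasserstein) distance,
then aggregates pessimistically: a gene's fit distance is the mean of
its 3 worst per-time-point distances, and a network's fit distance the
mean of the 3 worst gene distances (in-silico mode) or of all gene
distances (in-vitro mode).  When the true network is known, a
candidate's *quality* is the percentage of true edges it conserves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import wasserstein_distance

from .model_core import NetworkTopology

__all__ = [
    "FitReport",
    "kantorovitch",
    "gene_fit_distance",
    "grn_fit_distance",
    "quality",
    "acceptance_threshold",
]


@dataclass
class FitReport:
    """Distances of one candidate against the reference data."""

    per_gene_per_time: dict[str, dict[float, float]]
    gene_distance: dict[str, float]
    grn_distance: float
    mode: str = "in_silico"

    def to_json(self, path=None) -> str:
        doc = {
            "mode": self.mode,
            "grn_distance": self.grn_distance,
            "gene_distance": self.gene_distance,
            "per_gene_per_time": {
                g: {str(t): d for t, d in by_t.items()}
                for g, by_t in self.per_gene_per_time.items()
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def build(cls, per_gene_per_time, mode: str = "in_silico") -> "FitReport":
        gene_dist = {
            g: gene_fit_distance(list(by_t.values()))
            for g, by_t in per_gene_per_time.items()
        }
        return cls(
            per_gene_per_time=per_gene_per_time,
            gene_distance=gene_dist,
            grn_distance=grn_fit_distance(list(gene_dist.values()), mode),
            mode=mode,
        )


def kantorovitch(sample_a, sample_b) -> float:
    """Kantorovitch (1-Wasserstein) distance between two empirical samples.

    Equals the integral of the absolute difference between the two
    empirical CDFs; zero iff the empirical distributions coincide.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    return float(wasserstein_distance(a, b))


def gene_fit_distance(distances_over_time) -> float:
    """Mean of the 3 largest per-time-point distances (all, if fewer)."""
    d = np.sort(np.asarray(distances_over_time, dtype=float))
    if d.size == 0:
        raise ValueError("no distances")
    return float(d[-3:].mean())


def grn_fit_distance(gene_distances, mode: str = "in_silico") -> float:
    """Aggregate gene distances into a network fit distance.

    ``in_silico``: mean of the 3 worst gene distances (pessimistic, the
    benchmark convention); ``in_vitro``: mean over all genes.
    """
    d = np.sort(np.asarray(gene_distances, dtype=float))
    if d.size == 0:
        raise ValueError("no gene distances")
    if mode == "in_silico":
        return float(d[-3:].mean())
    if mode == "in_vitro":
        return float(d.mean())
    raise ValueError("mode must be 'in_silico' or 'in_vitro'")


def quality(
    candidate: NetworkTopology,
    truth: NetworkTopology,
    *,
    require_sign: bool = True,
) -> float:
    """Percentage of true interactions conserved in the candidate.

    An edge counts as conserved when the candidate carries the same
    (regulator, target) pair — and, by default, an interaction of the
    same sign.  Extra candidate edges are not penalized; this is a
    recall-style score against the truth, not a precision measure.
    """
    if not set(truth.gene_ids) & set(candidate.gene_ids):
        raise ValueError("candidate and truth share no genes")
    if not truth.theta:
        raise ValueError("truth network has no edges")
    hits = 0
    for (reg, tgt), th in truth.theta.items():
        th_c = candidate.theta.get((reg, tgt))
        if th_c is None:
            continue
        if not require_sign or np.sign(th_c) == np.sign(th):
            hits += 1
    return 100.0 * hits / len(truth.theta)


def acceptance_threshold(
    directed_distances, coverage: float = 0.95, *, min_replicates: int = 20
) -> float:
    """Empirical coverage percentile of directed-inference fit distances.

    Directed runs calibrate the *true* topology against fresh data, so
    their fit-distance spread measures the irreducible stochastic
    variability; the 95th percentile is the maximum fit distance a
    correct network should plausibly show, usable as a pruning
    threshold.  Linear interpolation between order statistics.
    """
    d = np.asarray(directed_distances, dtype=float)
    if d.size < min_replicates:
        raise ValueError(f"need at least {min_replicates} replicate distances")
    return float(np.percentile(d, 100.0 * coverage))
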