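"""Shared fixtures: small networks and simulated datasets.

Everything is generated programmatically at collection time; session
scope is used for the expensive simulated datasets so independent tests
reuse one realization.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

from wavegrn import (
    GeneParams,
    NetworkTopology,
    PiecewiseRate,
    SimulationConfig,
    simulate_population,
)
from wavegrn.synthetic_benchmark import BenchmarkSpec, generate_cascade, generate_dataset

TIMEPOINTS = [0.0, 2.0, 4.0, 8.0, 24.0, 33.0, 48.0, 72.0, 100.0]


def make_gene(
    gene_id="g1",
    s0=50.0,
    d0=0.25,
    s1=0.5,
    d1=0.08,
    kon_min=0.001,
    kon_max=0.12,
    koff_min=0.25,
    koff_max=1.8,
    kon_init=0.02,
    koff_init=0.7,
    H=100.0,
    **kw,
) -> GeneParams:
    return GeneParams(
        gene_id=gene_id,
        s0=s0,
        d0=PiecewiseRate.coerce(d0),
        s1=PiecewiseRate.coerce(s1),
        d1=PiecewiseRate.coerce(d1),
        kon_min=kon_min,
        kon_max=kon_max,
        koff_min=koff_min,
        koff_max=koff_max,
        kon_init=kon_init,
        koff_init=koff_init,
        H=H,
        **kw,
    )


@pytest.fixture
def gene() -> GeneParams:
    return make_gene()


@pytest.fixture
def single_gene_topology(gene) -> NetworkTopology:
    return NetworkTopology(genes=[gene], theta={})


@pytest.fixture(scope="session")
def telegraph_population():
    """5000 cells of one constant-rate unregulated gene, at stationarity."""
    topo = NetworkTopology(genes=[make_gene()], theta={})
    cfg = SimulationConfig(
        n_cells=5000, timepoints=[0.0, 24.0], seed=11, record_promoter=True
    )
    return topo, cfg, simulate_population(topo, cfg)


@pytest.fixture(scope="session")
def cascade3():
    """3-gene cascade benchmark bundle: (spec, truth, dataset, wave table)."""
    spec = BenchmarkSpec(levels=3, genes_per_level=1, n_cells=500, seed=3)
    topo = generate_cascade(spec)
    dataset, truth_waves = generate_dataset(topo, spec)
    return spec, topo, dataset, truth_waves


@pytest.fixture(scope="session")
def cascade6():
    """6-gene / 3-level cascade bundle (the benchmark toy shape)."""
    spec = BenchmarkSpec(levels=3, genes_per_level=2, n_cells=500, seed=7)
    topo = generate_cascade(spec)
    dataset, truth_waves = generate_dataset(topo, spec)
    return spec, topo, dataset, truth_waves
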