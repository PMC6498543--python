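"""Iterative inference: proposals, calibration, beam search, directed mode."""

import numpy as np
import pytest

from wavegrn import (
    CandidateGRN,
    InferenceConfig,
    NetworkTopology,
    SimulationConfig,
    Wave,
    WaveTable,
    init_early_network,
    iterate_inference,
    propose_regulators,
    quality,
    simulate_population,
    topology_space_size,
)
from wavegrn.inference_engine import calibrate_candidate
from wavegrn.model_core import STIMULUS_ID
from wavegrn.synthetic_benchmark import BenchmarkSpec, generate_cascade
from wavegrn.wave_analysis import build_wave_table

from .conftest import TIMEPOINTS, make_gene


def stim_gene_setup(theta_sign, seed=17):
    """One stimulus-regulated gene plus its simulated reference data."""
    from wavegrn.synthetic_benchmark import _orient_gene

    g = make_gene("gA", d0=0.3, koff_min=0.3, koff_max=1.8)
    _orient_gene(g, theta_sign)
    topo = NetworkTopology(genes=[g], theta={(STIMULUS_ID, "gA"): theta_sign * 3.0})
    data = simulate_population(
        topo, SimulationConfig(n_cells=500, timepoints=TIMEPOINTS, seed=seed)
    )
    params = {"gA": g}
    waves = build_wave_table(data.mean_rna, data.mean_protein, params)
    return topo, data, params, waves


def test_topology_space_size_grows_triple_exponentially():
    assert topology_space_size(1) == 3**2
    assert topology_space_size(2) == 3**6


class TestProposeRegulators:
    def _setup(self):
        genes = [make_gene(g) for g in ("a", "b")]
        topo = NetworkTopology(genes=genes, theta={(STIMULUS_ID, "a"): 1.0})
        cand = CandidateGRN(topology=topo)
        waves = WaveTable(
            waves=[
                Wave("a", "promoter", 3.0, "up", (0.0, 100.0)),
                Wave("a", "protein", 15.0, "up", (0.0, 100.0)),
                Wave("b", "promoter", 40.0, "up", (0.0, 100.0)),
            ]
        )
        return cand, waves

    def test_window_rule(self):
        cand, waves = self._setup()
        cfg = InferenceConfig()
        w = Wave("b", "promoter", 40.0, "up", (0.0, 100.0))
        # 40 - 15 = 25 in [-20, 30] -> proposed; stimulus excluded (wave >= 7h)
        assert propose_regulators(w, cand, waves, cfg) == ["a"]

    def test_difference_outside_normal_window_needs_auto_flag(self):
        cand, waves = self._setup()
        cfg = InferenceConfig()
        # regulator protein wave at 35h, target promoter wave at 10h:
        # difference -25 is outside [-20, 30] but inside [-30, 50]
        waves.waves[1] = Wave("a", "protein", 35.0, "up", (0.0, 100.0))
        w = Wave("b", "promoter", 10.0, "up", (0.0, 100.0))
        assert propose_regulators(w, cand, waves, cfg) == []
        assert propose_regulators(w, cand, waves, cfg, auto_flagged=True) == ["a"]

    def test_stimulus_proposed_below_maybe_early_threshold(self):
        cand, waves = self._setup()
        cfg = InferenceConfig()
        w = Wave("b", "promoter", 6.5, "up", (0.0, 100.0))
        assert STIMULUS_ID in propose_regulators(w, cand, waves, cfg)

    def test_directed_mode_returns_only_true_regulator(self):
        cand, waves = self._setup()
        cfg = InferenceConfig()
        truth = NetworkTopology(
            genes=[make_gene(g) for g in ("a", "b")],
            theta={(STIMULUS_ID, "a"): 1.0, ("a", "b"): 2.0},
        )
        w = Wave("b", "promoter", 6.5, "up", (0.0, 100.0))
        assert propose_regulators(w, cand, waves, cfg, truth=truth) == ["a"]


class TestEarlyInitialization:
    def test_activated_gene_gets_positive_theta(self):
        topo, data, params, waves = stim_gene_setup(+1)
        assert waves.first_promoter_time("gA") < 5.0
        sim_cfg = SimulationConfig(n_cells=150, timepoints=TIMEPOINTS, seed=0)
        cands = init_early_network(waves, data, params, sim_cfg, InferenceConfig(seed=1))
        assert len(cands) == 1
        assert cands[0].topology.theta[(STIMULUS_ID, "gA")] > 0

    def test_inhibited_gene_gets_negative_theta(self):
        topo, data, params, waves = stim_gene_setup(-1)
        sim_cfg = SimulationConfig(n_cells=150, timepoints=TIMEPOINTS, seed=0)
        cands = init_early_network(waves, data, params, sim_cfg, InferenceConfig(seed=1))
        assert cands[0].topology.theta[(STIMULUS_ID, "gA")] < 0

    def test_late_gene_not_initialized(self):
        topo, data, params, waves = stim_gene_setup(+1)
        late = WaveTable(
            waves=[Wave("gA", "promoter", 10.0, "up", (0.0, 100.0))]
        )
        sim_cfg = SimulationConfig(n_cells=100, timepoints=TIMEPOINTS, seed=0)
        with pytest.raises(ValueError, match="no early genes"):
            init_early_network(late, data, params, sim_cfg, InferenceConfig(seed=1))


class TestCalibration:
    def test_zero_theta_fits_worse_than_calibrated(self, cascade3):
        spec, topo, data, truth_waves = cascade3
        from wavegrn.inference_engine import _fit_report

        sim_cfg = SimulationConfig(n_cells=150, timepoints=list(spec.timepoints), seed=0)
        cfg = InferenceConfig(seed=2)
        sub = topo.subnetwork(["g1a", "g2a"])
        true_edge = ("g1a", "g2a")
        cand = CandidateGRN(topology=sub.copy())
        cand = calibrate_candidate(cand, true_edge, data, sim_cfg, cfg)
        # forcing the interaction off degrades the fit
        off = sub.copy()
        off.theta[true_edge] = 1e-9 if topo.theta[true_edge] > 0 else -1e-9
        del off.theta[true_edge]
        off.theta[(STIMULUS_ID, "g1a")] = cand.topology.theta[(STIMULUS_ID, "g1a")]
        off_cand = CandidateGRN(topology=off)
        off_fit = _fit_report(off_cand, data, sim_cfg, cfg)
        assert cand.fit.grn_distance < off_fit.grn_distance
        # sign of the recovered interaction matches the truth
        assert np.sign(cand.topology.theta[true_edge]) == np.sign(topo.theta[true_edge])

    def test_calibration_deterministic_given_seed(self, cascade3):
        spec, topo, data, truth_waves = cascade3
        sim_cfg = SimulationConfig(n_cells=100, timepoints=list(spec.timepoints), seed=0)
        cfg = InferenceConfig(seed=3)
        out = []
        for _ in range(2):
            cand = CandidateGRN(topology=topo.subnetwork(["g1a"]).copy())
            cand.topology.theta[(STIMULUS_ID, "g1a")] = 1.0
            cand = calibrate_candidate(cand, (STIMULUS_ID, "g1a"), data, sim_cfg, cfg)
            out.append((cand.topology.theta[(STIMULUS_ID, "g1a")], cand.fit.grn_distance))
        assert out[0] == out[1]


class TestIterateInference:
    @pytest.fixture(scope="class")
    def inference_inputs(self, cascade3):
        spec, topo, data, truth_waves = cascade3
        params = {g.gene_id: g for g in topo.genes}
        waves = build_wave_table(data.mean_rna, data.mean_protein, params)
        sim_cfg = SimulationConfig(n_cells=150, timepoints=list(spec.timepoints), seed=0)
        return topo, data, params, waves, sim_cfg

    def test_directed_mode_returns_single_true_candidate(self, inference_inputs):
        topo, data, params, waves, sim_cfg = inference_inputs
        cfg = InferenceConfig(beam_width=8, seed=4)
        cands = iterate_inference(waves, data, params, sim_cfg, cfg, truth=topo)
        assert len(cands) == 1
        assert set(topo.theta) <= set(cands[0].topology.theta)

    def test_beam_width_one_is_greedy(self, inference_inputs):
        topo, data, params, waves, sim_cfg = inference_inputs
        cfg = InferenceConfig(beam_width=1, seed=4)
        cands = iterate_inference(waves, data, params, sim_cfg, cfg)
        assert len(cands) == 1

    def test_lower_prune_threshold_never_returns_more(self, inference_inputs):
        topo, data, params, waves, sim_cfg = inference_inputs
        counts = []
        for thr in (10.0, 0.0):
            cfg = InferenceConfig(beam_width=8, seed=4, prune_threshold=thr)
            try:
                cands = iterate_inference(waves, data, params, sim_cfg, cfg)
                counts.append(sum(c.status == "active" for c in cands))
            except ValueError:
                counts.append(0)
        assert counts[1] <= counts[0]

    def test_reproducible_given_seed(self, inference_inputs):
        topo, data, params, waves, sim_cfg = inference_inputs
        runs = []
        for _ in range(2):
            cfg = InferenceConfig(beam_width=4, seed=11)
            cands = iterate_inference(waves, data, params, sim_cfg, cfg)
            runs.append([(c.history, round(c.fit_distance, 12)) for c in cands])
        assert runs[0] == runs[1]
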