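"""Per-gene estimators: decay, transcription, switching ranges, translation."""

import numpy as np
import pytest

from wavegrn import (
    DecayKinetics,
    NetworkTopology,
    SimulationConfig,
    assign_translation_fallback,
    detect_auto_feedback,
    estimate_H,
    estimate_d0,
    estimate_s0,
    estimate_switch_ranges,
    fit_translation,
    simulate_population,
)
from wavegrn.param_estimation import (
    _range_limits,
    telegraph_moment_rates,
    translation_power_law,
)

from .conftest import TIMEPOINTS, make_gene


class TestEstimateD0:
    def test_exact_on_noiseless_log_linear_decay(self):
        t = np.arange(7.0)
        decay = DecayKinetics("g", t, np.exp(-0.2 * t), cell_cycle_h=20.0)
        assert estimate_d0(decay) == pytest.approx(0.2 + np.log(2) / 20, abs=1e-12)

    def test_constant_levels_rejected(self):
        with pytest.raises(ValueError):
            estimate_d0(DecayKinetics("g", np.arange(5.0), np.ones(5)))

    def test_dilution_additivity(self):
        t = np.arange(7.0)
        lv = np.exp(-0.2 * t)
        d20 = estimate_d0(DecayKinetics("g", t, lv, cell_cycle_h=20.0))
        d40 = estimate_d0(DecayKinetics("g", t, lv, cell_cycle_h=40.0))
        assert d20 - d40 == pytest.approx(np.log(2) / 40)

    def test_scale_invariance(self):
        t = np.arange(7.0)
        lv = np.exp(-0.3 * t)
        a = estimate_d0(DecayKinetics("g", t, lv))
        b = estimate_d0(DecayKinetics("g", t, 137.0 * lv))
        assert a == pytest.approx(b, abs=1e-12)


class TestEstimateS0:
    def test_definition_and_max_monotonicity(self, telegraph_population):
        topo, cfg, ds = telegraph_population
        mmax = max(float(ds.rna[t]["g1"].max()) for t in ds.timepoints)
        assert estimate_s0(ds, 0.25, "g1") == pytest.approx(mmax * 0.25)

    def test_upward_consistency_on_simulated_gene(self, telegraph_population):
        """At constant d0 the estimator approaches s0 from below at large n."""
        topo, cfg, ds = telegraph_population
        g = topo.genes[0]
        est = estimate_s0(ds, g.d0, "g1")
        assert 0.3 * g.s0 < est <= g.s0 * 1.05


class TestSwitchRanges:
    def test_limit_formulas(self):
        lo, hi = _range_limits(0.1, 0.001)
        assert lo == pytest.approx((0.1 - 0.0001) / 0.9)
        assert hi == pytest.approx((0.1 - 0.0009) / 0.1)
        lo, hi = _range_limits(1.0, 0.3)
        assert lo == pytest.approx((1.0 - 0.03) / 0.9)
        assert hi == pytest.approx((1.0 - 0.27) / 0.1)

    def test_moment_estimator_recovers_rates(self, telegraph_population):
        topo, cfg, ds = telegraph_population
        g = topo.genes[0]
        kon, koff = telegraph_moment_rates(
            ds.rna[24.0]["g1"].to_numpy(), g.s0, g.d0.max(), dt=cfg.dt
        )
        assert kon == pytest.approx(g.kon_init, rel=0.35)
        assert koff == pytest.approx(g.koff_init, rel=0.35)

    def test_ranges_bracket_truth_and_respect_ordering(self, telegraph_population):
        topo, cfg, ds = telegraph_population
        g = topo.genes[0]
        r = estimate_switch_ranges(ds, g.s0, g.d0, 0.5, "g1", seed=1)
        assert r.kon_min < r.kon_max < g.d0.max() <= r.koff_min <= r.koff_max <= 1 / 0.5
        assert r.kon_min < g.kon_init < r.kon_max
        assert r.koff_min <= g.koff_init < r.koff_max

    def test_degenerate_distribution_falls_back(self):
        import pandas as pd

        from wavegrn.simulator import SnapshotDataset

        rna = {0.0: pd.DataFrame({"g": np.full(40, 7.0)})}
        ds = SnapshotDataset(timepoints=[0.0], rna=rna)
        with pytest.warns(UserWarning, match="degenerate"):
            r = estimate_switch_ranges(ds, 10.0, 0.25, 0.5, "g")
        assert r.kon_max == pytest.approx(0.125)
        assert r.koff_max == pytest.approx(2.0)


class TestFitTranslation:
    def test_steady_state_inverts_to_s1(self):
        t = np.array(TIMEPOINTS)
        m = np.full(t.size, 10.0)
        p = np.full(t.size, 100.0)
        fit = fit_translation(t, m, p)
        assert fit.category == "constant"
        # steady state: s1*M = d1*P -> s1/d1 = 10
        assert fit.s1.max() / fit.d1.max() == pytest.approx(10.0, rel=0.05)

    def test_constant_parameter_recovery(self):
        t = np.array(TIMEPOINTS)
        m = 10.0 + 0.2 * t
        s1, d1 = 0.6, 0.08
        p = np.empty(t.size)
        p[0] = s1 * m[0] / d1
        grid = np.linspace(0, 100, 2001)
        mg = np.interp(grid, t, m)
        pv = p[0]
        dense = [pv]
        for i in range(1, grid.size):
            h = grid[i] - grid[i - 1]
            pv = pv + h * (s1 * mg[i - 1] - d1 * pv)
            dense.append(pv)
        p = np.interp(t, grid, dense)
        fit = fit_translation(t, m, p)
        assert fit.category == "constant"
        assert fit.s1.max() == pytest.approx(s1, rel=0.10)
        assert fit.d1.max() == pytest.approx(d1, rel=0.10)

    def test_decreasing_protein_with_flat_rna_needs_varying_d1(self):
        t = np.array(TIMEPOINTS)
        m = np.full(t.size, 10.0)
        # protein holds steady then declines although mRNA is constant:
        # constant rates cannot produce a delayed decay
        p = np.where(t < 24.0, 100.0, 100.0 * np.exp(-0.03 * (t - 24.0)))
        fit = fit_translation(t, m, p)
        assert fit.category == "variable_d1"
        assert fit.d1.values[-1] > fit.d1.values[0]


class TestTranslationFallback:
    def test_power_law_values(self):
        assert translation_power_law(100.0) == pytest.approx(
            10 ** (-1.47) * 100**0.81
        )
        assert translation_power_law(1.0) == pytest.approx(10 ** (-1.47))

    def test_cap_and_minimum_degradation(self):
        s1, d1 = assign_translation_fallback(50.0)
        assert s1 == 1.0  # power law at P=100 exceeds the 1 molecule/mRNA/h cap
        assert d1 == pytest.approx(0.5)


class TestAutoFeedbackDetection:
    def _dataset(self, draw, n=400, timepoints=(2.0, 8.0, 24.0, 48.0)):
        import pandas as pd

        from wavegrn.simulator import SnapshotDataset

        rng = np.random.default_rng(8)
        rna = {t: pd.DataFrame({"g": draw(rng, n)}) for t in timepoints}
        return SnapshotDataset(timepoints=list(timepoints), rna=rna)

    def test_unimodal_not_flagged(self):
        ds = self._dataset(lambda rng, n: rng.gamma(3.0, 10.0, n))
        flag, gamma = detect_auto_feedback(ds, "g")
        assert flag is False and gamma is None

    def test_separated_mixture_flagged(self):
        def draw(rng, n):
            lo = rng.gamma(4.0, 1.0, n)
            hi = rng.gamma(4.0, 10.0, n)
            pick = rng.random(n) < 0.5
            return np.where(pick, hi, lo) + 1.0

        ds = self._dataset(draw)
        flag, gamma = detect_auto_feedback(ds, "g")
        assert flag is True
        assert gamma >= 2.0

    def test_unimodal_false_positive_rate(self):
        """No unimodal null is flagged across parameter draws (< 5% FPR)."""
        import pandas as pd

        from wavegrn.simulator import SnapshotDataset

        flags = 0
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            shape = rng.uniform(2.0, 6.0)
            scale = rng.uniform(3.0, 20.0)
            rna = {
                t: pd.DataFrame({"g": rng.gamma(shape, scale, 400)})
                for t in (2.0, 8.0, 24.0, 48.0)
            }
            ds = SnapshotDataset(timepoints=[2.0, 8.0, 24.0, 48.0], rna=rna)
            flag, _ = detect_auto_feedback(ds, "g")
            flags += flag
        assert flags == 0

    def test_flags_simulated_auto_activated_gene(self):
        """End-to-end: a strongly auto-activated gene is flagged from its
        simulated transitory snapshots."""
        from wavegrn.synthetic_benchmark import (
            BenchmarkSpec,
            add_feedback,
            generate_cascade,
            generate_dataset,
        )

        spec = BenchmarkSpec(levels=2, genes_per_level=1, n_cells=500, seed=4)
        topo = add_feedback(
            generate_cascade(spec), "auto_positive", "g1a",
            theta_magnitude=3.5, gamma_auto=4.0,
        )
        ds, _ = generate_dataset(topo, spec)
        flag, gamma = detect_auto_feedback(ds, "g1a")
        assert flag is True
        assert gamma >= 2.0

    def test_too_few_nonzero_cells_warns(self):
        ds = self._dataset(lambda rng, n: np.full(n, 0.1), n=60)
        with pytest.warns(UserWarning, match="nonzero"):
            flag, _ = detect_auto_feedback(ds, "g")
        assert flag is False


class TestEstimateH:
    @pytest.mark.parametrize(
        "trace,expected",
        [([0.0, 200.0], 50.0), ([40.0, 140.0], 65.0), ([7.0, 7.0, 7.0], 7.0)],
    )
    def test_quarter_point(self, trace, expected):
        assert estimate_H(np.asarray(trace)) == pytest.approx(expected)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_H(np.array([]))
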