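"""Interaction function, switching rates and basal-influence solving."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wavegrn import (
    GeneParams,
    NetworkTopology,
    PiecewiseRate,
    interaction_phi,
    solve_basal,
    switching_rate,
)
from wavegrn.model_core import STIMULUS_ID, initialize_basal_factors

from .conftest import make_gene


def two_gene_topology(theta, **kw):
    g1 = make_gene("g1", **kw)
    g2 = make_gene("g2")
    return NetworkTopology(genes=[g1, g2], theta=theta)


class TestPiecewiseRate:
    def test_interpolates_and_clamps(self):
        r = PiecewiseRate([0.0, 24.0, 72.0], [0.2, 0.4, 0.3])
        assert r(12.0) == pytest.approx(0.3)
        assert r(-100.0) == pytest.approx(0.2)  # constant extrapolation
        assert r(1000.0) == pytest.approx(0.3)
        assert r.max() == 0.4

    def test_rejects_bad_knots(self):
        with pytest.raises(ValueError):
            PiecewiseRate([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            PiecewiseRate([0.0, 1.0], [1.0, -1.0])


class TestInteractionPhi:
    def test_no_edges_gives_one(self):
        topo = two_gene_topology({})
        assert interaction_phi({"g1": 50.0, "g2": 3.0}, 1000.0, "g1", topo) == 1.0

    def test_stimulus_saturates_at_exp_theta(self):
        theta = 1.7
        topo = two_gene_topology({(STIMULUS_ID, "g1"): theta})
        phi = interaction_phi({"g1": 0.0, "g2": 0.0}, 1e9, "g1", topo)
        assert phi == pytest.approx(math.exp(theta), rel=1e-6)

    def test_half_saturation_point(self):
        # regulator protein exactly at its threshold H
        theta = 2.0
        topo = two_gene_topology({("g2", "g1"): theta})
        H2 = topo.gene("g2").H
        phi = interaction_phi({"g1": 0.0, "g2": H2}, 0.0, "g1", topo)
        assert phi == pytest.approx((1.0 + math.exp(theta)) / 2.0)

    def test_negation_flips_effect(self):
        topo = two_gene_topology({("g2", "g1"): 2.0})
        P = {"g1": 0.0, "g2": 300.0}
        up = interaction_phi(P, 0.0, "g1", topo)
        down = interaction_phi(P, 0.0, "g1", topo, negate=True)
        assert up > 1.0 > down

    @pytest.mark.parametrize("theta", [2.0, -2.0])
    def test_monotone_in_regulator_protein(self, theta):
        topo = two_gene_topology({("g2", "g1"): theta})
        grid = np.linspace(0.0, 500.0, 40)
        phis = [
            interaction_phi({"g1": 0.0, "g2": p}, 0.0, "g1", topo) for p in grid
        ]
        diffs = np.diff(phis)
        assert np.all(diffs > 0) if theta > 0 else np.all(diffs < 0)

    def test_negative_protein_rejected(self):
        topo = two_gene_topology({("g2", "g1"): 2.0})
        with pytest.raises(ValueError):
            interaction_phi({"g1": 0.0, "g2": -1.0}, 0.0, "g1", topo)
        with pytest.raises(ValueError):
            interaction_phi({"g1": 0.0, "g2": 1.0}, -5.0, "g1", topo)

    def test_gamma_auto_applies_to_self_edge_only(self):
        g1 = make_gene("g1", gamma_auto=4.0)
        g2 = make_gene("g2")
        topo = NetworkTopology(
            genes=[g1, g2],
            theta={("g1", "g1"): 2.0, ("g2", "g1"): 2.0},
            auto_edges={"g1"},
        )
        # at P = H/2: sharper exponent -> smaller x -> phi closer to 1
        P = {"g1": g1.H / 2, "g2": g2.H / 2}
        phi = interaction_phi(P, 0.0, "g1", topo)
        x_self = (0.5) ** 4.0
        x_other = (0.5) ** 2.0
        expected = ((1 + math.e**2 * x_self) / (1 + x_self)) * (
            (1 + math.e**2 * x_other) / (1 + x_other)
        )
        assert phi == pytest.approx(expected)


class TestSwitchingRate:
    def test_limits_and_midpoint(self, gene):
        assert switching_rate(1e-12, gene, "on") == pytest.approx(gene.kon_min)
        assert switching_rate(1e12, gene, "on") == pytest.approx(gene.kon_max)
        # beta*phi = 1 -> midpoint of the bounds
        gene.beta_on = 1.0
        assert switching_rate(1.0, gene, "on") == pytest.approx(
            (gene.kon_min + gene.kon_max) / 2
        )

    @settings(max_examples=200, deadline=None)
    @given(phi=st.floats(1e-6, 1e6), which=st.sampled_from(["on", "off"]))
    def test_rate_strictly_inside_bounds(self, phi, which):
        g = make_gene()
        rate = switching_rate(phi, g, which)
        kmin = g.kon_min if which == "on" else g.koff_min
        kmax = g.kon_max if which == "on" else g.koff_max
        assert kmin < rate < kmax


class TestSolveBasal:
    def test_midpoint_gives_beta_one(self, gene):
        target = (gene.kon_min + gene.kon_max) / 2
        beta_on, _ = solve_basal(target, gene.koff_init, 1.0, 1.0, gene)
        assert beta_on == pytest.approx(1.0)

    def test_printed_example(self):
        g = make_gene(kon_min=0.001, kon_max=0.1, kon_init=0.05)
        beta_on, _ = solve_basal(0.05, g.koff_init, 1.0, 1.0, g)
        assert beta_on == pytest.approx(0.049 / 0.05)
        g.beta_on = beta_on
        assert switching_rate(1.0, g, "on") == pytest.approx(0.05)

    @settings(max_examples=100, deadline=None)
    @given(
        frac_on=st.floats(0.01, 0.99),
        frac_off=st.floats(0.01, 0.99),
        phi_on=st.floats(0.01, 100.0),
        phi_off=st.floats(0.01, 100.0),
    )
    def test_round_trip(self, frac_on, frac_off, phi_on, phi_off):
        g = make_gene()
        kon = g.kon_min + frac_on * (g.kon_max - g.kon_min)
        koff = g.koff_min + frac_off * (g.koff_max - g.koff_min)
        g.beta_on, g.beta_off = solve_basal(kon, koff, phi_on, phi_off, g)
        assert switching_rate(phi_on, g, "on") == pytest.approx(kon, rel=1e-10)
        assert switching_rate(phi_off, g, "off") == pytest.approx(koff, rel=1e-10)

    def test_infeasible_target_rejected(self, gene):
        with pytest.raises(ValueError):
            solve_basal(gene.kon_max * 2, gene.koff_init, 1.0, 1.0, gene)

    def test_network_initialization_reproduces_basal_rates(self):
        g1 = make_gene("g1")
        g2 = make_gene("g2")
        topo = NetworkTopology(
            genes=[g1, g2], theta={("g1", "g2"): 2.5, (STIMULUS_ID, "g1"): 1.0}
        )
        topo = initialize_basal_factors(topo, Q0=0.0)
        # at the initial protein state the rates equal the declared inits
        P0 = {}
        for g in topo.genes:
            occ = g.kon_init / (g.kon_init + g.koff_init)
            m0 = g.s0 * occ / g.d0(0.0)
            P0[g.gene_id] = m0 * g.s1(0.0) / g.d1(0.0)
        for g in topo.genes:
            phi = interaction_phi(P0, 0.0, g.gene_id, topo)
            assert switching_rate(phi, g, "on") == pytest.approx(g.kon_init, rel=1e-10)


class TestNetworkTopology:
    def test_json_round_trip(self, tmp_path):
        g1 = make_gene("g1", d0=PiecewiseRate([0.0, 24.0, 72.0], [0.2, 0.3, 0.25]))
        g2 = make_gene("g2", gamma_auto=4.0)
        topo = NetworkTopology(
            genes=[g1, g2],
            theta={(STIMULUS_ID, "g1"): 1.5, ("g1", "g2"): -2.0, ("g2", "g2"): 3.0},
            auto_edges={"g2"},
        )
        path = tmp_path / "net.json"
        topo.to_json(path)
        back = NetworkTopology.from_json(path)
        assert back.theta == topo.theta
        assert back.auto_edges == {"g2"}
        assert back.gene("g1").d0.values.tolist() == [0.2, 0.3, 0.25]
        assert back.gene("g2").gamma_auto == 4.0

    def test_rejects_zero_theta_and_unknown_nodes(self):
        with pytest.raises(ValueError):
            NetworkTopology(genes=[make_gene("g1")], theta={("g1", "g1"): 0.0})
        with pytest.raises(ValueError):
            NetworkTopology(genes=[make_gene("g1")], theta={("gX", "g1"): 1.0})

    def test_subnetwork_drops_outside_edges(self):
        genes = [make_gene(g) for g in ("a", "b", "c")]
        topo = NetworkTopology(
            genes=genes,
            theta={(STIMULUS_ID, "a"): 1.0, ("a", "b"): 1.0, ("b", "c"): 1.0},
        )
        sub = topo.subnetwork(["a", "c"])
        assert sub.gene_ids == ["a", "c"]
        assert set(sub.theta) == {(STIMULUS_ID, "a")}
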