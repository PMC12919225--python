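import math

import numpy as np
import pytest

from caliberflow.audits import (
    bound_hierarchy_check,
    delta_nabla_coefficients,
    ensemble_bound_scatter,
    symmetry_residuals,
)
from caliberflow.fixtures import detailed_balance_network, random_ergodic_network
from caliberflow.network import build_frame
from caliberflow.response import response_matrix


class TestSymmetryIdentities:
    def test_edge_reciprocity_constant_two_state(self, net2a):
        # (1/pi1) d<tau12>/dk12 + (1/pi2) d<tau12>/dk21 = 3*(2/9) + (3/2)*(8/9) = 2
        frame = build_frame(net2a)
        res = symmetry_residuals(net2a, frame)
        t12 = frame.traffic_index("1", "2")
        assert abs(res.edge[t12, 0]) < 1e-12          # LHS - 2 = 0
        d2 = frame.dwell_index("2")
        assert abs(res.edge[d2, 0]) < 1e-12           # LHS - 0 for x = pi2

    def test_node_escaping_constant_two_state(self, net2a):
        frame = build_frame(net2a)
        res = symmetry_residuals(net2a, frame)
        d2 = frame.dwell_index("2")
        assert abs(res.node[d2, 0]) < 1e-12           # own dwell: LHS = 1
        t12 = frame.traffic_index("1", "2")
        assert abs(res.node[t12, 0]) < 1e-12          # traffic: LHS = 0

    def test_cycle_symmetry_constant_ring(self, net3c):
        frame = build_frame(net3c)
        res = symmetry_residuals(net3c, frame)
        c0 = frame.cycle_index(0)
        assert abs(res.cycle[c0, 0]) < 1e-12          # own flux: LHS = 2
        for e in range(frame.n_edges):
            assert abs(res.cycle[e, 0]) < 1e-12       # traffic: LHS = 0

    @pytest.mark.parametrize("seed", range(10))
    def test_all_identities_on_random_networks(self, seed):
        rng = np.random.default_rng(1300 + seed)
        V = int(rng.integers(3, 9))
        E = int(rng.integers(V - 1, V * (V - 1) // 2 + 1))
        net = random_ergodic_network(V, E, seed=1400 + seed)
        frame = build_frame(net)
        assert symmetry_residuals(net, frame).max_abs <= 1e-8

    def test_dense_graph(self):
        net = random_ergodic_network(5, 10, seed=42)  # complete K5
        frame = build_frame(net)
        assert symmetry_residuals(net, frame).max_abs <= 1e-8

    def test_numeric_mode_agrees(self, net3c):
        frame = build_frame(net3c)
        res = symmetry_residuals(net3c, frame, numeric=True, fd_step=1e-6)
        assert res.max_abs <= 1e-4


class TestDeltaNabla:
    def test_two_state_closed_forms(self, net2a):
        frame = build_frame(net2a)
        table = delta_nabla_coefficients(net2a, frame)
        row = table[(table.source == "1") & (table.target == "2")].iloc[0]
        assert math.isclose(row.Delta, 1.0, abs_tol=1e-12)        # dJ/dk = 0 here
        assert math.isclose(row.Nabla, -1 / 3, abs_tol=1e-12)     # 3*(2/9) - 1
        assert math.isclose(row.dpij_dkij, 1 / 9, abs_tol=1e-12)
        assert math.isclose(row.dpji_dkij, 1 / 9, abs_tol=1e-12)
        assert row.middle_saturated

    @pytest.mark.parametrize("seed", range(6))
    def test_algebraic_constraints_on_random_networks(self, seed):
        net = random_ergodic_network(5, 8, seed=1500 + seed)
        frame = build_frame(net)
        table = delta_nabla_coefficients(net, frame)
        assert (table.Delta >= -1e-10).all() and (table.Delta <= 1 + 1e-10).all()
        assert (table.Nabla <= table.Delta + 1e-10).all()


class TestBoundHierarchy:
    def test_two_state_chain_with_saturated_middle(self, net2a):
        frame = build_frame(net2a)
        bs = bound_hierarchy_check(net2a, frame)
        e = frame.directed_index("1", "2")
        assert math.isclose(bs.pi_src[e], 1 / 3)
        assert bs.pi_src[e] >= bs.dpij_dkij[e] >= bs.dpji_dkij[e] >= 0
        assert bs.saturated_middle[e]  # J12 = 0

    def test_upper_bound_saturates_as_rate_vanishes(self):
        net = random_ergodic_network(4, 5, seed=21)
        frame = build_frame(net)
        i, j = frame.directed_edges[0]
        weak = net.with_rates({(i, j): net.rates[(i, j)] * 1e-6})
        bs = bound_hierarchy_check(weak, frame)
        e = frame.directed_index(i, j)
        assert abs(bs.dpij_dkij[e] - bs.pi_src[e]) < 1e-4

    @pytest.mark.parametrize("seed", range(5))
    def test_middle_equality_iff_zero_net_flux(self, seed):
        net = random_ergodic_network(4, 5, seed=1600 + seed)
        frame = build_frame(net)
        bs = bound_hierarchy_check(net, frame)
        for e in range(frame.n_basis):
            gap = bs.dpij_dkij[e] - bs.dpji_dkij[e]
            if abs(bs.J_edge[e]) < 1e-12:
                assert abs(gap) < 1e-10
            else:
                assert gap > 1e-12


class TestEnsembleBoundScatter:
    def test_500_random_networks_have_no_violations(self):
        table = ensemble_bound_scatter(V=4, count=500, seed=0)
        assert ((table.x <= 1 + 1e-10) & (table.x >= table.y - 1e-10)
                & (table.y >= -1e-10)).all()

    def test_two_state_point_sits_on_diagonal(self, net2a):
        # zero-flux edge: normalized point (1/3, 1/3) on x = y
        frame = build_frame(net2a)
        bs = bound_hierarchy_check(net2a, frame)
        e = frame.directed_index("1", "2")
        x = bs.dpij_dkij[e] / bs.pi_src[e]
        y = bs.dpji_dkij[e] / bs.pi_src[e]
        assert math.isclose(x, 1 / 3) and math.isclose(y, 1 / 3)

    def test_bridge_edge_sits_on_diagonal(self):
        # a pendant edge can never carry net flux, so its forward and
        # induced-reverse flux responses coincide for any rates
        from caliberflow.network import RateNetwork

        net = RateNetwork(
            ("1", "2", "3", "4"),
            {("1", "2"): 2.0, ("2", "1"): 1.0, ("2", "3"): 3.0, ("3", "2"): 1.0,
             ("3", "1"): 2.0, ("1", "3"): 0.5, ("3", "4"): 1.5, ("4", "3"): 0.7},
        )
        frame = build_frame(net)
        bs = bound_hierarchy_check(net, frame)
        e = frame.directed_index("3", "4")
        assert abs(bs.dpij_dkij[e] - bs.dpji_dkij[e]) < 1e-12
        assert bs.saturated_middle[e]

    def test_detailed_balance_cycle_edges_leave_the_diagonal(self):
        # instantaneously zero flux is not enough: perturbing a cycle edge of
        # an equilibrium network drives a current, so dJ/dk > 0 there
        net = detailed_balance_network(4, 5, seed=0)
        frame = build_frame(net)
        bs = bound_hierarchy_check(net, frame)
        assert np.abs(bs.J_edge).max() < 1e-12
        S = frame.cycle_signs()
        on_cycle = np.abs(S).sum(axis=0) > 0
        gaps = bs.dpij_dkij[on_cycle] - bs.dpji_dkij[on_cycle]
        assert gaps.min() > 1e-6

    def test_count_must_be_positive(self):
        with pytest.raises(ValueError):
            ensemble_bound_scatter(V=4, count=0, seed=0)


class TestNodeIdentityConsequences:
    def test_site_energy_proportionality_to_high_precision(self):
        from caliberflow.network import traffic_observable
        from caliberflow.response import energy_barrier_responses
        from caliberflow.steady import edge_flux_observable, steady_observables

        net = random_ergodic_network(5, 7, seed=31)
        frame = build_frame(net)
        ss = steady_observables(net, frame)
        tau = traffic_observable(frame, *frame.undirected[0])
        flux = edge_flux_observable(frame, *frame.chords[0])
        for obs, target in ((tau, ss.tau[0]), (flux, ss.evaluate(flux))):
            dE = energy_barrier_responses(net, frame, obs)["dE"]
            assert np.abs(dE - ss.pi * target).max() < 1e-10
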