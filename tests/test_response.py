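import math

import numpy as np
import pytest

from caliberflow.fixtures import random_ergodic_network
from caliberflow.network import (
    ObservableCoefficients,
    build_frame,
    dwell_observable,
    traffic_observable,
)
from caliberflow.oracles import finite_difference_response
from caliberflow.response import (
    build_jacobian,
    energy_barrier_responses,
    invert_jacobian,
    observable_gradient,
    response_matrix,
)
from caliberflow.steady import edge_flux_observable, steady_observables


class TestJacobian:
    def test_two_state_asymmetric_entries(self, net2a):
        A = build_jacobian(net2a, build_frame(net2a)).A.toarray()
        assert np.allclose(A, [[0.5, 2.0], [0.5, -1.0]])

    def test_two_state_symmetric_entries(self, net2s):
        A = build_jacobian(net2s, build_frame(net2s)).A.toarray()
        assert np.allclose(A, [[0.5, 1.0], [0.5, -1.0]])

    def test_caliber_gradient_lives_on_reference_rows(self, net3c):
        frame = build_frame(net3c)
        jac = build_jacobian(net3c, frame)
        for d, (i, j) in enumerate(frame.directed_edges):
            expected = net3c.rates[(i, j)] if i == frame.reference else 0.0
            assert jac.caliber_grad[d] == expected

    def test_ring_block_structure(self, net3c):
        frame = build_frame(net3c)
        A = build_jacobian(net3c, frame).A.toarray()
        E = frame.n_edges
        # edge block: +1/2 on both directed rows of the own edge, 0 elsewhere
        for d in range(frame.n_basis):
            for e in range(E):
                assert A[d, e] == (0.5 if d // 2 == e else 0.0)
        # cycle block entries are +-1/2 or structural zeros
        cyc = A[:, E + 2:]
        assert set(np.round(np.unique(cyc), 12)) <= {-0.5, 0.0, 0.5}

    def test_inverse_closed_form(self, net2a):
        inv = invert_jacobian(build_jacobian(net2a, build_frame(net2a)))
        assert np.allclose(inv.full(), [[2 / 3, 4 / 3], [1 / 3, -1 / 3]])

    @pytest.mark.parametrize("fixture", ["net2a", "net3c"])
    def test_identity_sanity(self, fixture, request):
        net = request.getfixturevalue(fixture)
        frame = build_frame(net)
        jac = build_jacobian(net, frame)
        inv = invert_jacobian(jac)
        eye = jac.A.toarray() @ inv.full()
        assert np.abs(eye - np.eye(frame.n_basis)).max() < 1e-12


class TestResponseMatrix:
    def test_two_state_closed_forms(self, net2a):
        frame = build_frame(net2a)
        R = response_matrix(net2a, frame)
        t12 = frame.traffic_index("1", "2")
        d2 = frame.dwell_index("2")
        k12 = frame.directed_index("1", "2")
        k21 = frame.directed_index("2", "1")
        assert math.isclose(R.R[t12, k12], 4 / 9)
        assert math.isclose(R.R[t12, k21], 8 / 9)
        assert math.isclose(R.R[d2, k12], 2 / 9)
        assert math.isclose(R.R[d2, k21], -2 / 9)

    def test_unit_rate_dwell_response(self, net2s):
        frame = build_frame(net2s)
        R = response_matrix(net2s, frame)
        assert math.isclose(R.R[frame.dwell_index("2"), frame.directed_index("1", "2")], 1 / 4)

    def test_observable_gradient_both_scales(self, net2a):
        frame = build_frame(net2a)
        grad = observable_gradient(net2a, frame, traffic_observable(frame, "1", "2"))
        assert np.allclose(grad["d_dk"], [2 / 9, 8 / 9])
        assert np.allclose(grad["d_dlnk"], [4 / 9, 8 / 9])

    def test_zero_observable_zero_gradient(self, net3c):
        frame = build_frame(net3c)
        obs = ObservableCoefficients(np.zeros(frame.n_basis), frame)
        grad = observable_gradient(net3c, frame, obs)
        assert np.abs(grad["d_dlnk"]).max() == 0.0

    def test_cycle_flux_gradient_matches_finite_differences(self, net3c):
        frame = build_frame(net3c)
        obs = edge_flux_observable(frame, *frame.chords[0])
        grad = observable_gradient(net3c, frame, obs)["d_dlnk"]
        for d, e in enumerate(frame.directed_edges):
            fd = finite_difference_response(net3c, frame, obs, e)
            assert math.isclose(grad[d], fd, rel_tol=1e-6, abs_tol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_rim_matches_finite_differences_on_random_networks(self, seed):
        rng = np.random.default_rng(1000 + seed)
        V = int(rng.integers(3, 9))
        E = int(rng.integers(V - 1, V * (V - 1) // 2 + 1))
        net = random_ergodic_network(V, E, seed=2000 + seed)
        frame = build_frame(net)
        R = response_matrix(net, frame)
        scale = max(np.abs(R.R).max(), 1.0)
        for alpha in range(frame.n_basis):
            w = np.zeros(frame.n_basis)
            w[alpha] = 1.0
            obs = ObservableCoefficients(w, frame)
            for d, e in enumerate(frame.directed_edges):
                fd = finite_difference_response(net, frame, obs, e, h=1e-6)
                assert abs(R.R[alpha, d] - fd) <= 1e-6 * scale


class TestForceSusceptibility:
    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_with_positive_diagonal(self, seed):
        net = random_ergodic_network(5, 7, seed=300 + seed)
        frame = build_frame(net)
        R = response_matrix(net, frame)
        chi = R.R @ R.Ainv.full().T   # d<x_a>/dF_b via the chain rule
        assert np.abs(chi - chi.T).max() < 1e-8
        assert np.diag(chi).min() > 0  # monotonic own-force response


class TestEnergyBarrierResponses:
    def test_site_energy_scales_fluxes_by_occupancy(self, net3c):
        frame = build_frame(net3c)
        ss = steady_observables(net3c, frame)
        tau = traffic_observable(frame, "1", "2")
        resp = energy_barrier_responses(net3c, frame, tau)
        sidx = {s: n for n, s in enumerate(net3c.states)}
        for s in net3c.states:
            assert math.isclose(resp["dE"][sidx[s]], ss.pi[sidx[s]] * ss.tau[0], abs_tol=1e-12)
        flux = edge_flux_observable(frame, *frame.chords[0])
        respJ = energy_barrier_responses(net3c, frame, flux)
        assert np.allclose(respJ["dE"], (1 / 3) * (1 / 3), atol=1e-12)

    def test_barrier_blind_on_equilibrium_edge(self, net2a):
        # J12 = 0 on the 2-state network: barrier moves nothing but traffic
        frame = build_frame(net2a)
        resp = energy_barrier_responses(net2a, frame, dwell_observable(frame, "2"))
        assert abs(resp["dB"][0]) < 1e-12


class TestFrameInvariance:
    @pytest.mark.parametrize("seed", range(4))
    def test_physical_responses_independent_of_reference(self, seed):
        net = random_ergodic_network(5, 7, seed=400 + seed)
        frames = [build_frame(net, reference_node=net.states[0]),
                  build_frame(net, reference_node=net.states[2])]
        grads = []
        for fr in frames:
            R = response_matrix(net, fr)
            tau = traffic_observable(fr, *fr.undirected[0])
            flux = edge_flux_observable(fr, *fr.undirected[0])
            dwell = ObservableCoefficients(
                np.zeros(fr.n_basis), fr
            )
            # dwell of a fixed non-reference state present in both frames
            state = net.states[3]
            w = np.zeros(fr.n_basis)
            w[fr.dwell_index(state)] = 1.0
            dwell = ObservableCoefficients(w, fr)
            by_edge = {}
            for obs_name, obs in (("tau", tau), ("flux", flux), ("dwell", dwell)):
                g = observable_gradient(net, fr, obs)["d_dlnk"]
                by_edge[obs_name] = {e: g[d] for d, e in enumerate(fr.directed_edges)}
            grads.append(by_edge)
        for name in grads[0]:
            for e, v in grads[0][name].items():
                assert math.isclose(v, grads[1][name][e], abs_tol=1e-10)
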