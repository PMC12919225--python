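"""Universal response symmetries and kinetic bounds.

Three exact identities follow from ``A^{-1} A = I`` and hold for every
basis observable ``<x>`` of any ergodic network:

* node escaping:  the reference node's rate-weighted occupancy
  sensitivities minus node ``n``'s equal 1 iff ``<x> = pi_n``, else 0;
* edge reciprocity: ``(1/pi_i) d<x>/dk_ij + (1/pi_j) d<x>/dk_ji`` equals
  2 iff ``<x> = tau_ij``, else 0;
* cycle symmetry: the oriented sensitivity sum around any fundamental
  cycle equals 2 iff ``<x> = J_c``, else 0.

The edge coefficients ``Delta_ij = 1 - (1/pi_i) dJ_ij/dk_ij`` and
``Nabla_ij = (1/pi_i) dtau_ij/dk_ij - 1`` satisfy ``0 <= Delta <= 1`` and
``Nabla <= Delta``, equivalent to the kinetic hierarchy of one-way flux
responses ``pi_i >= dp_ij/dk_ij >= dp_ji/dk_ij >= 0`` (population
depletion, causality, Le Chatelier-like compensation).  Violations beyond
tolerance indicate an implementation bug, never physics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import RateNetwork, TreeCycleFrame, build_frame
from .response import ResponseMatrix, response_matrix


class BoundViolationError(AssertionError):
    pass


@dataclass(frozen=True)
class SymmetryResiduals:
    """LHS minus expected Kronecker-delta RHS for each identity.

    ``node[alpha, n]`` over basis observables x non-reference nodes;
    ``edge[alpha, e]`` over undirected edges; ``cycle[alpha, c]`` over
    fundamental cycles.
    """

    node: np.ndarray
    edge: np.ndarray
    cycle: np.ndarray

    @property
    def max_abs(self) -> float:
        parts = [self.node, self.edge, self.cycle]
        return max((float(np.abs(p).max()) for p in parts if p.size), default=0.0)


def _sensitivity_dk_over_pi(resp: ResponseMatrix) -> np.ndarray:
    """``(1/pi_i) d<x_alpha>/dk_ij`` = ``[A^{-1}]_{alpha,(ij)}`` for all alpha, (ij)."""
    return resp.R / resp.steady.p[np.newaxis, :]


def symmetry_residuals(
    net: RateNetwork,
    frame: TreeCycleFrame,
    resp: ResponseMatrix | None = None,
    numeric: bool = False,
    fd_step: float = 1e-6,
) -> SymmetryResiduals:
    """Evaluate all three identities for every basis observable.

    ``numeric=True`` replaces the analytic response matrix with central
    finite differences of the recomputed steady state — an independent
    check that separates math bugs from tolerance noise.
    """
    if numeric:
        from .oracles import finite_difference_response
        from .network import ObservableCoefficients

        R = np.empty((frame.n_basis, frame.n_basis))
        for alpha in range(frame.n_basis):
            w = np.zeros(frame.n_basis)
            w[alpha] = 1.0
            obs = ObservableCoefficients(w, frame)
            for d, e in enumerate(frame.directed_edges):
                R[alpha, d] = finite_difference_response(net, frame, obs, e, h=fd_step)
        r = resp if resp is not None else response_matrix(net, frame)
        B = R / r.steady.p[np.newaxis, :]
    else:
        r = resp if resp is not None else response_matrix(net, frame)
        B = _sensitivity_dk_over_pi(r)  # B[alpha, d] = k_d/p_d * dlnk resp = Ainv entry

    nB = frame.n_basis
    E, V = frame.n_edges, net.n_states
    k = frame.rate_vector(net)
    dedges = frame.directed_edges
    m = frame.reference

    # node escaping: sum_l k_ml B[:, (m->l)] - sum_j k_nj B[:, (n->j)] = delta(alpha, dwell_n)
    out_rows: dict[str, list[int]] = {s: [] for s in net.states}
    for d, (i, _j) in enumerate(dedges):
        out_rows[i].append(d)
    esc_m = sum(k[d] * B[:, d] for d in out_rows[m])
    node = np.empty((nB, V - 1))
    for n, s in enumerate(frame.nonref_nodes):
        lhs = esc_m - sum(k[d] * B[:, d] for d in out_rows[s])
        expected = np.zeros(nB)
        expected[frame.dwell_index(s)] = 1.0
        node[:, n] = lhs - expected

    # edge reciprocity: B[:, (ij)] + B[:, (ji)] = 2 delta(alpha, traffic_e)
    edge = np.empty((nB, E))
    for e in range(E):
        lhs = B[:, 2 * e] + B[:, 2 * e + 1]
        expected = np.zeros(nB)
        expected[e] = 2.0
        edge[:, e] = lhs - expected

    # cycle symmetry: oriented sum of B over the cycle = 2 delta(alpha, cycle_c)
    S = frame.cycle_signs()
    cycle = np.empty((nB, frame.n_cycles))
    for c in range(frame.n_cycles):
        lhs = B @ S[c]
        expected = np.zeros(nB)
        expected[frame.cycle_index(c)] = 2.0
        cycle[:, c] = lhs - expected

    return SymmetryResiduals(node, edge, cycle)


@dataclass(frozen=True)
class BoundSample:
    """Per-directed-edge one-way flux sensitivities and Delta/Nabla coefficients."""

    frame: TreeCycleFrame
    pi_src: np.ndarray
    dpij_dkij: np.ndarray
    dpji_dkij: np.ndarray
    delta: np.ndarray
    nabla: np.ndarray
    J_edge: np.ndarray
    saturated_middle: np.ndarray  # True where the causality bound is tight

    def to_frame(self) -> pd.DataFrame:
        dedges = self.frame.directed_edges
        return pd.DataFrame(
            {
                "source": [i for i, _ in dedges],
                "target": [j for _, j in dedges],
                "pi_i": self.pi_src,
                "dpij_dkij": self.dpij_dkij,
                "dpji_dkij": self.dpji_dkij,
                "Delta": self.delta,
                "Nabla": self.nabla,
                "J_ij": self.J_edge,
                "middle_saturated": self.saturated_middle,
            }
        )


def _flux_sensitivities(net: RateNetwork, frame: TreeCycleFrame, resp: ResponseMatrix):
    """(pi_src, dp_ij/dk_ij, dp_ji/dk_ij) per directed edge from the RIM."""
    ss = resp.steady
    k = frame.rate_vector(net)
    src = frame.source_state_index()
    tgt = frame.target_state_index()
    dPi = resp.dpi_dlnk()  # d pi_n / d ln k_e
    nD = frame.n_basis
    dpij = np.empty(nD)
    dpji = np.empty(nD)
    for e in range(nD):
        rev = e + 1 if e % 2 == 0 else e - 1
        dpij[e] = ss.pi[src[e]] + dPi[src[e], e]            # pi_i + k dpi_i/dk = pi_i + dpi_i/dlnk
        dpji[e] = k[rev] * dPi[src[rev], e] / k[e]          # k_ji dpi_j/dk_ij
    return ss.pi[src], dpij, dpji


def delta_nabla_coefficients(
    net: RateNetwork,
    frame: TreeCycleFrame,
    resp: ResponseMatrix | None = None,
) -> pd.DataFrame:
    """``Delta_ij`` and ``Nabla_ij`` per directed edge."""
    r = resp if resp is not None else response_matrix(net, frame)
    return bound_hierarchy_check(net, frame, r).to_frame()


def bound_hierarchy_check(
    net: RateNetwork,
    frame: TreeCycleFrame,
    resp: ResponseMatrix | None = None,
    tol: float = 1e-10,
) -> BoundSample:
    """Assert ``pi_i >= dp_ij/dk_ij >= dp_ji/dk_ij >= 0`` on every edge.

    A violation beyond ``tol`` raises :class:`BoundViolationError` naming
    the edge — the hierarchy is a theorem for valid input, so a failure
    flags an implementation bug.  The causality (middle) bound saturates on
    bridge edges, whose net flux is identically zero no matter how the rate
    is perturbed; a merely *instantaneously* zero flux (e.g. a cycle edge of
    a detailed-balance network) does not saturate it, since the perturbation
    itself drives a current through the edge.
    """
    r = resp if resp is not None else response_matrix(net, frame)
    pi_src, dpij, dpji = _flux_sensitivities(net, frame, r)
    ss = r.steady
    scale = max(1.0, float(np.abs(ss.p).max()))
    for e, (i, j) in enumerate(frame.directed_edges):
        chain = (pi_src[e] - dpij[e], dpij[e] - dpji[e], dpji[e])
        if min(chain) < -tol * scale:
            raise BoundViolationError(
                f"kinetic hierarchy violated on edge ({i},{j}): "
                f"pi_i={pi_src[e]:.3e}, dpij={dpij[e]:.3e}, dpji={dpji[e]:.3e}"
            )
    tau_resp = np.empty(frame.n_basis)
    B = _sensitivity_dk_over_pi(r)
    for e in range(frame.n_basis):
        tau_resp[e] = pi_src[e] * B[e // 2, e]  # d tau / dk_ij
    delta = 1.0 - (dpij - dpji) / pi_src
    nabla = tau_resp / pi_src - 1.0
    J = ss.J_edge
    return BoundSample(
        frame, pi_src, dpij, dpji, delta, nabla, J,
        saturated_middle=np.abs(dpij - dpji) <= tol * scale,
    )


def ensemble_bound_scatter(
    V: int,
    count: int,
    seed: int,
    E: int | None = None,
    rate_bounds: tuple[float, float] = (0.1, 10.0),
) -> pd.DataFrame:
    """Normalized forward/reverse flux responses over a random ensemble.

    For every directed edge of every sampled network, the pair
    ``x = (1/pi_i) dp_ij/dk_ij``, ``y = (1/pi_i) dp_ji/dk_ij``; the theory
    confines all points to the triangle ``1 >= x >= y >= 0``.  Both axes
    are normalized by the source occupancy ``pi_i``.
    """
    from .fixtures import random_ergodic_network

    if count < 1:
        raise ValueError("count must be >= 1")
    rows = []
    for n in range(count):
        net = random_ergodic_network(V, E if E is not None else min(V + 1, V * (V - 1) // 2),
                                     seed=seed + n, rate_bounds=rate_bounds)
        frame = build_frame(net)
        r = response_matrix(net, frame)
        pi_src, dpij, dpji = _flux_sensitivities(net, frame, r)
        for e, (i, j) in enumerate(frame.directed_edges):
            rows.append((n, i, j, dpij[e] / pi_src[e], dpji[e] / pi_src[e]))
    return pd.DataFrame(rows, columns=["network", "source", "target", "x", "y"])
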