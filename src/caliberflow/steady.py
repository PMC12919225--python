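"""Stationary distribution and mean counting-observable rates.

The stationary distribution solves the master-equation balance
``pi @ Q = 0`` with the rate matrix ``Q[i, j] = k_ij`` (off-diagonal) and
``Q[i, i] = -sum_j k_ij``.  From ``pi`` follow the one-way fluxes
``p_ij = pi_i k_ij``, the edge traffic ``tau_ij = p_ij + p_ji``, the net
fluxes ``J_ij = p_ij - p_ji``, the per-cycle fluxes (net flux on each
chord), and the caliber rate ``c = sum_{j != m} (k_mj - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .network import (
    ObservableCoefficients,
    RateNetwork,
    TreeCycleFrame,
)

_DENSE_MAX_STATES = 200


class DegenerateNetworkError(RuntimeError):
    """Linear solve for the stationary distribution failed or is inaccurate."""


def rate_matrix(net: RateNetwork, sparse: bool | None = None):
    """Generator ``Q`` with ``Q[i,j] = k_ij`` and zero row sums."""
    V = net.n_states
    sidx = {s: n for n, s in enumerate(net.states)}
    if sparse is None:
        sparse = V > _DENSE_MAX_STATES
    if sparse:
        rows, cols, vals = [], [], []
        diag = np.zeros(V)
        for (a, b), k in net.rates.items():
            rows.append(sidx[a]); cols.append(sidx[b]); vals.append(k)
            diag[sidx[a]] -= k
        rows += list(range(V)); cols += list(range(V)); vals += list(diag)
        return scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(V, V))
    Q = np.zeros((V, V))
    for (a, b), k in net.rates.items():
        Q[sidx[a], sidx[b]] = k
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(net: RateNetwork, balance_tol: float = 1e-12) -> np.ndarray:
    """Stationary probability vector in state-list order.

    One balance equation is replaced by normalisation; the residual of the
    full balance system is checked against ``balance_tol`` (relative).
    """
    V = net.n_states
    Q = rate_matrix(net)
    if scipy.sparse.issparse(Q):
        M = Q.T.tolil()
        M[0, :] = 1.0
        b = np.zeros(V)
        b[0] = 1.0
        try:
            pi = scipy.sparse.linalg.spsolve(M.tocsc(), b)
        except Exception as exc:  # pragma: no cover - solver failure path
            raise DegenerateNetworkError(f"degenerate network: {exc}") from exc
        Qd = Q
    else:
        M = Q.T.copy()
        M[0, :] = 1.0
        b = np.zeros(V)
        b[0] = 1.0
        try:
            pi = scipy.linalg.solve(M, b)
        except scipy.linalg.LinAlgError as exc:
            raise DegenerateNetworkError(f"degenerate network: {exc}") from exc
        Qd = Q
    resid = np.abs(pi @ Qd).max()
    scale = max(abs(k) for k in net.rates.values())
    if not np.all(np.isfinite(pi)) or resid > balance_tol * max(scale, 1.0) * 1e2:
        raise DegenerateNetworkError(f"degenerate network: balance residual {resid:g}")
    if np.any(pi <= 0):
        raise DegenerateNetworkError("degenerate network: non-positive stationary probability")
    return pi / pi.sum()


@dataclass(frozen=True)
class SteadyState:
    """Stationary distribution and all mean basis-observable rates."""

    frame: TreeCycleFrame
    pi: np.ndarray            # per state
    p: np.ndarray             # one-way flux per directed edge index
    tau: np.ndarray           # traffic per undirected edge
    J_edge: np.ndarray        # net flux per directed edge index (J_ij = -J_ji)
    J_cycle: np.ndarray       # net flux per fundamental cycle (on its chord)
    caliber_rate: float

    @property
    def mean_vector(self) -> np.ndarray:
        """Mean observable rates in basis order (tau, pi_{n != m}, J_c)."""
        net = self.frame.net
        ref_i = net.states.index(self.frame.reference)
        pi_nonref = np.delete(self.pi, ref_i)
        return np.concatenate([self.tau, pi_nonref, self.J_cycle])

    def evaluate(self, obs: ObservableCoefficients) -> float:
        return float(obs.weights @ self.mean_vector)


def steady_observables(net: RateNetwork, frame: TreeCycleFrame) -> SteadyState:
    """Populate every mean CFT rate observable at steady state."""
    pi = stationary_distribution(net)
    src = frame.source_state_index()
    k = np.array([net.rates[d] for d in frame.directed_edges])
    p = pi[src] * k
    E = frame.n_edges
    tau = p[0::2] + p[1::2]
    J_edge = np.empty_like(p)
    J_edge[0::2] = p[0::2] - p[1::2]
    J_edge[1::2] = -J_edge[0::2]
    J_cycle = np.array(
        [J_edge[frame.directed_index(*frame.chords[c])] for c in range(frame.n_cycles)]
    )
    m = frame.reference
    c_rate = sum(net.rates[(m, j)] - 1.0 for j in net.neighbors(m))
    return SteadyState(frame, pi, p, tau, J_edge, J_cycle, float(c_rate))


def edge_flux_observable(frame: TreeCycleFrame, i, j) -> ObservableCoefficients:
    """Net flux through directed edge ``i -> j`` as cycle-basis weights.

    A chord's net flux is its own cycle coordinate; a tree edge's net flux
    is the signed sum of the fluxes of the fundamental cycles traversing it
    (Kirchhoff's current law).
    """
    d = frame.directed_index(i, j)  # raises if edge absent
    S = frame.cycle_signs()
    w = np.zeros(frame.n_basis)
    for c in range(frame.n_cycles):
        if S[c, d]:
            w[frame.cycle_index(c)] = S[c, d]
    return ObservableCoefficients(w, frame, label=f"edgeflux:{i}-{j}")
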