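"""Caliber-force coordinates: forces conjugate to the counting basis.

The path entropy of a trajectory — the log probability ratio of the jump
process with rates ``k`` against the unit-rate reference — is asymptotically
``F(k) . X - c(k) t``: a force vector conjugate to the complete counting
basis ``X`` minus the caliber rate, the dynamical analogue of a free
energy.  The forces are

* edge exchange:  ``F_edge,ij = (1/2) ln(k_ij * k_ji)``  (conjugate to traffic),
* node dwell:     ``F_node,n = eps_m - eps_n`` with ``eps_i = sum_j k_ij - 1``,
* cycle affinity: ``F_cycle,c = (1/2) ln(prod fwd rates / prod rev rates)``,

and ``c(k) = eps_m`` for reference node ``m``.  The map ``ln k -> F`` is a
diffeomorphism; its Newton inverse is provided here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import ObservableCoefficients, RateNetwork, TreeCycleFrame


@dataclass(frozen=True)
class ForceVector:
    """Forces in basis order: edge block, node block, cycle block."""

    values: np.ndarray
    frame: TreeCycleFrame

    @property
    def F_edge(self) -> np.ndarray:
        return self.values[: self.frame.n_edges]

    @property
    def F_node(self) -> np.ndarray:
        E, V = self.frame.n_edges, self.frame.net.n_states
        return self.values[E : E + V - 1]

    @property
    def F_cycle(self) -> np.ndarray:
        E, V = self.frame.n_edges, self.frame.net.n_states
        return self.values[E + V - 1 :]


@dataclass(frozen=True)
class TrajectoryCounts:
    """Raw counting observables of one trajectory.

    ``N`` maps directed edges to jump counts; ``T`` maps states to total
    dwell time; ``t`` is the duration (``sum(T) == t``).
    """

    N: dict[tuple[str, str], int]
    T: dict[str, float]
    t: float


def excess_escape_rates(net: RateNetwork) -> np.ndarray:
    """``eps_i = sum_j (k_ij - 1)`` over neighbors, in state order.

    The reference process runs at unit rate on every edge of the same
    support, so the excess escape rate of a state is its total escape rate
    minus its degree.
    """
    eps = np.zeros(net.n_states)
    sidx = {s: n for n, s in enumerate(net.states)}
    for (a, _b), k in net.rates.items():
        eps[sidx[a]] += k - 1.0
    return eps


def caliber_rate(net: RateNetwork, frame: TreeCycleFrame) -> float:
    """``c(k) = sum_{j != m}(k_mj - 1)``: the excess escape rate of the reference."""
    m = frame.reference
    return float(sum(net.rates[(m, j)] - 1.0 for j in net.neighbors(m)))


def forces_from_rates(net: RateNetwork, frame: TreeCycleFrame) -> ForceVector:
    F = np.zeros(frame.n_basis)
    eps = excess_escape_rates(net)
    sidx = {s: n for n, s in enumerate(net.states)}
    for e, (a, b) in enumerate(frame.undirected):
        F[e] = 0.5 * math.log(net.rates[(a, b)] * net.rates[(b, a)])
    eps_m = eps[sidx[frame.reference]]
    for n, s in enumerate(frame.nonref_nodes):
        F[frame.n_edges + n] = eps_m - eps[sidx[s]]
    for c, cyc in enumerate(frame.cycles):
        aff = sum(math.log(net.rates[d] / net.rates[d[::-1]]) for d in cyc)
        F[frame.cycle_index(c)] = 0.5 * aff
    return ForceVector(F, frame)


def rates_from_forces(
    F: ForceVector,
    frame: TreeCycleFrame,
    initial_guess: RateNetwork | None = None,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> RateNetwork:
    """Invert ``F(k)`` by damped Newton iteration on ``ln k``.

    The Jacobian of the force map with respect to ``ln k`` is the transpose
    of the sparse matrix ``A`` built in :mod:`caliberflow.response`, so each
    Newton step is one sparse solve.  Raises ``RuntimeError`` with the final
    residual on non-convergence.
    """
    from .response import build_jacobian  # local import: response builds on caliber's frame only

    net = initial_guess
    if net is None:
        net = RateNetwork(frame.net.states, {d: 1.0 for d in frame.net.rates}, dict(frame.net.metadata))
    target = np.asarray(F.values, dtype=float)
    dedges = frame.directed_edges
    lnk = np.log([net.rates[d] for d in dedges])

    def as_net(lnk_vec):
        return net.with_rates({d: math.exp(v) for d, v in zip(dedges, lnk_vec)})

    cur = as_net(lnk)
    resid = forces_from_rates(cur, frame).values - target
    for _ in range(max_iter):
        err = np.abs(resid).max()
        if err <= tol:
            return cur
        A = build_jacobian(cur, frame).A
        # dF/dlnk = A^T  (A rows are directed edges, columns are forces)
        step = np.linalg.solve(A.toarray().T, -resid)
        lam = 1.0
        for _bt in range(40):
            trial = as_net(lnk + lam * step)
            trial_resid = forces_from_rates(trial, frame).values - target
            if np.abs(trial_resid).max() < err:
                break
            lam *= 0.5
        else:
            raise RuntimeError(f"rates_from_forces: line search stalled at residual {err:g}")
        lnk = lnk + lam * step
        cur, resid = trial, trial_resid
    err = np.abs(resid).max()
    if err <= tol:
        return cur
    raise RuntimeError(f"rates_from_forces: no convergence, residual {err:g}")


def empirical_rates(frame: TreeCycleFrame, counts: TrajectoryCounts) -> np.ndarray:
    """Empirical basis observable rates ``x`` of a trajectory.

    Traffic: ``(N_ij + N_ji)/t``; dwell fraction: ``T_n/t``; cycle flux:
    net count on the chord over ``t``.
    """
    if counts.t <= 0:
        raise ValueError("trajectory duration must be positive")
    x = np.zeros(frame.n_basis)
    N = counts.N
    for e, (a, b) in enumerate(frame.undirected):
        x[e] = (N.get((a, b), 0) + N.get((b, a), 0)) / counts.t
    for n, s in enumerate(frame.nonref_nodes):
        x[frame.n_edges + n] = counts.T.get(s, 0.0) / counts.t
    for c, (a, b) in enumerate(frame.chords):
        x[frame.cycle_index(c)] = (N.get((a, b), 0) - N.get((b, a), 0)) / counts.t
    return x


def path_entropy_rate(
    net: RateNetwork, frame: TreeCycleFrame, counts: TrajectoryCounts
) -> tuple[float, float]:
    """Path entropy per unit time, in raw-count and caliber forms.

    Returns ``(raw, caliber_form)`` where ``raw = [sum N_ij ln k_ij -
    sum T_i eps_i]/t`` and ``caliber_form = F . x - c`` with ``x`` the
    empirical basis rates.  The two agree up to a boundary term that decays
    as ``O(1/t)``.
    """
    for d in counts.N:
        if d not in net.rates:
            raise ValueError(f"trajectory counts on edge {d} absent from network")
    eps = excess_escape_rates(net)
    sidx = {s: n for n, s in enumerate(net.states)}
    raw = sum(n_ij * math.log(net.rates[d]) for d, n_ij in counts.N.items())
    raw -= sum(T_i * eps[sidx[s]] for s, T_i in counts.T.items())
    raw /= counts.t
    F = forces_from_rates(net, frame)
    x = empirical_rates(frame, counts)
    caliber_form = float(F.values @ x) - caliber_rate(net, frame)
    return raw, caliber_form
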