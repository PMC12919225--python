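"""Independent verification engines.

Three routes that never touch the inverse-Jacobian machinery:

* exact-jump (Gillespie) stochastic simulation with full counting
  statistics, for sampling-based checks of means, covariances and the
  per-transition noise sources;
* tilted-generator spectral cumulants (Koza's method): derivatives of the
  dominant eigenvalue of the generator with jump terms weighted by
  ``exp(s w_ij)`` give the mean and variance rates of any jump-counting
  observable;
* central finite differences of the recomputed steady state, for response
  gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .caliber import TrajectoryCounts, empirical_rates
from .network import ObservableCoefficients, RateNetwork, TreeCycleFrame
from .response import build_jacobian
from .steady import rate_matrix, stationary_distribution, steady_observables


# ---------------------------------------------------------------------------
# Gillespie simulation
# ---------------------------------------------------------------------------

def gillespie_simulate(
    net: RateNetwork,
    t: float,
    seed,
    initial_state: str | None = None,
) -> TrajectoryCounts:
    """Exact-jump simulation for duration ``t``; the final dwell is truncated.

    ``seed`` may be an int or a ``numpy.random.Generator``.  The initial
    state is drawn from the stationary distribution unless given, so
    ensemble statistics start in steady state.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = net.states
    sidx = {s: n for n, s in enumerate(states)}
    nbrs = [net.neighbors(s) for s in states]
    esc = np.array([sum(net.rates[(s, v)] for v in nbrs[i]) for i, s in enumerate(states)])
    cum = [np.cumsum([net.rates[(s, v)] for v in nbrs[i]]) for i, s in enumerate(states)]

    if initial_state is None:
        pi = stationary_distribution(net)
        cur = int(rng.choice(len(states), p=pi))
    else:
        cur = sidx[str(initial_state)]

    N: dict[tuple[str, str], int] = {}
    T = np.zeros(len(states))
    clock = 0.0
    while True:
        dwell = rng.exponential(1.0 / esc[cur])
        if clock + dwell >= t:
            T[cur] += t - clock
            break
        T[cur] += dwell
        clock += dwell
        u = rng.random() * esc[cur]
        nxt = nbrs[cur][int(np.searchsorted(cum[cur], u))]
        d = (states[cur], nxt)
        N[d] = N.get(d, 0) + 1
        cur = sidx[nxt]
    if t == 0:
        return TrajectoryCounts({}, {s: 0.0 for s in states}, 0.0)
    return TrajectoryCounts(N, {s: float(T[i]) for i, s in enumerate(states)}, float(t))


@dataclass(frozen=True)
class EnsembleStatistics:
    """Empirical means and scaled covariances over an ensemble of trajectories."""

    frame: TreeCycleFrame
    mean_x: np.ndarray            # mean basis rates
    mean_x_se: np.ndarray
    cov_x: np.ndarray             # t*Cov of basis observables
    cov_x_se: np.ndarray
    lam_mean: np.ndarray          # per-directed-edge noise sources
    lam_cov: np.ndarray           # t*Cov(lambda_ij, lambda_mn)
    lam_cov_se: np.ndarray
    eq7_residual: float           # max |lambda - (A x - grad c)| over trajectories
    n_traj: int
    t: float
    seed: int


def _lambda_vector(net: RateNetwork, frame: TreeCycleFrame, counts: TrajectoryCounts) -> np.ndarray:
    lam = np.empty(frame.n_basis)
    for d, (i, j) in enumerate(frame.directed_edges):
        lam[d] = (counts.N.get((i, j), 0) - net.rates[(i, j)] * counts.T[i]) / counts.t
    return lam


def ensemble_statistics(
    net: RateNetwork,
    frame: TreeCycleFrame,
    t: float,
    n_traj: int,
    seed: int,
) -> EnsembleStatistics:
    """Simulate ``n_traj`` trajectories and collect counting statistics.

    Per-trajectory RNG streams are spawned from a single ``SeedSequence``,
    so results depend only on ``(seed, n_traj)``, not execution order.
    Also evaluates the trajectory-level identity ``lambda ~ A x - grad c``.
    """
    if n_traj < 2:
        raise ValueError("need at least 2 trajectories")
    children = np.random.SeedSequence(seed).spawn(n_traj)
    jac = build_jacobian(net, frame)
    A = jac.A.toarray()
    X = np.empty((n_traj, frame.n_basis))
    L = np.empty((n_traj, frame.n_basis))
    eq7 = 0.0
    for n, child in enumerate(children):
        counts = gillespie_simulate(net, t, np.random.default_rng(child))
        X[n] = empirical_rates(frame, counts)
        L[n] = _lambda_vector(net, frame, counts)
        eq7 = max(eq7, float(np.abs(L[n] - (A @ X[n] - jac.caliber_grad)).max()))

    def _cov_with_se(M):
        mu = M.mean(axis=0)
        C = M - mu
        prod = np.einsum("na,nb->nab", C, C)
        cov = t * prod.sum(axis=0) / (n_traj - 1)
        se = t * prod.std(axis=0, ddof=1) / math.sqrt(n_traj)
        return cov, se

    cov_x, cov_x_se = _cov_with_se(X)
    lam_cov, lam_cov_se = _cov_with_se(L)
    return EnsembleStatistics(
        frame=frame,
        mean_x=X.mean(axis=0),
        mean_x_se=X.std(axis=0, ddof=1) / math.sqrt(n_traj),
        cov_x=cov_x,
        cov_x_se=cov_x_se,
        lam_mean=L.mean(axis=0),
        lam_cov=lam_cov,
        lam_cov_se=lam_cov_se,
        eq7_residual=eq7,
        n_traj=n_traj,
        t=float(t),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Tilted-generator spectral cumulants
# ---------------------------------------------------------------------------

def _dominant_eigenvalue(net: RateNetwork, weights: dict[tuple[str, str], float], s: float) -> float:
    Q = rate_matrix(net, sparse=False).astype(float)
    sidx = {st: n for n, st in enumerate(net.states)}
    L = Q.copy()
    for (a, b), w in weights.items():
        if w and (a, b) in net.rates:
            L[sidx[a], sidx[b]] = net.rates[(a, b)] * math.exp(s * w)
    ev = scipy.linalg.eigvals(L)
    return float(ev.real.max())


def tilted_cumulants(
    net: RateNetwork,
    weights: dict[tuple[str, str], float],
    step: float = 1e-3,
) -> tuple[float, float]:
    """Mean and variance rates of ``sum_ij w_ij N_ij / t`` via Koza's method.

    The dominant eigenvalue ``lam(s)`` of the generator with off-diagonals
    ``k_ij exp(s w_ij)`` is the scaled cumulant generating function;
    ``lam'(0)`` and ``lam''(0)`` are estimated by Richardson-extrapolated
    central differences (``lam(0) = 0`` exactly for a generator).  The
    default tilt step balances the O(step^4) truncation of the
    extrapolated stencil against eigenvalue roundoff amplified by 1/step^2,
    which matters on networks with fast (≫1) rates.
    """
    weights = {(str(a), str(b)): float(w) for (a, b), w in weights.items()}
    for d in weights:
        if d not in net.rates:
            raise ValueError(f"counting weight on edge {d} absent from network")
    if not any(weights.values()):
        return 0.0, 0.0

    def lam(s):
        return _dominant_eigenvalue(net, weights, s)

    h = step
    lp, lm = lam(h), lam(-h)
    lp2, lm2 = lam(h / 2), lam(-h / 2)
    d1_h = (lp - lm) / (2 * h)
    d1_h2 = (lp2 - lm2) / h
    mean = (4 * d1_h2 - d1_h) / 3
    d2_h = (lp + lm) / h**2           # lam(0) = 0
    d2_h2 = (lp2 + lm2) / (h / 2) ** 2
    var = (4 * d2_h2 - d2_h) / 3
    return float(mean), float(var)


def counting_weights(frame: TreeCycleFrame, obs: ObservableCoefficients) -> dict[tuple[str, str], float]:
    """Map a jump-representable observable to per-directed-edge count weights.

    Traffic coordinates count +1 in both directions of their edge; cycle
    fluxes count +-1 on their chord.  Dwell coordinates have no jump
    representation (they are verified by simulation instead) and raise.
    """
    E, V = frame.n_edges, frame.net.n_states
    w_dwell = obs.weights[E : E + V - 1]
    if np.any(w_dwell != 0):
        raise ValueError("dwell observables are not jump-representable")
    out: dict[tuple[str, str], float] = {}
    for e, (a, b) in enumerate(frame.undirected):
        if obs.weights[e]:
            out[(a, b)] = out.get((a, b), 0.0) + obs.weights[e]
            out[(b, a)] = out.get((b, a), 0.0) + obs.weights[e]
    for c, (a, b) in enumerate(frame.chords):
        wc = obs.weights[frame.cycle_index(c)]
        if wc:
            out[(a, b)] = out.get((a, b), 0.0) + wc
            out[(b, a)] = out.get((b, a), 0.0) - wc
    return out


def basis_weights_from_counting(frame: TreeCycleFrame, w: dict[tuple[str, str], float]) -> ObservableCoefficients:
    """Project arbitrary jump-count weights onto the observable basis.

    ``N_ij = Phi_ij/2 + net_ij/2`` and net fluxes reduce to cycle
    coordinates by Kirchhoff's law, so any counting functional has an
    asymptotically equivalent basis representation.
    """
    wv = np.zeros(frame.n_basis)
    S = frame.cycle_signs()
    for (a, b), weight in w.items():
        d = frame.directed_index(a, b)
        wv[frame.traffic_index(a, b)] += weight / 2.0
        for c in range(frame.n_cycles):
            if S[c, d]:
                wv[frame.cycle_index(c)] += weight * S[c, d] / 2.0
    return ObservableCoefficients(wv, frame, label="counting")


# ---------------------------------------------------------------------------
# Finite-difference responses
# ---------------------------------------------------------------------------

def finite_difference_response(
    net: RateNetwork,
    frame: TreeCycleFrame,
    obs: ObservableCoefficients,
    edge: tuple[str, str],
    h: float = 1e-6,
) -> float:
    """Central-difference ``d<x>/d ln k_edge`` by recomputing the steady state."""
    if h <= 0:
        raise ValueError("h must be positive")
    i, j = str(edge[0]), str(edge[1])
    k0 = net.rates[(i, j)]
    vals = []
    for sgn in (+1.0, -1.0):
        pert = net.with_rates({(i, j): k0 * math.exp(sgn * h)})
        ss = steady_observables(pert, frame)
        vals.append(ss.evaluate(obs))
    return (vals[0] - vals[1]) / (2 * h)


def brute_force_randomness_gradient(
    net: RateNetwork,
    frame: TreeCycleFrame,
    flux_obs: ObservableCoefficients,
    h: float = 3e-3,
    step: float = 3e-2,
) -> np.ndarray:
    """Gradient of ``r`` by finite differences over spectral cumulants.

    This is the generating-function baseline: for each of the ``2E`` rates,
    the tilted-generator mean and variance are recomputed at ``k e^{+-h}``.
    Cost grows with both the edge count and the eigensolve size.  The
    default steps are deliberately coarse: eigenvalue roundoff ``~eps |L|``
    is amplified by ``1/step^2`` and again by ``1/h``, so tight steps make
    the baseline noisier, not sharper.
    """
    w = counting_weights(frame, flux_obs)
    grad = np.empty(frame.n_basis)
    for d, (i, j) in enumerate(frame.directed_edges):
        k0 = net.rates[(i, j)]
        rs = []
        for sgn in (+1.0, -1.0):
            pert = net.with_rates({(i, j): k0 * math.exp(sgn * h)})
            mean, var = tilted_cumulants(pert, w, step=step)
            rs.append(var / abs(mean))
        grad[d] = (rs[0] - rs[1]) / (2 * h)
    return grad
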