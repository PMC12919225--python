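"""The rate-to-force Jacobian and exact steady-state response gradients.

``A[(ij), beta] = dF_beta / d ln k_ij`` is a sparse ``2E x 2E`` matrix with
rows indexed by directed edges and columns by basis forces:

* edge-force column of edge ``{a,b}``: ``+1/2`` on rows ``a->b`` and ``b->a``;
* node-force column ``n``: ``k_ij (delta_{i,m} - delta_{i,n})`` on row ``i->j``;
* cycle-force column ``c``: ``+-1/2`` on rows traversed forward/backward by
  the fundamental cycle;

everything else is a structural zero.  Inverting ``A`` yields the
response-inverse-matrix (RIM) relation

    d<x_alpha> / d ln k_ij = pi_i k_ij [A^{-1}]_{alpha, (ij)},

i.e. every steady-state sensitivity is one matrix element of the inverse
Jacobian weighted by the one-way flux of the perturbed transition.  The
Jacobian also carries the caliber gradient ``d c / d ln k_mj = k_mj`` on
edges leaving the reference, used in the trajectory-level noise identity
``lambda ~ A x - grad c``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .network import ObservableCoefficients, RateNetwork, TreeCycleFrame
from .steady import SteadyState, steady_observables

logger = logging.getLogger(__name__)

_DENSE_MAX = 500  # 2E above which the full inverse is no longer formed


class SingularJacobianError(RuntimeError):
    pass


@dataclass(frozen=True)
class JacobianA:
    """Sparse Jacobian ``A`` plus the caliber gradient over directed edges."""

    A: scipy.sparse.csr_matrix
    caliber_grad: np.ndarray
    frame: TreeCycleFrame


def build_jacobian(net: RateNetwork, frame: TreeCycleFrame) -> JacobianA:
    nE = frame.n_edges
    nB = frame.n_basis
    m = frame.reference
    dedges = frame.directed_edges
    node_col = {s: nE + n for n, s in enumerate(frame.nonref_nodes)}

    rows, cols, vals = [], [], []
    cal = np.zeros(nB)
    for d, (i, j) in enumerate(dedges):
        k = net.rates[(i, j)]
        rows.append(d); cols.append(d // 2); vals.append(0.5)  # edge-force block
        if i == m:
            for col in node_col.values():
                rows.append(d); cols.append(col); vals.append(k)
            cal[d] = k
        else:
            rows.append(d); cols.append(node_col[i]); vals.append(-k)
    S = frame.cycle_signs()  # (n_cycles, 2E) over directed edges
    for c in range(frame.n_cycles):
        col = frame.cycle_index(c)
        for d in np.nonzero(S[c])[0]:
            rows.append(int(d)); cols.append(col); vals.append(0.5 * S[c, d])
    A = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(nB, nB))
    return JacobianA(A, cal, frame)


class JacobianInverse:
    """Factorization handle for ``A^{-1}``.

    For small systems the full dense inverse is formed once; above
    ``_DENSE_MAX`` rows of ``A^{-1}`` are extracted on demand by transposed
    sparse solves, which is all the RIM relation needs for single
    observables.
    """

    def __init__(self, jac: JacobianA):
        self.jac = jac
        n = jac.A.shape[0]
        self._dense = n <= _DENSE_MAX
        if self._dense:
            Ad = jac.A.toarray()
            try:
                self._inv = scipy.linalg.inv(Ad)
            except scipy.linalg.LinAlgError as exc:
                raise SingularJacobianError(f"degenerate frame/network: {exc}") from exc
            cond = np.linalg.cond(Ad)
            if not np.isfinite(cond):
                raise SingularJacobianError("degenerate frame/network: singular Jacobian")
            logger.debug("Jacobian condition number: %.3g", cond)
        else:
            try:
                self._lu = scipy.sparse.linalg.splu(jac.A.tocsc())
            except RuntimeError as exc:
                raise SingularJacobianError(f"degenerate frame/network: {exc}") from exc

    def full(self) -> np.ndarray:
        if self._dense:
            return self._inv
        n = self.jac.A.shape[0]
        return self._lu.solve(np.eye(n))

    def row(self, alpha: int) -> np.ndarray:
        """Row ``alpha`` of ``A^{-1}`` (one transposed solve when sparse)."""
        if self._dense:
            return self._inv[alpha]
        e = np.zeros(self.jac.A.shape[0])
        e[alpha] = 1.0
        return self._lu.solve(e, trans="T")

    def solve(self, b: np.ndarray) -> np.ndarray:
        """``A^{-1} b``."""
        return self._inv @ b if self._dense else self._lu.solve(np.asarray(b, dtype=float))

    def solve_T(self, w: np.ndarray) -> np.ndarray:
        """``A^{-T} w`` — observable weights pushed to directed-edge space."""
        w = np.asarray(w, dtype=float)
        return self._inv.T @ w if self._dense else self._lu.solve(w, trans="T")


def invert_jacobian(A: JacobianA) -> JacobianInverse:
    return JacobianInverse(A)


@dataclass(frozen=True)
class ResponseMatrix:
    """All sensitivities ``R[alpha, (ij)] = d<x_alpha>/d ln k_ij``."""

    R: np.ndarray
    frame: TreeCycleFrame
    steady: SteadyState
    Ainv: JacobianInverse
    k: np.ndarray               # rates in directed-edge order, as analysed

    def d_dlnk(self, obs: ObservableCoefficients) -> np.ndarray:
        return obs.weights @ self.R

    def d_dk(self, obs: ObservableCoefficients) -> np.ndarray:
        return self.d_dlnk(obs) / self.k

    def dpi_dlnk(self) -> np.ndarray:
        """``d pi_n / d ln k_ij`` for every state n (V x 2E).

        Non-reference rows come straight from the dwell block; the
        reference row follows from normalisation ``sum_n pi_n = 1``.
        """
        V = self.frame.net.n_states
        E = self.frame.n_edges
        out = np.zeros((V, self.frame.n_basis))
        ref_i = self.frame.net.states.index(self.frame.reference)
        nonref = [self.frame.net.states.index(s) for s in self.frame.nonref_nodes]
        out[nonref, :] = self.R[E : E + V - 1, :]
        out[ref_i, :] = -out[nonref, :].sum(axis=0)
        return out


def response_matrix(
    net: RateNetwork,
    frame: TreeCycleFrame,
    steady: SteadyState | None = None,
    jac: JacobianA | None = None,
) -> ResponseMatrix:
    """Exact response of every basis observable to every log-rate (RIM)."""
    ss = steady if steady is not None else steady_observables(net, frame)
    inv = invert_jacobian(jac if jac is not None else build_jacobian(net, frame))
    R = inv.full() * ss.p[np.newaxis, :]
    return ResponseMatrix(R, frame, ss, inv, frame.rate_vector(net))


def observable_gradient(
    net: RateNetwork,
    frame: TreeCycleFrame,
    obs: ObservableCoefficients,
    resp: ResponseMatrix | None = None,
) -> dict[str, np.ndarray]:
    """Gradient of a mean observable with respect to every rate.

    Returns ``{"d_dlnk": ..., "d_dk": ...}`` over directed-edge index order.
    """
    if obs.frame.n_basis != frame.n_basis:
        raise ValueError("observable built on an incompatible frame")
    r = resp if resp is not None else response_matrix(net, frame)
    d_dlnk = r.d_dlnk(obs)
    return {"d_dlnk": d_dlnk, "d_dk": d_dlnk / r.k}


def energy_barrier_responses(
    net: RateNetwork,
    frame: TreeCycleFrame,
    obs: ObservableCoefficients,
    resp: ResponseMatrix | None = None,
) -> dict[str, np.ndarray]:
    """Responses to Arrhenius site-energy and barrier-height perturbations.

    In an Arrhenius parameterisation ``k_nj ~ exp(E_n)`` and
    ``k_ij, k_ji ~ exp(-B_ij)``, raising the site energy ``E_n`` scales all
    rates out of ``n`` jointly, and raising the barrier ``B_ij`` lowers both
    rates across the edge jointly:

        d<x>/dE_n  =  sum_j k_nj d<x>/dk_nj
        d<x>/dB_ij = -k_ij d<x>/dk_ij - k_ji d<x>/dk_ji

    Returns per-node (state order) and per-undirected-edge arrays.
    """
    grad = observable_gradient(net, frame, obs, resp)["d_dlnk"]  # k*d/dk per edge
    V = net.n_states
    src = frame.source_state_index()
    dE = np.zeros(V)
    np.add.at(dE, src, grad)
    dB = -(grad[0::2] + grad[1::2])
    return {"dE": dE, "dB": dB}
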