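"""Asymptotic covariances of counting observables and the randomness parameter.

Each transition ``i -> j`` carries an independent noise source
``lambda_ij = (N_ij - k_ij T_i)/t`` whose scaled covariance is diagonal,
``t Cov(lambda_ij, lambda_mn) -> pi_i k_ij delta``.  Since the basis
observables span these sources linearly through the Jacobian ``A``, the
scaled covariance of any two observables is the inner product of their
projections onto the unit-variance noise axes:

    D = A^{-1} diag(pi_i k_ij) A^{-T},   D_ab = lim t Cov(x_a, x_b).

The randomness parameter ``r`` of a flux observable (its long-time Fano
factor, variance-to-mean ratio) then decomposes exactly into non-negative
per-transition sensitivity contributions
``(1/<psi>) (k_ij/pi_i) (d<psi>/dk_ij)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ObservableCoefficients, RateNetwork, TreeCycleFrame
from .response import ResponseMatrix, response_matrix


class StalledFluxError(ValueError):
    """The flux observable has zero mean: the randomness parameter is undefined."""


@dataclass(frozen=True)
class CovarianceMatrix:
    """Scaled asymptotic covariances ``D[a, b] = lim t Cov(x_a, x_b)``."""

    D: np.ndarray
    frame: TreeCycleFrame

    def of(self, obs: ObservableCoefficients, obs2: ObservableCoefficients | None = None) -> float:
        w2 = obs.weights if obs2 is None else obs2.weights
        return float(obs.weights @ self.D @ w2)


def covariance_matrix(
    net: RateNetwork,
    frame: TreeCycleFrame,
    resp: ResponseMatrix | None = None,
) -> CovarianceMatrix:
    r = resp if resp is not None else response_matrix(net, frame)
    Ainv = r.Ainv.full()
    D = (Ainv * r.steady.p[np.newaxis, :]) @ Ainv.T
    return CovarianceMatrix(D, frame)


def noise_projections(
    net: RateNetwork,
    frame: TreeCycleFrame,
    obs: ObservableCoefficients,
    resp: ResponseMatrix | None = None,
) -> np.ndarray:
    """Projection of an observable onto each unit-variance noise source.

    Entry ``(ij)`` is ``sqrt(pi_i k_ij) [A^{-T} w]_(ij)``; the squared
    entries sum to the observable's scaled variance rate.
    """
    r = resp if resp is not None else response_matrix(net, frame)
    u = r.Ainv.solve_T(obs.weights)
    return np.sqrt(r.steady.p) * u


def randomness_parameter(
    net: RateNetwork,
    frame: TreeCycleFrame,
    flux_obs: ObservableCoefficients,
    resp: ResponseMatrix | None = None,
    mean_tol: float = 1e-12,
) -> float:
    """Long-time Fano factor ``r = lim t Var(psi)/<psi>`` of a flux.

    The flux is oriented so that its mean is positive; ``r`` is reported
    positive.  Raises :class:`StalledFluxError` when the mean flux vanishes.
    """
    r = resp if resp is not None else response_matrix(net, frame)
    mean = r.steady.evaluate(flux_obs)
    if abs(mean) <= mean_tol:
        raise StalledFluxError(f"stalled flux: <psi> = {mean:g}")
    var = covariance_matrix(net, frame, r).of(flux_obs)
    return float(var / abs(mean))


@dataclass(frozen=True)
class DecompositionReport:
    """Per-transition decomposition of the randomness parameter."""

    frame: TreeCycleFrame
    contributions: np.ndarray          # per directed edge, >= 0
    mean_flux: float
    total: float
    group_sums: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        dedges = self.frame.directed_edges
        groups = [self.frame.net.edge_group(i, j) for (i, j) in dedges]
        return pd.DataFrame(
            {
                "source": [i for i, _ in dedges],
                "target": [j for _, j in dedges],
                "group": groups,
                "contribution": self.contributions,
            }
        )


def randomness_decomposition(
    net: RateNetwork,
    frame: TreeCycleFrame,
    flux_obs: ObservableCoefficients,
    groups: list[str] | None = None,
    resp: ResponseMatrix | None = None,
) -> DecompositionReport:
    """Split ``r`` into per-transition sensitivity contributions.

    Contribution of transition ``i -> j``:
    ``(1/<psi>) (k_ij/pi_i) (d<psi>/dk_ij)^2 >= 0``; the contributions sum
    to ``r`` exactly (to rounding).  ``groups`` optionally restricts the
    group summary to the listed metadata labels.
    """
    r = resp if resp is not None else response_matrix(net, frame)
    mean = r.steady.evaluate(flux_obs)
    if abs(mean) <= 1e-12:
        raise StalledFluxError(f"stalled flux: <psi> = {mean:g}")
    proj = noise_projections(net, frame, flux_obs, r)
    contrib = proj**2 / abs(mean)
    dedges = frame.directed_edges
    labels = [net.edge_group(i, j) for (i, j) in dedges]
    valid = sorted({g for g in labels if g is not None})
    if groups is not None:
        unknown = [g for g in groups if g not in valid]
        if unknown:
            raise ValueError(f"unknown group label(s) {unknown}; valid labels: {valid}")
        wanted = list(groups)
    else:
        wanted = valid
    group_sums = {
        g: float(sum(c for c, lab in zip(contrib, labels) if lab == g)) for g in wanted
    }
    return DecompositionReport(frame, contrib, float(mean), float(contrib.sum()), group_sums)
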