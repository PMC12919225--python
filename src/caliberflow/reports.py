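"""Machine-readable run reports and the end-to-end audit pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .audits import BoundViolationError, bound_hierarchy_check, symmetry_residuals
from .fluctuations import covariance_matrix
from .network import RateNetwork, build_frame, network_to_dict, read_network
from .oracles import counting_weights, ensemble_statistics, tilted_cumulants
from .response import response_matrix
from .steady import steady_observables

# Exit-code contract: 0 pass, 1 validation error, 2 numerical failure, 3 audit violation.
EXIT_OK, EXIT_VALIDATION, EXIT_NUMERICAL, EXIT_AUDIT = 0, 1, 2, 3


@dataclass
class Tolerances:
    """Central pass/fail thresholds, echoed into every report."""

    linear_solve: float = 1e-12
    audit: float = 1e-8
    oracle_relative: float = 1e-6
    sampling_sigmas: float = 3.0


@dataclass
class RunReport:
    tool_version: str
    input_digest: str
    frame_summary: dict
    requested: list[str]
    results: dict
    residuals: dict
    passed: dict
    tolerances: dict
    wall_time_s: float
    seed_registry: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def ok(self) -> bool:
        return all(self.passed.values())


def _digest(net: RateNetwork) -> str:
    blob = json.dumps(network_to_dict(net), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_full_audit(
    net_or_path,
    seed: int = 0,
    deep: bool = False,
    tolerances: Tolerances | None = None,
) -> RunReport:
    """Steady state + response + covariance + symmetry/bound audits.

    Always cross-checks the covariance of one jump-representable observable
    against the spectral oracle; ``deep=True`` adds a Gillespie sampling
    check.  Raises the stage's own exception type on hard failures so the
    CLI can map it to the exit-code contract.
    """
    tol = tolerances or Tolerances()
    t0 = time.perf_counter()
    net = net_or_path if isinstance(net_or_path, RateNetwork) else read_network(net_or_path)
    frame = build_frame(net)
    ss = steady_observables(net, frame)
    resp = response_matrix(net, frame, steady=ss)
    D = covariance_matrix(net, frame, resp)

    results: dict = {
        "pi": dict(zip(net.states, ss.pi.tolist())),
        "caliber_rate": ss.caliber_rate,
        "J_cycle": ss.J_cycle.tolist(),
    }
    residuals: dict = {}
    passed: dict = {}

    sym = symmetry_residuals(net, frame, resp)
    residuals["symmetry_max_abs"] = sym.max_abs
    passed["symmetry"] = sym.max_abs <= tol.audit

    try:
        bound_hierarchy_check(net, frame, resp)
        passed["bound_hierarchy"] = True
        residuals["bound_hierarchy"] = 0.0
    except BoundViolationError as exc:
        passed["bound_hierarchy"] = False
        residuals["bound_hierarchy"] = str(exc)

    # spectral cross-check on one traffic observable
    from .network import traffic_observable

    a, b = frame.undirected[0]
    obs = traffic_observable(frame, a, b)
    mean_s, var_s = tilted_cumulants(net, counting_weights(frame, obs))
    mean_a = ss.evaluate(obs)
    var_a = D.of(obs)
    rel = max(abs(mean_s - mean_a) / max(abs(mean_a), 1e-300),
              abs(var_s - var_a) / max(abs(var_a), 1e-300))
    residuals["spectral_relative"] = rel
    passed["spectral_oracle"] = rel <= 10 * tol.oracle_relative
    results["traffic_check"] = {"edge": f"{a}-{b}", "mean": mean_a, "variance_rate": var_a}

    if deep:
        es = ensemble_statistics(net, frame, t=500.0, n_traj=200, seed=seed)
        dev = np.abs(es.cov_x - D.D)
        ok = dev <= tol.sampling_sigmas * np.maximum(es.cov_x_se, 1e-12)
        passed["sampling_oracle"] = bool(ok.mean() >= 0.90)
        residuals["sampling_within_3se_fraction"] = float(ok.mean())

    return RunReport(
        tool_version=__version__,
        input_digest=_digest(net),
        frame_summary={
            "states": net.n_states,
            "edges": net.n_edges,
            "cycles": frame.n_cycles,
            "reference": frame.reference,
        },
        requested=["steady", "response", "covariance", "symmetry", "bounds", "spectral"]
        + (["sampling"] if deep else []),
        results=results,
        residuals=residuals,
        passed=passed,
        tolerances=dataclasses.asdict(tol),
        wall_time_s=time.perf_counter() - t0,
        seed_registry={"audit_seed": int(seed)},
    )


def render_report(report: RunReport, format: str = "json") -> str:
    """Serialize a report: lossless JSON, flattened TSV, or human text."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=1, default=_jsonable)
    if format == "tsv":
        buf = io.StringIO()
        buf.write("key\tvalue\n")
        for key, val in _flatten(report.to_dict()):
            buf.write(f"{key}\t{val}\n")
        return buf.getvalue()
    if format == "text":
        lines = [f"caliberflow {report.tool_version}  input {report.input_digest}"]
        fs = report.frame_summary
        lines.append(f"network: {fs['states']} states, {fs['edges']} edges, "
                     f"{fs['cycles']} cycles, reference {fs['reference']}")
        for fam, ok in report.passed.items():
            lines.append(f"{'PASS' if ok else 'FAIL'}  {fam}")
        lines.append(f"max symmetry residual: {report.residuals.get('symmetry_max_abs'):.3g}")
        lines.append(f"wall time: {report.wall_time_s:.3f} s")
        return "\n".join(lines)
    raise ValueError(f"unknown format {format!r}")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _flatten(d, prefix=""):
    out = []
    if isinstance(d, dict):
        for k, v in d.items():
            out += _flatten(v, f"{prefix}{k}." if not prefix else f"{prefix}{k}.")
    elif isinstance(d, (list, tuple)):
        for n, v in enumerate(d):
            out += _flatten(v, f"{prefix}{n}.")
    else:
        out.append((prefix.rstrip("."), d))
    return out
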