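"""Rate networks, their I/O, and the spanning-tree / fundamental-cycle frame.

A rate network is an ergodic continuous-time Markov jump process: a set of
states with strictly positive directed transition rates in which every
transition is reversible (``k_ij > 0`` iff ``k_ji > 0``).  Rates are
dimensionless multiples of a unit-rate reference process, so a rate of 1
means "as fast as the reference".

The :class:`TreeCycleFrame` fixes the complete counting-observable basis
``X = (traffic per edge, dwell per non-reference node, net flux per
fundamental cycle)`` by choosing a reference node, a spanning tree and a
canonical ordering of chords.  All downstream linear algebra (forces,
Jacobian, responses, covariances) is expressed in this basis; physical
outputs are invariant to the choice.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

JSON_SCHEMA_ID = "caliberflow-net-1"


class NetworkError(ValueError):
    """Base class for rate-network validation failures."""


class IrreversibleEdgeError(NetworkError):
    pass


class NonPositiveRateError(NetworkError):
    pass


class NotErgodicError(NetworkError):
    pass


@dataclass(frozen=True)
class RateNetwork:
    """States plus positive, reversible directed transition rates.

    Parameters
    ----------
    states
        Ordered state labels.  Order is part of the object's identity: it
        fixes canonical edge orientations and every index map downstream.
    rates
        Mapping ``(i, j) -> k_ij`` over ordered label pairs, units of the
        reference rate (inverse time).
    metadata
        Optional free-form annotations.  Recognised keys:
        ``mechanical_edge`` (a ``(source, target)`` pair), ``groups``
        (mapping ``"i-j"`` undirected edge keys to group labels),
        ``description``.
    """

    states: tuple[str, ...]
    rates: dict[tuple[str, str], float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        object.__setattr__(
            self, "rates", {(str(a), str(b)): float(k) for (a, b), k in self.rates.items()}
        )
        if len(set(self.states)) != len(self.states):
            raise NetworkError("duplicate state labels")
        idx = {s: n for n, s in enumerate(self.states)}
        for (a, b), k in self.rates.items():
            if a not in idx or b not in idx:
                raise NetworkError(f"rate on unknown state pair ({a},{b})")
            if a == b:
                raise NetworkError(f"self-loop on state {a}")
            if not (k > 0.0) or not math.isfinite(k):
                raise NonPositiveRateError(f"non-positive rate on edge ({a},{b}): {k}")
            if (b, a) not in self.rates:
                raise IrreversibleEdgeError(f"irreversible edge ({a},{b}): missing reverse rate")
        g = nx.Graph()
        g.add_nodes_from(self.states)
        g.add_edges_from(self.rates)
        if len(self.states) and not nx.is_connected(g):
            raise NotErgodicError("not ergodic: undirected support graph is disconnected")

    # -- convenience -----------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, s) -> int:
        return self.states.index(str(s))

    def undirected_edges(self) -> list[tuple[str, str]]:
        """Canonical undirected edges ``(i, j)`` with i before j in state order."""
        idx = {s: n for n, s in enumerate(self.states)}
        edges = {tuple(sorted(e, key=idx.__getitem__)) for e in self.rates}
        return sorted(edges, key=lambda e: (idx[e[0]], idx[e[1]]))

    @property
    def n_edges(self) -> int:
        return len(self.rates) // 2

    def neighbors(self, s: str) -> list[str]:
        """Neighbors of ``s`` in state-list order."""
        s = str(s)
        nbrs = {b for (a, b) in self.rates if a == s}
        return sorted(nbrs, key=self.states.index)

    def with_rates(self, rates: dict[tuple[str, str], float]) -> "RateNetwork":
        new = dict(self.rates)
        new.update({(str(a), str(b)): float(k) for (a, b), k in rates.items()})
        return RateNetwork(self.states, new, dict(self.metadata))

    def edge_group(self, i: str, j: str):
        groups = self.metadata.get("groups") or {}
        return groups.get(f"{i}-{j}") or groups.get(f"{j}-{i}")


def regularize(net: RateNetwork, epsilon: float) -> RateNetwork:
    """Add ``epsilon`` to missing/zero reverse rates, loudly.

    Forces diverge logarithmically at zero rates, so strictly irreversible
    input is rejected by :class:`RateNetwork`; this helper patches such data
    into an admissible network with an explicit warning.
    """
    rates = {(str(a), str(b)): float(k) for (a, b), k in net.rates.items()} if isinstance(net, RateNetwork) else dict(net)
    patched = []
    for (a, b) in list(rates):
        if (b, a) not in rates or rates.get((b, a), 0.0) <= 0.0:
            rates[(b, a)] = rates.get((b, a), 0.0) + epsilon
            patched.append((b, a))
    if patched:
        logger.warning("regularize: added epsilon=%g to %d reverse rates: %s", epsilon, len(patched), patched)
    states = net.states if isinstance(net, RateNetwork) else sorted({s for e in rates for s in e})
    meta = dict(net.metadata) if isinstance(net, RateNetwork) else {}
    return RateNetwork(tuple(states), rates, meta)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_network(path, format: str | None = None) -> RateNetwork:
    """Read a rate network from a JSON document or a TSV edge list.

    The JSON layout is the ``caliberflow-net-1`` schema; the TSV dialect has
    the header ``source<TAB>target<TAB>rate`` with one directed rate per
    row.  Invalid input is rejected, never repaired.
    """
    path = str(path)
    if format is None:
        format = "tsv" if path.endswith((".tsv", ".txt")) else "json"
    if format == "json":
        with open(path) as fh:
            doc = json.load(fh)
        return network_from_dict(doc)
    if format == "tsv":
        rates: dict[tuple[str, str], float] = {}
        states: list[str] = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if header[:3] != ["source", "target", "rate"]:
                raise NetworkError(f"bad TSV header: {header!r}")
            for line in fh:
                if not line.strip():
                    continue
                a, b, k = line.split("\t")
                for s in (a, b):
                    if s not in states:
                        states.append(s)
                rates[(a, b.strip() if False else b)] = float(k)
        rates = {(a.strip(), b.strip()): k for (a, b), k in rates.items()}
        return RateNetwork(tuple(states), rates)
    raise ValueError(f"unknown format {format!r}")


def network_from_dict(doc: dict) -> RateNetwork:
    if doc.get("schema") != JSON_SCHEMA_ID:
        raise NetworkError(f"unknown schema {doc.get('schema')!r}; expected {JSON_SCHEMA_ID!r}")
    states = tuple(str(s) for s in doc["states"])
    rates: dict[tuple[str, str], float] = {}
    groups: dict[str, str] = {}
    for e in doc["edges"]:
        a, b = str(e["source"]), str(e["target"])
        if (a, b) in rates or (b, a) in rates:
            raise NetworkError(f"parallel edge ({a},{b})")
        rates[(a, b)] = float(e["rate_fwd"])
        rates[(b, a)] = float(e["rate_rev"])
        if e.get("group"):
            groups[f"{a}-{b}"] = str(e["group"])
    meta: dict = {}
    if groups:
        meta["groups"] = groups
    if doc.get("reference_state") is not None:
        meta["reference_state"] = str(doc["reference_state"])
    if doc.get("mechanical_edge") is not None:
        meta["mechanical_edge"] = tuple(str(s) for s in doc["mechanical_edge"])
    if doc.get("description"):
        meta["description"] = doc["description"]
    return RateNetwork(states, rates, meta)


def network_to_dict(net: RateNetwork) -> dict:
    edges = []
    for (a, b) in net.undirected_edges():
        e = {
            "source": a,
            "target": b,
            "rate_fwd": net.rates[(a, b)],
            "rate_rev": net.rates[(b, a)],
        }
        grp = net.edge_group(a, b)
        if grp is not None:
            e["group"] = grp
        edges.append(e)
    doc = {"schema": JSON_SCHEMA_ID, "states": list(net.states), "edges": edges}
    for key in ("reference_state", "mechanical_edge", "description"):
        if key in net.metadata:
            val = net.metadata[key]
            doc[key] = list(val) if isinstance(val, tuple) else val
    return doc


def write_network(net: RateNetwork, path, format: str | None = None) -> None:
    """Write ``net`` so that :func:`read_network` round-trips rates bit-exactly."""
    path = str(path)
    if format is None:
        format = "tsv" if path.endswith((".tsv", ".txt")) else "json"
    if format == "json":
        doc = network_to_dict(net)
        with open(path, "w") as fh:
            # repr() of a float is its shortest exact decimal form
            json.dump(doc, fh, indent=1)
    elif format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\trate\n")
            idx = {s: n for n, s in enumerate(net.states)}
            for (a, b) in sorted(net.rates, key=lambda e: (idx[e[0]], idx[e[1]])):
                fh.write(f"{a}\t{b}\t{net.rates[(a, b)]!r}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkReport:
    n_states: int
    n_edges: int
    n_cycles: int
    connected: bool
    min_rate: float
    max_rate: float
    detailed_balance: bool


def validate_network(net: RateNetwork, affinity_tol: float = 1e-12) -> NetworkReport:
    """Report-only diagnostics: sizes, cycle count, detailed-balance flag.

    Detailed balance holds iff the affinity (log ratio of forward to reverse
    rate products) of every fundamental cycle vanishes.
    """
    frame = build_frame(net)
    db = True
    for cyc in frame.cycles:
        aff = sum(math.log(net.rates[d] / net.rates[d[::-1]]) for d in cyc)
        if abs(aff) > affinity_tol:
            db = False
            break
    rates = list(net.rates.values())
    return NetworkReport(
        n_states=net.n_states,
        n_edges=net.n_edges,
        n_cycles=net.n_edges - net.n_states + 1,
        connected=True,
        min_rate=min(rates),
        max_rate=max(rates),
        detailed_balance=db,
    )


# ---------------------------------------------------------------------------
# Tree/cycle frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeCycleFrame:
    """Deterministic observable-basis frame for a rate network.

    Basis order (length ``2E``): traffic per undirected edge, dwell per
    node other than the reference, net flux per fundamental cycle (one per
    chord).  Directed edges are indexed ``2e`` (canonical direction) and
    ``2e + 1`` (reverse) for the ``e``-th undirected edge.
    """

    net: RateNetwork
    reference: str
    tree_edges: tuple[tuple[str, str], ...]
    chords: tuple[tuple[str, str], ...]
    cycles: tuple[tuple[tuple[str, str], ...], ...]  # oriented directed-edge sequences

    def __post_init__(self):
        if self.reference not in self.net.states:
            raise NetworkError(f"reference node {self.reference!r} not in state list")

    # -- index maps ------------------------------------------------------
    @property
    def undirected(self) -> list[tuple[str, str]]:
        return self.net.undirected_edges()

    @property
    def n_edges(self) -> int:
        return self.net.n_edges

    @property
    def n_basis(self) -> int:
        return 2 * self.n_edges

    @property
    def n_cycles(self) -> int:
        return len(self.chords)

    @property
    def directed_edges(self) -> list[tuple[str, str]]:
        out = []
        for (a, b) in self.undirected:
            out.append((a, b))
            out.append((b, a))
        return out

    def directed_index(self, i, j) -> int:
        i, j = str(i), str(j)
        und = self.undirected
        idx = {s: n for n, s in enumerate(self.net.states)}
        a, b = sorted((i, j), key=idx.__getitem__)
        e = und.index((a, b))
        return 2 * e if (i, j) == (a, b) else 2 * e + 1

    def traffic_index(self, i, j) -> int:
        return self.directed_index(i, j) // 2

    @property
    def nonref_nodes(self) -> list[str]:
        return [s for s in self.net.states if s != self.reference]

    def dwell_index(self, n) -> int:
        return self.n_edges + self.nonref_nodes.index(str(n))

    def cycle_index(self, c: int) -> int:
        if not 0 <= c < self.n_cycles:
            raise IndexError(f"cycle {c} out of range (have {self.n_cycles})")
        return self.n_edges + (self.net.n_states - 1) + c

    def basis_labels(self) -> list[str]:
        labels = [f"traffic:{a}-{b}" for (a, b) in self.undirected]
        labels += [f"dwell:{n}" for n in self.nonref_nodes]
        labels += [f"cycle:{c}" for c in range(self.n_cycles)]
        return labels

    # -- cycle incidence -------------------------------------------------
    def cycle_signs(self) -> np.ndarray:
        """Signed incidence ``S[c, d]`` of cycle ``c`` on directed edge ``d``.

        +1 if the cycle traverses ``d`` forward, -1 if it traverses the
        reverse of ``d``, 0 otherwise.  Each fundamental cycle is simple, so
        entries are in {-1, 0, +1}.
        """
        S = np.zeros((self.n_cycles, self.n_basis))
        for c, cyc in enumerate(self.cycles):
            for (i, j) in cyc:
                S[c, self.directed_index(i, j)] += 1.0
                S[c, self.directed_index(j, i)] -= 1.0
        return S

    def source_state_index(self) -> np.ndarray:
        """State index of the source node of each directed edge."""
        sidx = {s: n for n, s in enumerate(self.net.states)}
        return np.array([sidx[i] for (i, j) in self.directed_edges], dtype=int)

    def target_state_index(self) -> np.ndarray:
        sidx = {s: n for n, s in enumerate(self.net.states)}
        return np.array([sidx[j] for (i, j) in self.directed_edges], dtype=int)

    def rate_vector(self, net: "RateNetwork | None" = None) -> np.ndarray:
        """Rates ``k_ij`` in directed-edge index order.

        Pass ``net`` to index a perturbed network sharing this topology;
        defaults to the frame's own network.
        """
        rates = (net or self.net).rates
        return np.array([rates[d] for d in self.directed_edges])


@dataclass(frozen=True)
class ObservableCoefficients:
    """A linear counting observable: weights over the 2E-dimensional basis."""

    weights: np.ndarray
    frame: TreeCycleFrame
    label: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.frame.n_basis,):
            raise ValueError(f"weights shape {w.shape} != ({self.frame.n_basis},)")
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite observable weights")
        object.__setattr__(self, "weights", w)


def traffic_observable(frame: TreeCycleFrame, i, j) -> ObservableCoefficients:
    w = np.zeros(frame.n_basis)
    w[frame.traffic_index(i, j)] = 1.0
    return ObservableCoefficients(w, frame, label=f"traffic:{i}-{j}")


def dwell_observable(frame: TreeCycleFrame, n) -> ObservableCoefficients:
    w = np.zeros(frame.n_basis)
    w[frame.dwell_index(n)] = 1.0
    return ObservableCoefficients(w, frame, label=f"dwell:{n}")


def cycle_observable(frame: TreeCycleFrame, c: int) -> ObservableCoefficients:
    w = np.zeros(frame.n_basis)
    w[frame.cycle_index(c)] = 1.0
    return ObservableCoefficients(w, frame, label=f"cycle:{c}")


def build_frame(
    net: RateNetwork,
    reference_node: str | None = None,
    tree_strategy: str = "bfs",
) -> TreeCycleFrame:
    """Build the deterministic spanning-tree / fundamental-cycle frame.

    The tree is grown breadth-first from the reference node with neighbors
    visited in state-list order; remaining edges are chords, each closing
    exactly one fundamental cycle.  The cycle's oriented edge list starts
    with the chord's canonical direction and returns through the tree.
    """
    ref = str(reference_node) if reference_node is not None else net.metadata.get("reference_state", net.states[0])
    if ref not in net.states:
        raise NetworkError(f"reference node {ref!r} not in state list")
    if tree_strategy != "bfs":
        raise ValueError(f"unknown tree strategy {tree_strategy!r}")

    # BFS with deterministic neighbor order
    parent: dict[str, str] = {}
    seen = {ref}
    queue = [ref]
    while queue:
        u = queue.pop(0)
        for v in net.neighbors(u):
            if v not in seen:
                seen.add(v)
                parent[v] = u
                queue.append(v)

    idx = {s: n for n, s in enumerate(net.states)}
    canon = lambda i, j: tuple(sorted((i, j), key=idx.__getitem__))
    tree = {canon(v, p) for v, p in parent.items()}
    und = net.undirected_edges()
    tree_edges = tuple(e for e in und if e in tree)
    chords = tuple(e for e in und if e not in tree)

    # tree path from any node back to the reference, as node list
    def path_to_ref(u: str) -> list[str]:
        out = [u]
        while out[-1] != ref:
            out.append(parent[out[-1]])
        return out

    cycles = []
    for (a, b) in chords:
        pa, pb = path_to_ref(a), path_to_ref(b)
        # splice at lowest common ancestor
        sa, sb = set(pa), set(pb)
        lca = next(u for u in pb if u in sa)
        walk_b = pb[: pb.index(lca) + 1]          # b ... lca
        walk_a = pa[: pa.index(lca) + 1][::-1]    # lca ... a
        walk = [a, b] + walk_b[1:] + walk_a[1:]   # a -> b -> ... -> lca -> ... -> a
        assert walk[0] == a and walk[-1] == a
        cyc = tuple((walk[t], walk[t + 1]) for t in range(len(walk) - 1))
        cycles.append(cyc)

    return TreeCycleFrame(net, ref, tree_edges, chords, tuple(cycles))
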