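"""Fixture network generators: random ergodic ensembles, a 6-state
kinesin-like motor topology, and the Θ-shaped substep benchmark family.

The kinesin-like network is the standard chemomechanical picture: a ring
of six chemical states plus one mechanical transition bridging states 2
and 5, so the graph has two fundamental cycles (a forward and a backward
chemomechanical cycle sharing the mechanical edge).  The default rate
table is ILLUSTRATIVE ONLY — a plausible placeholder with chemical rates
an order of magnitude faster than the mechanical step — and is meant to be
replaced by user-supplied fitted constants for any quantitative motor
claim.

The Θ family generalizes the single mechanical hop into a biased random
walk over ``N`` substeps, mimicking a diffusive swing; it grows the state
space linearly while keeping exactly two fundamental cycles, which makes
it a clean scaling benchmark for gradient evaluation.
"""

from __future__ import annotations

import numpy as np

from .network import RateNetwork

# Illustrative placeholder rates (multiples of the reference rate); NOT a
# fitted kinesin parameter set.  Forward chemistry fast, backward slow,
# mechanical step slower than chemistry and strongly forward-biased.
DEFAULT_KINESIN_RATES: dict[tuple[str, str], float] = {
    ("1", "2"): 120.0, ("2", "1"): 6.0,     # ATP binding / release
    ("2", "3"): 90.0,  ("3", "2"): 4.0,     # hydrolysis (forward branch)
    ("3", "4"): 75.0,  ("4", "3"): 5.0,
    ("4", "5"): 110.0, ("5", "4"): 8.0,
    ("5", "6"): 95.0,  ("6", "5"): 3.0,     # product release (backward branch)
    ("6", "1"): 85.0,  ("1", "6"): 4.0,
    ("2", "5"): 12.0,  ("5", "2"): 0.5,     # mechanical step (chord)
}

# canonical undirected keys (lower state index first)
KINESIN_GROUPS = {
    "1-2": "chemical_F", "2-3": "chemical_B", "3-4": "chemical_B",
    "4-5": "chemical_B", "5-6": "chemical_F", "1-6": "chemical_F",
    "2-5": "mechanical",
}


def random_ergodic_network(
    V: int,
    E: int,
    seed: int,
    rate_bounds: tuple[float, float] = (0.1, 10.0),
) -> RateNetwork:
    """Random connected reversible network: spanning tree plus extra edges.

    Both directed rates of every edge are drawn log-uniformly from
    ``rate_bounds``.  Fully determined by ``seed`` (integer-indexed draws
    only, no set-iteration order dependence).
    """
    if V < 2:
        raise ValueError("need at least 2 states")
    max_E = V * (V - 1) // 2
    if not (V - 1 <= E <= max_E):
        raise ValueError(f"E={E} out of range [{V - 1}, {max_E}] for V={V}")
    rng = np.random.default_rng(seed)
    states = tuple(str(n + 1) for n in range(V))
    # random spanning tree by uniform attachment over a random node order
    order = rng.permutation(V)
    edges: list[tuple[int, int]] = []
    for pos in range(1, V):
        anchor = order[rng.integers(0, pos)]
        edges.append(tuple(sorted((int(order[pos]), int(anchor)))))
    pool = sorted(
        (a, b) for a in range(V) for b in range(a + 1, V) if (a, b) not in set(edges)
    )
    extra = rng.choice(len(pool), size=E - (V - 1), replace=False) if E > V - 1 else []
    edges += [pool[int(i)] for i in np.sort(extra)]
    lo, hi = np.log(rate_bounds[0]), np.log(rate_bounds[1])
    rates: dict[tuple[str, str], float] = {}
    for (a, b) in edges:
        rates[(states[a], states[b])] = float(np.exp(rng.uniform(lo, hi)))
        rates[(states[b], states[a])] = float(np.exp(rng.uniform(lo, hi)))
    return RateNetwork(states, rates)


def detailed_balance_network(
    V: int,
    E: int,
    seed: int,
    rate_bounds: tuple[float, float] = (0.1, 10.0),
) -> RateNetwork:
    """Random network satisfying detailed balance (all cycle affinities zero).

    Built from random node potentials and symmetric edge conductances:
    ``k_ij = g_ij exp((u_i - u_j)/2)``, so every cycle's log rate-ratio sum
    telescopes to zero.
    """
    base = random_ergodic_network(V, E, seed, rate_bounds)
    rng = np.random.default_rng(seed + 2**20)
    u = rng.uniform(-1.0, 1.0, size=V)
    sidx = {s: n for n, s in enumerate(base.states)}
    rates = {}
    for (a, b) in base.undirected_edges():
        g = np.sqrt(base.rates[(a, b)] * base.rates[(b, a)])
        rates[(a, b)] = float(g * np.exp((u[sidx[a]] - u[sidx[b]]) / 2))
        rates[(b, a)] = float(g * np.exp((u[sidx[b]] - u[sidx[a]]) / 2))
    return RateNetwork(base.states, rates)


def uniform_ring(N: int, forward: float = 1.0, backward: float = 1e-6) -> RateNetwork:
    """N-state unidirectionally biased ring (renewal-limit fixture).

    With ``backward -> 0`` the cycle time is a sum of N exponentials, so
    the flux randomness parameter approaches ``1/N``.
    """
    if N < 3:
        raise ValueError("ring needs at least 3 states")
    states = tuple(str(n + 1) for n in range(N))
    rates = {}
    for n in range(N):
        a, b = states[n], states[(n + 1) % N]
        rates[(a, b)] = float(forward)
        rates[(b, a)] = float(backward)
    return RateNetwork(states, rates)


def kinesin6(rates: dict | None = None) -> RateNetwork:
    """6-state kinesin-like ring with mechanical chord 2-5.

    ``rates`` may replace the illustrative default table; it must cover all
    14 directed transitions of the topology.
    """
    table = DEFAULT_KINESIN_RATES if rates is None else {
        (str(a), str(b)): float(k) for (a, b), k in rates.items()
    }
    if set(table) != set(DEFAULT_KINESIN_RATES):
        raise ValueError(
            "rate table must cover exactly the 14 directed transitions of the "
            "6-state ring plus the 2-5 chord"
        )
    # Reference state 4 makes the mechanical edge 2-5 a chord of the BFS
    # spanning tree, so the mechanical stepping flux is itself a cycle-basis
    # coordinate — the natural frame for the randomness decomposition.
    meta = {
        "mechanical_edge": ("2", "5"),
        "reference_state": "4",
        "groups": dict(KINESIN_GROUPS),
        "description": "6-state kinesin-like fixture; default rates are "
                       "illustrative placeholders, not fitted constants",
    }
    return RateNetwork(tuple(str(n + 1) for n in range(6)), table, meta)


def theta_motor_network(
    N: int,
    backbone_rates: dict | None = None,
    substep_fwd: float | None = None,
    substep_rev: float | None = None,
) -> RateNetwork:
    """Θ-shaped benchmark: kinesin backbone with an N-substep mechanical arm.

    The mechanical edge 2-5 is replaced by a chain of ``N`` hops through
    ``N - 1`` inserted states.  Defaults keep the arm's total force: each
    hop runs at ``N`` times the single-hop forward rate with the per-hop
    log rate ratio equal to ``(1/N)`` of the original, so ``N = 1``
    reduces exactly to :func:`kinesin6`.  The cycle count stays 2 for all N.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    base = kinesin6(backbone_rates)
    k_f, k_r = base.rates[("2", "5")], base.rates[("5", "2")]
    if substep_fwd is None:
        substep_fwd = N * k_f
    if substep_rev is None:
        substep_rev = substep_fwd * (k_r / k_f) ** (1.0 / N)
    if substep_fwd <= 0 or substep_rev <= 0:
        raise ValueError("substep rates must be positive")
    if N == 1:
        return base
    rates = {d: k for d, k in base.rates.items() if d not in {("2", "5"), ("5", "2")}}
    subs = [f"s{n}" for n in range(1, N)]
    chain = ["2"] + subs + ["5"]
    for a, b in zip(chain[:-1], chain[1:]):
        rates[(a, b)] = float(substep_fwd)
        rates[(b, a)] = float(substep_rev)
    groups = dict(KINESIN_GROUPS)
    del groups["2-5"]
    for a, b in zip(chain[:-1], chain[1:]):
        groups[f"{a}-{b}"] = "mechanical"
    states = tuple(str(n + 1) for n in range(6)) + tuple(subs)
    meta = {
        "mechanical_edge": ("2", subs[0]),
        "reference_state": "4",
        "groups": groups,
        "description": f"Theta benchmark, N={N} mechanical substeps "
                       "(illustrative backbone rates)",
    }
    return RateNetwork(states, rates, meta)
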