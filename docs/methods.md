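# Methods

## Model and scope

`caliberflow` analyses ergodic, time-homogeneous Markov jump processes on
finite networks in which every transition is reversible (`k_ij > 0` iff
`k_ji > 0`), there are no self-loops or parallel edges, and the undirected
support graph is connected.  Rates are dimensionless multiples of a
unit-rate reference process, so `k = 1` everywhere is the reference
itself.  Time-inhomogeneous rates, absorbing states and continuous state
spaces are out of scope; inputs violating the invariants are rejected,
never repaired (an explicit `regularize(net, epsilon)` helper exists for
patching zero reverse rates, and it warns loudly).

## The observable frame

All second-order statistics live in a `2E`-dimensional counting basis
fixed by a `TreeCycleFrame`: traffic per undirected edge, dwell per
non-reference node, and net flux per fundamental cycle (one per chord of a
spanning tree).  The frame is a *convention*, chosen deterministically —
undirected edges oriented by state-list order, breadth-first spanning tree
from the reference with neighbors visited in state-list order — so that
identical inputs always produce identical index maps.  Physical outputs
(π, τ, edge fluxes, responses and covariances of physical observables) are
invariant to the convention; the test suite rebuilds frames with different
reference nodes and compares results at 1e-10.

The default reference node is the first listed state.  A network's
metadata may override it: the bundled kinesin fixture sets the reference
to state 4 so that the mechanical edge 2–5 becomes a chord, which makes
the mechanical stepping flux itself a cycle-basis coordinate — the natural
frame for decomposing motor randomness.

## Forces, caliber, and the reference process

The path entropy (log likelihood ratio of the process against the
unit-rate reference on the same support) is asymptotically `F·X − c t`.
The edge force is the *symmetric* combination `½ ln(k_ij k_ji)`, conjugate
to traffic; antisymmetric log-ratios appear only inside cycle affinities.
This split follows from writing each jump count as half traffic plus half
net flux.  The excess escape rate is `ε_i = Σ_j (k_ij − 1)` over
neighbors — the reference contributes one unit of escape rate per
neighbor — and only this reading makes the raw-count and caliber forms of
the path entropy agree on simulated trajectories (they then differ by a
boundary term bounded by a constant over `t`, exactly zero on closed
paths).  The node force is `ε_m − ε_n` (reference minus node), consistent
with `c = ε_m`; the sign is validated numerically by the node response
symmetry.

The force map `ln k → F` is inverted by a damped Newton iteration whose
Jacobian is `Aᵀ` (one sparse solve per step, backtracking line search,
default tolerance 1e-12 on `max|ΔF|`).  Round-trips recover rates to
1e-8 across random networks; non-convergence raises with the residual.

## Responses, covariances, gradients

The Jacobian `A` is assembled exactly from its three blocks (constants
±½ in the edge and cycle columns; `k_ij(δ_{i,m} − δ_{i,n})` in the node
columns) and factorized once.  Up to `2E = 500` the dense inverse is
formed (`scipy.linalg.inv`) — the regime of all bundled benchmarks —
and beyond that a sparse LU (`splu`) serves rows of `A⁻¹` on demand via
transposed solves.  A singular or non-finite-conditioned Jacobian raises.

The stationary distribution solves the balance system with one row
replaced by normalisation (dense LU below 200 states, sparse above);
residual global balance beyond tolerance or non-positive probabilities
raise a degenerate-network error rather than returning a repaired vector.

Covariances use `D = A⁻¹ diag(p) A⁻ᵀ` with `p_ij = π_i k_ij`.  Gradients
of variances reuse the same factorization: the rate-dependence of `A` is
confined to single rows, so `∂A⁻¹ = −A⁻¹(∂A)A⁻¹` reduces to two
matrix-vector products per target, and the gradient of `diag(p)` comes
from the response matrix itself (π is a basis observable; the reference
row follows from normalisation).  Everything is computed in `ln k`
internally and converted on output.

## Numerical choices

* Spectral oracle (tilted generator): cumulants come from
  Richardson-extrapolated central differences of the dominant eigenvalue,
  default tilt step 1e-3.  The step balances the O(step⁴) truncation of
  the extrapolated stencil against eigenvalue roundoff `~ε‖L‖` amplified
  by `1/step²`; with fast rates (hundreds, as in the motor fixtures) a
  smaller step makes the oracle *less* accurate.
* Brute-force gradient baseline (finite differences over spectral
  cumulants): default rate step 3e-3 and tilt step 3e-2, coarse for the
  same amplification reason.  Its agreement with the analytic gradient is
  checked at 1e-4 relative; the analytic route itself is held to 1e-5
  against finite differences of the steady-state recomputation, which is
  far better conditioned.
* Finite-difference responses perturb `k → k·e^{±h}` (exact in `ln k`),
  default `h = 1e-6`.
* Bound-hierarchy assertions use tolerance 1e-10 scaled by the largest
  one-way flux; symmetry residuals use 1e-8.

## Saturation of the causality bound

The middle inequality of the kinetic hierarchy,
`∂p_ij/∂k_ij ≥ ∂p_ji/∂k_ij`, saturates exactly on *bridge* edges — edges
whose net flux is identically zero however the rate is perturbed (any
edge of a 2-state network, any pendant edge).  An edge whose flux is only
instantaneously zero, such as a cycle edge of a detailed-balance network,
does **not** saturate it: the perturbation itself drives a current, so
`∂J_ij/∂k_ij > 0` there.  Both behaviours are confirmed against central
finite differences and asserted in the tests.  `bound_hierarchy_check`
therefore flags saturation from the gap itself, not from the unperturbed
flux.

## Synthetic data and fixtures

* `random_ergodic_network(V, E, seed, rate_bounds=(0.1, 10))`: random
  spanning tree by uniform attachment over a shuffled node order, plus
  uniformly chosen extra edges; both directed rates log-uniform.  The
  log-uniform band spans two decades, wide enough to produce strongly
  driven and nearly balanced edges in the same graph; ensembles are
  seeded and integer-indexed, so they are reproducible across platforms.
* `detailed_balance_network`: node potentials plus symmetric
  conductances, so every cycle affinity telescopes to zero.
* `uniform_ring(N, forward=1, backward=1e-6)`: the renewal-limit fixture;
  with vanishing backward rates the cycle time is a sum of N exponentials
  and the flux Fano factor approaches 1/N.
* `kinesin6()`: the 6-state chemomechanical ring with mechanical chord
  2–5 and edge→group metadata.  The default rate table is an
  **illustrative placeholder** (forward chemistry ~100, backward ~5,
  mechanical step 12 vs 0.5) chosen only to give an order-of-magnitude
  separation between chemistry and stepping and a strongly forward-driven
  cycle; no quantitative claim about real kinesin follows from it, and
  users supply fitted constants via `kinesin6(rates=...)`.
* `theta_motor_network(N)`: replaces the mechanical hop by a biased
  N-step walk.  Substep defaults preserve the arm's total thermodynamic
  force — each hop runs at `N×` the single-hop forward rate with `1/N` of
  the log rate ratio — so `N = 1` reduces exactly to `kinesin6()` and the
  cycle count stays 2 for all N.  The family exists to scale the state
  space linearly for benchmarking, not to model stepping mechanics.

What the generators do *not* emulate: experimental noise floors,
state-lumping or hidden states, load- or concentration-dependent rate
laws, and non-exponential dwell times.  Passing tests therefore certify
the engine's internal mathematics and its agreement with independent
oracles on networks of this class — not the fidelity of any particular
biological parameterisation.

## Simulation oracle

The Gillespie sampler is an exact-jump implementation with per-state
cumulative jump tables; the final dwell is truncated so dwell times sum
to `t` exactly, and the initial state is drawn from the stationary
distribution so ensembles start in steady state.  Ensemble RNG streams
are spawned per trajectory from one `SeedSequence`, making statistics a
function of `(seed, n_traj)` only.  Sampling checks use 3-standard-error
brackets; covariance standard errors come from the spread of centered
products across trajectories.

## Problem sizes

Default test and acceptance runs use networks of 2–8 states (ensembles of
500 at 4 states), Gillespie ensembles of up to 400 trajectories at
duration 2·10³, and Θ-benchmark sizes N ∈ {4, 8, 16, 32, 64} (up to 69
states, 140 directed edges).  These sizes keep every identity at its
stated tolerance while the full suite runs in well under a minute of
compute for the analytic parts; the timing benchmark reports median wall
times over three repeats and asserts only the monotone growth of the
brute-force/analytic cost ratio, since absolute timings and fitted
exponents are hardware-dependent.

## Known limitations

* The dense-inverse path is quadratic in memory (`(2E)²`); the sparse
  path covers larger networks but the crossover (set at `2E = 500`) was
  chosen by convenience, not profiling on the target hardware.
* `design_step` is a fixed-step projected-gradient primitive; no line
  search or constrained-manifold optimisation is provided.
* Dwell observables have no jump representation, so their covariances are
  cross-checked by sampling only, not by the spectral oracle.
* Finite-time (non-asymptotic) statistics — transient distributions,
  finite-time Fano factors, higher cumulants — are out of scope.
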