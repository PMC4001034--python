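# Methods

## The model

`connset` realizes network connectivity from declarative connection-set
expressions. A connection-set `C = (M, V₀, V₁, …)` couples a mask `M` — a
Boolean indicator over source/target index pairs `(i, j)`, possibly with
infinite support — with `arity`-many value sets `V_k(i, j) → ℝ`. Populations
are abstracted to 0-based consecutive index sets; simulator global ids
(GIDs) are mapped to indices in user-list order, so the algebra never sees
the nature of the population elements (neurons, synaptic sites, devices).

Expressions are lazy trees: elementary masks at the leaves (`δ`, `ρ(p)`,
Cartesian products, explicit pair lists, `full`) and pointwise Boolean
operators (∩, ∪, −) at the internal nodes. Nothing is materialized until a
generator cuts the expression to a finite window — the Cartesian product of
the source and target index sets actually present — and streams the
members. Operators are restricted to arity-0 operands; value sets attach
only at the top of an expression (`cset`). How value sets should merge
under set union is not well defined, so the restriction avoids inventing
semantics for it.

## The random mask and the counter-based RNG

`ρ(p)` is an infinite matrix of independent Bernoulli(p) variables whose
*realization* is a fixed set, not a stream: `(i, j) ∈ ρ(p)` iff
`u(seed, i, j) < p`, where `u` maps the triple through three rounds of the
splitmix64 avalanche finalizer to a uniform value in [0, 1) with 53 bits of
precision. Consequences, all load-bearing for the partitioning contract:

- membership is pure: any rank, window, or query order sees the same mask;
- equal `(p, seed)` denotes the identical mask in different expressions;
- the seed is part of the expression and is mandatory in serialized form,
  so a parsed document reproduces the same network on any machine.

Iteration over a window evaluates the membership function on whole candidate
source rows at a time (vectorised numpy, one row per target). This is an
implementation technique only — semantics are defined by membership, and
brute-force oracle tests pin the equivalence. Counting similarly sums row
sizes without materializing pairs.

Uniform value sets reuse the same hash; clipped-normal noise applies the
inverse normal CDF to the uniform draw before clipping, so all random value
sets are equally pure in `(seed, i, j)`.

## The generator protocol

A consumer declares per-rank windows (`set_masks(masks, local)`: source
indices are typically shared, target sets disjoint across ranks — overlap
is flagged with a warning, not an error), calls `start()`, then `next()`
until the end signal (`None`). Streams are strictly increasing in
(target, source) with target major — all sources per target — matching how
a simulator kernel builds the inbound connections of each local neuron.
`size()` returns the exact count when computable without iteration
(explicit lists, δ/cross/full cut by interval windows, and intersections
with a Cartesian product, which merely narrow the window) and the sentinel
−1 otherwise; it is never wrong when non-negative. `start()` mid-iteration
resets to the beginning; changing masks mid-iteration is an error.

## The kernel

`cg_connect` emulates the simulator side in-process: GIDs map to indices,
targets partition over `n_ranks` by round-robin (`j mod n_ranks`;
injectable, so partition invariance is also tested under block
assignments), every rank receives the complete mask list plus its own rank
number, and each yielded `(i, j, values)` is stored as
`(source GID, target GID, named parameters)` through a `param_map` from
parameter names to value-vector positions. Arbitrary arities are supported;
`Network(strict_arity=True)` reproduces the historical consumer restriction
to arities 0 and 2 for fidelity testing. Repeated identical pairs are kept
as multi-edges and flagged in `network_stats`. The stored table is
independent of the rank count by construction, and tests assert it.

## Parameters and defaults

- `p` — Bernoulli inclusion probability of `ρ(p)`, dimensionless in [0, 1].
  Benchmarks default to 0.1, the density used in the scaling studies this
  package's benchmarks mirror.
- `seed` — 64-bit hash key; default 0 everywhere, always explicit in XML.
- `distance_delay(pos_s, pos_t, velocity, base, sigma, lo, hi, seed)` —
  delay = `base + ‖pos_s(i) − pos_t(j)‖ / velocity + clip(N(0, σ), lo, hi)`.
  Positions and distances share one length unit; `velocity` is length per
  time unit, `base`, `σ`, `lo`, `hi` and the result are in the consumer's
  time unit (ms for typical simulators). The functional form beyond
  "distance-dependent delay with clipped-normal noise" is this package's
  choice: additive noise with a hard clip is the simplest form that keeps
  delays bounded and strictly positive for suitable `lo`.
- CLI ranges are half-open `lo:hi` (common tooling convention); internal
  interval sets are closed on both ends, matching the contiguous-GID-range
  representation of simulator kernels.

## Benchmarks and problem sizes

The wall-clock scaling of the historical C++/Python implementations is
hardware-bound and not assertable; connection *counts* share the same
asymptotic exponents and are exact, so the benchmark harness measures
counts and reports times as information only. The slope convention is the
ratio of logarithms of the last and first data points,
`log(C_last/C_first)/log(x_last/x_first)`: expected 2 for `ρ(0.1)` (O(n²)
connections) and exactly 1 for one-to-one. The shipped test and acceptance
problem sizes — n = 100…10,000 for population scaling, n = 4,800 with up
to 48 emulated ranks (≈2.3·10⁶ connections) for strong scaling — were
chosen so the whole suite runs comfortably on a laptop; the full
48,000-neuron, ≈2.3·10⁸-connection configuration is reachable through
`connset bench-strong --n 48000` unchanged.

## What the synthetic conditions do and do not show

All inputs are synthetic by nature (the algebra *defines* the network), so
tests demonstrate correctness of realization — membership, ordering,
partitioning, reproducibility, counts within 4 binomial standard deviations
of expectation — not biological plausibility of any particular expression.
Real parallel execution (MPI), neuron dynamics, devices and synapse models
are out of scope; ranks are emulated in one process, which exercises the
full mask-partitioning contract but not communication or memory scaling.

## Numerical and design choices

- Uniform draws have 53-bit resolution; `p` below ~1.1e-16 is
  indistinguishable from 0. The inverse-CDF normal transform guards the
  open endpoint u = 0.
- Index sets permit emptiness (a rank may own no targets); populations at
  the kernel level must be non-empty.
- Duplicate ids, duplicate GIDs, out-of-range `param_map` indices, operator
  application to positive-arity operands, unknown XML elements and
  unregistered root tags are all hard errors — nothing is silently dropped.
- Tag re-registration in the parser registry is last-write-wins with a
  warning, so an application can deliberately override the builtin dialect.
- The XML dialect (docs/xml-dialect.md) is purpose-built and versioned; it
  is inspired by MathML's apply/operand structure but fully specified here.
  Parsing returns a generator with masks unset; the consumer supplies
  windows.

## Known limitations

- `size()` is conservative: any expression involving `ρ(p)` reports −1
  even where bounds are derivable.
- Row-wise vectorised iteration is O(|sources|) per target regardless of
  density; for very sparse masks over huge windows a skip-sampling scheme
  consistent with hash membership would be faster and is not implemented.
- Only Euclidean distance is offered for geometric value sets, and custom
  Python value sets do not serialize.
- The weak-scaling protocol of the historical timing studies (fixed
  connection increment per added process, with its per-process rounding
  rule) is under-specified and deliberately not reproduced.
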