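# Methods

## Model and encoding

A Boolean network on nodes `x1 … xn` assigns each node one logic rule over
the node variables; synchronous updating applies all rules simultaneously,
so the network is a map `F : {0,1}^n → {0,1}^n`.  States are encoded as
integers with `x1` as the most significant bit
(`w = Σ x_i · 2^(n−i)`); the encoding is fixed package-wide because every
integer-labelled artifact (maps, matrices, landscape plots, bit-string
reports) depends on it.  The one-step dynamics is materialized as an
*integer map*: a length-`2^n` index table built by evaluating each rule AST
once over the bit-sliced enumeration of the state space (vectorized, no
per-state Python loop).

Two rule dialects parse to the same AST: BoolNet-style `&`/`|`/`!`, and an
algebraic dialect in which juxtaposition is AND, `+` is OR and `!` is
negation (the typeset overbar).  In the algebraic dialect variable names
are restricted to one letter plus digits so a product like `x1x2` tokenizes
unambiguously.  Constant rules (`0`, `1`) are legal.

Exhaustive operations refuse to run above `n = 24` (configurable `cap`
argument) with an explicit error rather than truncating.

## Matrix formalism

The transition matrix stores `M[i, j] = 1` iff state `j` steps to state
`i`: columns index sources, so `M^t u0` with a one-hot column `u0` advances
the dynamics `t` steps (Chapman-Kolmogorov form).  Multiplication is over
the Boolean semiring (OR of ANDs).  A matrix derived from a map is
*functional* — exactly one 1 per column — and stays functional under
powers.  Powers are computed by exponentiation-by-squaring on the index
table (`O(2^n log t)`); the dense semiring product exists for cross-checks
and non-functional inputs.

The matrix power sequence of a functional matrix is eventually periodic:
`M^(T0+p) = M^(T0)` with transient `T0 ≤ 2^n` (the maximum tree depth) and
period `p` the lcm of the cycle lengths.  `T0` and `p` are found exactly by
hashing successive powers of the map until one repeats — not by evaluating
a "large t" — so the landscape limit is exact and always terminates.  The
landscape is `M^(T0)` when `p = 1` and the entrywise OR of `M^t` over
`t ∈ {T0, …, T0 + p − 1}` otherwise.  Any full window at/after `T0` gives
the same OR; the implementation uses the earliest.

## Attractors and basins

Fixed points are the reflexive states of the map; cycles are the cycles of
its functional graph; each state's attractor is the cycle its trajectory
enters, and basins partition the state space.  Detection is a single
iterative traversal with state coloring (each state walked at most twice,
`O(2^n)` total), recording per-state transient lengths as a by-product.
Orbits are canonically rotated to start at their minimal state and
attractor lists are sorted by minimal orbit element, so reports and test
goldens are byte-stable.

The matrix-limit landscape and the functional-graph landscape are computed
by disjoint code paths and compared on random networks in the test suite —
a deliberate dual route, kept separate so each checks the other.

## Canonical form

1. **Compaction.**  Replace the map `f` by `f^(t*)`, where `t*` is the
   least `t ≥ `(maximum transient length) with `gcd(t, L) = 1` for every
   cycle length `L`.  Every state then lands on its attractor orbit in one
   application, and coprimality makes the restriction to each orbit a
   full-length cycle again (such `t` always exists).  When every attractor
   is a fixed point the rule degenerates to "any `t` past the longest
   transient".  For cycles of period ≥ 3 the compacted cycle may traverse
   its states in a different order; the landscape is unaffected (see
   equivalence below).
2. **Minterms.**  Node `i`'s minterm set is `{w : bit i of f^(t*)(w) = 1}`.
3. **Minimization.**  Each minterm set is minimized exactly to a smallest
   sum-of-products — prime implicant generation plus minimum cover
   (Quine-McCluskey, delegated to sympy's `SOPform`, which is
   deterministic for a fixed variable order; variables are ordered by node
   index with the first node as the most significant minterm bit).  Full
   and empty sets become the constants 1 and 0.  Exactness matters: the
   minimized rule must reproduce minterm membership on *every* state, and
   the tests verify this by direct evaluation.
4. **Verification.**  The assembled network is checked for dynamical
   equivalence with the input before being returned.

**Equivalence** means identical attractor landscape: the same attractor
state-sets and the same basin assignment for every state.  One-step maps
may differ — that is the point of simplification — and the traversal order
within a cycle is not part of the landscape, since the landscape relation
pairs every basin element with every orbit state regardless of order.

## Deterministic asynchronous updating

A schedule assigns each node a period `τ_i` (node `i` updates at steps
`t ≡ 0 mod τ_i`, steps 1-based) or gives an explicit cyclic list of update
subsets; explicit lists exist because a period rule alone does not pin down
phase, and they let any printed update ordering be specified verbatim.
Each step applies a subset-update function (chosen nodes compute their
rules, all other bits copy); the composition of one hyperperiod of steps
(lcm of the periods, or the list length) is a single map `G`, and the
asynchronous attractors, basins and landscape are defined as those of `G`.

Consequences, all covered by tests: every synchronous fixed point is fixed
under every subset-update function and hence under `G`, for any schedule;
cyclic attractors can disappear; basin membership can shift between
schedules.  Because function composition is not commutative, different
update orders yield different `G` — there is no unique canonical form for
asynchronous systems, so this module only reports landscapes and
differences and deliberately offers no canonical-form operation.
Stochastic (random-order) asynchrony is out of scope.

## Modular solving of large networks

For networks whose modules depend on each other acyclically:

- **Semi-attractors.**  Modules are processed in topological order.  A
  module's external inputs are frozen at the values they take in upstream
  semi-attractors (every combination drawn from the cross product of the
  upstream sets, restricted to the variables actually read); for each
  frozen input the module's fixed states over its own `2^k` local states
  are collected.  Only fixed semi-attractors are supported; a frozen module
  whose only attractors are cyclic yields an error rather than a guess.
- **Join and validation.**  Candidates are the unconstrained cross product
  of per-module semi-attractor sets, concatenated in node order.  A
  candidate is a true attractor iff `F(s) = s` on the full network — one
  vectorized rule sweep over all candidates, no state-space enumeration.
- **Basin counting by drivers.**  For each frozen module the settled map
  (the module map raised to a power past every transient, computed by
  pointer doubling) gives each initial local state's fixed point.  The
  *support* of that settled map — the local variables whose flip changes
  some output — equals the support of the module's exactly minimized
  canonical form, and is computed directly from the table (materializing a
  minimized DNF over 2^20 minterms would be pointless work for the same
  answer).  Module drivers are that support plus, when the settled
  behaviour differs across frozen-input values, the drivers of the
  feeding modules.  With `D` the union of drivers, each validated attractor
  is reached from the `2^(n − |D|)` states sharing its driver assignment.
  This count is only reported when it is provably consistent: every
  frozen module fixed-point-only, distinct attractors with distinct driver
  restrictions, and exactly `2^|D|` attractors; otherwise the procedure
  raises "not computable by support counting".

The modular route answers *which* attractors exist and *how large* their
basins are without touching the `2^n` state space; on the 9-node bundled
example, where brute force is trivial, the test suite confirms both against
full enumeration.  Feedback between modules is unsupported by construction
(the partition validator rejects cyclic module dependencies); only a
consecutive-blocks partition helper is provided, not automatic SCC
decomposition.

## Random network ensemble

`random_network(n, max_inputs, seed)` draws, per node, a regulator count
uniform on `1..max_inputs`, a uniform random regulator subset, and a
uniform random truth table over those regulators, materialized as the sum
of its minterms.  This is the standard quenched random Boolean network
ensemble; it reproduces the structural variety the property tests need
(mixes of fixed points, long cycles, deep transients) but not the
topological or truth-table biases of curated biological networks
(canalyzing rules, scale-free in-degree), so green property suites certify
the algebra — basin partitioning, formalism equivalence, canonical-form
equivalence, fixed-point invariance, cycle decomposition — not biological
realism.  All generation is seeded; the suites run 200 instances at
`n ∈ {2..6}` with `max_inputs ≤ 3`, sizes at which every property can also
be checked against brute-force enumeration in well under a minute.

## Problem sizes and costs

Everything exhaustive is `O(2^n)` in memory (one int64 table) and near-linear
in time; `n ≤ 12` is instantaneous, `n = 20` (a single modular block of the
200-node example) takes a few seconds, and the default cap refuses `n > 24`.
The 200-node modular analysis — 11 frozen-module solves of `2^20` states
plus candidate validation — completes in seconds.

## Known limitations

- Exhaustive analyses are inherently exponential in `n`; the package offers
  exactness below the cap and the modular procedure above it, nothing in
  between (no sampling or approximate attractor search).
- Modular solving requires an acyclic module dependency graph and fixed
  (non-cyclic) semi-attractors; the basin count additionally requires the
  driver factorization to be exact, and refuses otherwise.
- The modular attractor set is validated exactly, but candidates are only
  as complete as the semi-attractor construction: attractors whose
  module-restrictions are not fixed states of the frozen modules (possible
  with inter-module feedback, which the partition validator excludes) are
  outside its scope.
- Asynchronous analysis covers deterministic periodic schedules only; the
  stochastic update semantics used by tools like GINSIM is a non-goal, as
  are SBML-qual/GINSIM file formats and multi-valued logic.
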