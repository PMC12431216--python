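# boolscape

Attractor landscapes, canonical forms and update schemes for Boolean
networks.

Boolean networks are a workhorse model of gene-regulatory and signalling
systems: each node (gene, protein) is ON or OFF, and a logic rule
`x_i(t+1) = f_i(x_1(t), …, x_n(t))` determines its next state.  The
long-run behaviour — which attractors exist (cell fates), and which initial
configurations reach which attractor (their basins) — is what connects the
model to biology.  `boolscape` is for modellers who want that landscape
computed exactly, together with the *canonical form* of the network: the
minimal set of rules that generates the identical landscape.

## What it computes

Encode each state as an integer `w = Σ x_i · 2^(n−i)` (node `x1` is the
most significant bit).  The synchronous dynamics is then a single map
`f** : Ω → Ω` on `Ω = {0, …, 2^n − 1}`, or equivalently a 0/1 transition
matrix `M` over the Boolean semiring with `M[i, j] = 1` iff state `j` steps
to state `i`.  Iteration is the Chapman-Kolmogorov power form
`S(t) = M^t u0` — the synchronous scheme is a degenerate Markov chain.  On
top of this the package provides:

- **Attractors and basins** — fixed points are the reflexive states
  `f**(w) = w`; cycles are the cycles of the functional graph; basins are
  the trees feeding them.  Detected in `O(2^n)` by graph traversal, and
  independently by the matrix limit `S* = lim S(t)` (stationary for
  fixed-point-only systems, a periodic logical sum `Ω = Σ_{t∈T} S(t)` when
  cycles are present).
- **Canonical form** — compact the map so every state jumps straight onto
  its attractor orbit, read off each node's minterms, and minimize exactly
  (prime implicants + minimum cover) into a two-level rule per node.  The
  result is verified to have the identical landscape (same attractors, same
  basin assignment).
- **Deterministic asynchronous schedules** — each node updated every
  `τ_i` steps (or an explicit subset sequence).  Each step is a
  subset-update function; their composition over one hyperperiod is a
  single map whose attractors define the asynchronous landscape.  Fixed
  points are invariant to the schedule; cycles and basins are not, and no
  unique canonical form exists for asynchronous systems.
- **Modular solving of large networks** — partition the nodes into modules
  with acyclic dependencies, find each module's *semi-attractors* (fixed
  states with upstream inputs frozen), join them into candidate global
  attractors, validate with one rule sweep per candidate (`F(s) = s`), and
  count basin sizes from the driver variables of the module canonical
  forms — tractable at hundreds of nodes, far beyond the `2^n` state space.

## Worked example

The bundled 3-node network `E13`

```
x1+ = x1
x2+ = x2 | x3
x3+ = (x1 | !x3) & (x2 | !x3)
```

has the integer map `{0:1, 1:2, 2:3, 3:2, 4:5, 5:6, 6:7, 7:7}`:

```sh
$ boolscape attractors --fixture E13
```

```json
{
  "attractors": [
    {"basin_size": 4, "kind": "cyclic", "orbit": [2, 3], "orbit_bits": ["010", "011"]},
    {"basin_size": 4, "kind": "fixed", "orbit": [7], "orbit_bits": ["111"]}
  ],
  "n": 3
}
```

States 2 and 3 (`x1 = 0`, `x2 = 1`) oscillate in `x3`; state 7 (all ON) is
a fixed point; each attracts half of the 8 states.  Its canonical form:

```sh
$ boolscape canonical --fixture E13
targets, factors
x1, x1
x2, 1
x3, x1 | !x3
# equivalent: true
```

Three minimal rules — `x2` is constitutively ON, `x1` self-sustains and
drives `x3` — with the identical attractor landscape, as the trailing
equivalence check confirms.  The same library calls are available in
Python (`fixture`, `build_integer_map`, `analyze_map`,
`canonical_network`, `async_landscape`, `modular_solve`).

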