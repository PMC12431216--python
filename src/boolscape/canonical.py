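"""Canonical (minimal, dynamically equivalent) form of a synchronous network.

The pipeline:

1. *Compaction* — replace the one-step map by a power of itself that sends
   every state straight into its attractor orbit while keeping every cycle a
   full-length cycle.  The power used is ``t* = `` the least ``t`` at least
   the maximum transient length with ``gcd(t, L) = 1`` for every cycle
   length ``L`` (coprimality makes the restriction of ``f^t`` to each orbit
   a single full cycle again; such ``t`` always exists).
2. *Minterm extraction* — node ``i``'s minterms are the input states whose
   compacted image sets bit ``i``.
3. *Exact two-level minimization* — each node's minterm set is minimized to
   a smallest sum-of-products (Quine-McCluskey prime implicants with
   minimal cover, via sympy); full/empty minterm sets become the constants
   1/0.
4. *Re-assembly* — the minimized rules form a new network with the same
   nodes, verified to have the identical attractor landscape (attractors
   and basin assignment) as the input.

Dynamical equivalence throughout means *identical landscape*: the same
attractors with the same basin assignment, even though one-step maps differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sympy import And as SymAnd, Not as SymNot, Or as SymOr, Symbol, false, true
from sympy.logic import SOPform

from .attractors import analyze_map
from .network import (And, BoolExpr, BooleanNetwork, Const, Not, Or,
                      STATE_SPACE_CAP, Var, check_cap)
from .statemap import IntegerMap, build_integer_map

__all__ = [
    "MintermTable",
    "DNF",
    "compact_map",
    "minterms_from_map",
    "minimize_dnf",
    "canonical_network",
    "check_equivalence",
]


@dataclass(frozen=True)
class MintermTable:
    """Per node, the set of input states (minterm integers) mapping to 1."""

    n: int
    minterms: tuple[tuple[int, ...], ...]  # one sorted tuple per node

    def __post_init__(self):
        if len(self.minterms) != self.n:
            raise ValueError("one minterm set per node is required")
        size = 1 << self.n
        for ms in self.minterms:
            if any(not 0 <= w < size for w in ms):
                raise ValueError("minterm out of state-space range")

    def membership(self, node: int) -> np.ndarray:
        out = np.zeros(1 << self.n, dtype=bool)
        out[list(self.minterms[node])] = True
        return out


@dataclass(frozen=True)
class DNF:
    """Two-level sum-of-products form, one formula per node.

    Each node holds either a constant (0/1) or a list of product terms; a
    term is a sorted tuple of ``(variable_index, positive)`` literals.
    """

    n: int
    nodes: tuple[object, ...]  # per node: int constant | tuple of terms

    def expr(self, node: int) -> BoolExpr:
        spec = self.nodes[node]
        if isinstance(spec, int):
            return Const(spec)
        products: list[BoolExpr] = []
        for term in spec:
            lits: list[BoolExpr] = [Var(i) if pos else Not(Var(i))
                                    for i, pos in term]
            products.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
        return products[0] if len(products) == 1 else Or(tuple(products))

    def exprs(self) -> list[BoolExpr]:
        return [self.expr(i) for i in range(self.n)]


def compact_map(m: IntegerMap) -> IntegerMap:
    """Send every state directly into its attractor orbit.

    Returns ``m`` composed with itself ``t*`` times, where ``t*`` is the
    least power at least the maximum transient length that is coprime to
    every cycle length.  The result maps each basin onto its orbit and
    restricts to a full-length cycle on each orbit.
    """
    analysis = analyze_map(m)
    cycle_lengths = {a.period for a in analysis.attractors}
    t = analysis.max_transient
    while any(math.gcd(t, L) != 1 for L in cycle_lengths):
        t += 1
    return m.power(t)


def minterms_from_map(m: IntegerMap) -> MintermTable:
    """Node ``i``'s minterms are the inputs whose image sets bit ``i``."""
    n = m.n
    out = []
    for i in range(n):
        bit = (m.image >> (n - 1 - i)) & 1
        out.append(tuple(np.nonzero(bit)[0].tolist()))
    return MintermTable(n, tuple(out))


def _sympy_to_dnf_node(expr, sym_index: dict) -> object:
    if expr is true:
        return 1
    if expr is false:
        return 0
    terms = expr.args if isinstance(expr, SymOr) else (expr,)
    out = []
    for term in terms:
        lits = term.args if isinstance(term, SymAnd) else (term,)
        parsed = []
        for lit in lits:
            if isinstance(lit, SymNot):
                parsed.append((sym_index[lit.args[0]], False))
            else:
                parsed.append((sym_index[lit], True))
        out.append(tuple(sorted(parsed)))
    return tuple(out)


def minimize_dnf(table: MintermTable) -> DNF:
    """Exact two-level minimization of every node's minterm function.

    Prime implicants plus minimum cover (Quine-McCluskey, delegated to
    sympy's ``SOPform``), with the first node as the most significant
    minterm bit.  Full and empty minterm sets become the constants 1 and 0.
    The minimized form evaluates identically to minterm membership on every
    state — exactness is what makes the canonical network faithful.
    """
    n = table.n
    size = 1 << n
    # zero-padded names keep sympy's ordering identical to node order
    syms = [Symbol(f"v{i:03d}") for i in range(n)]
    sym_index = {s: i for i, s in enumerate(syms)}
    nodes: list[object] = []
    for i in range(n):
        ms = table.minterms[i]
        if len(ms) == 0:
            nodes.append(0)
        elif len(ms) == size:
            nodes.append(1)
        else:
            nodes.append(_sympy_to_dnf_node(SOPform(syms, list(ms)), sym_index))
    return DNF(n, tuple(nodes))


def canonical_network(net: BooleanNetwork, cap: int = STATE_SPACE_CAP) -> BooleanNetwork:
    """The minimal network with the identical attractor landscape.

    Pipeline: integer map -> basin compaction -> minterms -> exact
    minimization -> network.  The output is verified to be dynamically
    equivalent to the input before it is returned.
    """
    check_cap(net.n, cap)
    m = build_integer_map(net, cap=cap)
    compacted = compact_map(m)
    dnf = minimize_dnf(minterms_from_map(compacted))
    out = BooleanNetwork(list(net.nodes), dnf.exprs())
    if not check_equivalence(net, out, cap=cap):
        raise AssertionError("canonical form failed the equivalence check")
    return out


def check_equivalence(a: BooleanNetwork, b: BooleanNetwork,
                      cap: int = STATE_SPACE_CAP) -> bool:
    """True iff the two networks have the identical attractor landscape.

    Identical landscape means the same attractor orbits AND the same basin
    assignment for every state; the one-step maps may differ.
    """
    if a.n != b.n or a.nodes != b.nodes:
        raise ValueError("networks must share node count and order")
    sig_a = analyze_map(build_integer_map(a, cap=cap)).signature()
    sig_b = analyze_map(build_integer_map(b, cap=cap)).signature()
    return sig_a == sig_b
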