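"""Boolean networks, rule expressions and the state <-> integer encoding.

A Boolean network is an ordered list of nodes, each carrying one Boolean
update rule over the node variables.  Under the synchronous scheme every
node applies its rule simultaneously, so the network is a map
``F : {0,1}^n -> {0,1}^n``.  Throughout the package a state is also
identified with an integer in ``{0 .. 2^n - 1}`` where node 1 contributes
the most significant bit; all attractor and matrix machinery operates on
that integer encoding.

Two textual rule dialects are supported:

* ``bnet`` -- BoolNet-style operators ``&``, ``|``, ``!`` with free-form
  identifiers, as used in ``targets, factors`` rule files.
* ``paper`` -- algebraic product/sum notation: juxtaposition means AND,
  ``+`` means OR and ``!`` means negation (the typeset overbar).  Variable
  names are restricted to one letter plus digits (``x1``, ``x12``) so that
  products such as ``x1x2`` tokenize unambiguously.

Both dialects compile to the same expression AST.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "BoolExpr",
    "Var",
    "Not",
    "And",
    "Or",
    "Const",
    "BooleanNetwork",
    "ParseError",
    "parse_expression",
    "parse_network",
    "serialize_network",
    "encode_state",
    "decode_state",
    "STATE_SPACE_CAP",
    "StateSpaceCapError",
]

#: Refuse exhaustive state-space operations above this node count unless the
#: caller explicitly raises the cap; 2^24 states is the largest table that is
#: still comfortably addressable as a dense integer array.
STATE_SPACE_CAP = 24


class StateSpaceCapError(ValueError):
    """Raised when an exhaustive operation would exceed the state-space cap."""


def check_cap(n: int, cap: int = STATE_SPACE_CAP) -> None:
    if n > cap:
        raise StateSpaceCapError(
            f"exhaustive operation over 2^{n} states exceeds the cap of 2^{cap}; "
            "pass a larger cap explicitly to override"
        )


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------

class BoolExpr:
    """Base class for Boolean rule expressions.

    ``evaluate`` accepts either a sequence of scalar bits or, for vectorized
    truth-table construction, numpy integer/boolean arrays (one entry per
    state of the state space).
    """

    def evaluate(self, bits):  # pragma: no cover - abstract
        raise NotImplementedError

    def variables(self) -> set[int]:
        """Indices of the variables occurring in the expression."""
        raise NotImplementedError

    def to_bnet(self, names: Sequence[str]) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class Var(BoolExpr):
    index: int

    def evaluate(self, bits):
        return bits[self.index]

    def variables(self):
        return {self.index}

    def to_bnet(self, names):
        return names[self.index]


@dataclass(frozen=True)
class Const(BoolExpr):
    value: int

    def evaluate(self, bits):
        return self.value

    def variables(self):
        return set()

    def to_bnet(self, names):
        return str(self.value)


@dataclass(frozen=True)
class Not(BoolExpr):
    operand: BoolExpr

    def evaluate(self, bits):
        return 1 - self.operand.evaluate(bits)

    def variables(self):
        return self.operand.variables()

    def to_bnet(self, names):
        inner = self.operand.to_bnet(names)
        if isinstance(self.operand, (Var, Const)):
            return f"!{inner}"
        return f"!({inner})"


@dataclass(frozen=True)
class And(BoolExpr):
    operands: tuple[BoolExpr, ...]

    def evaluate(self, bits):
        out = self.operands[0].evaluate(bits)
        for op in self.operands[1:]:
            out = out & op.evaluate(bits)
        return out

    def variables(self):
        out: set[int] = set()
        for op in self.operands:
            out |= op.variables()
        return out

    def to_bnet(self, names):
        parts = []
        for op in self.operands:
            s = op.to_bnet(names)
            if isinstance(op, Or):
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(BoolExpr):
    operands: tuple[BoolExpr, ...]

    def evaluate(self, bits):
        out = self.operands[0].evaluate(bits)
        for op in self.operands[1:]:
            out = out | op.evaluate(bits)
        return out

    def variables(self):
        out: set[int] = set()
        for op in self.operands:
            out |= op.variables()
        return out

    def to_bnet(self, names):
        return " | ".join(op.to_bnet(names) for op in self.operands)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """Syntax or reference error in a rule file, with a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


_BNET_TOKEN = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_.]*)|(?P<const>[01])"
                         r"|(?P<op>[&|!()]))")
# paper dialect: single letter + digits, so products like x1x2 split correctly
_PAPER_TOKEN = re.compile(r"\s*(?:(?P<name>[A-Za-z]\d*)|(?P<const>[01])"
                          r"|(?P<op>[+!()]))")


def _tokenize(text: str, dialect: str, line: int | None) -> list[tuple[str, str]]:
    pattern = _BNET_TOKEN if dialect == "bnet" else _PAPER_TOKEN
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = pattern.match(text, pos)
        if m is None:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ParseError(f"unexpected character {rest[0]!r}", line)
        pos = m.end()
        if m.lastgroup is None:
            continue
        tokens.append((m.lastgroup, m.group(m.lastgroup)))
    return tokens


class _Parser:
    """Recursive-descent parser shared by both dialects.

    Grammar (OR-op is ``|`` or ``+``; AND is ``&`` or juxtaposition)::

        expr    := term (OR term)*
        term    := factor (AND factor | factor)*     # juxtaposition in paper
        factor  := '!' factor | atom
        atom    := name | const | '(' expr ')'
    """

    def __init__(self, tokens, dialect, line):
        self.tokens = tokens
        self.dialect = dialect
        self.line = line
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> BoolExpr:
        expr = self.expr()
        if self.pos != len(self.tokens):
            raise ParseError(f"trailing input near {self.peek()[1]!r}", self.line)
        return expr

    def expr(self) -> BoolExpr:
        terms = [self.term()]
        while self.peek() == ("op", "|") or self.peek() == ("op", "+"):
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def _starts_factor(self) -> bool:
        kind, val = self.peek()
        return kind in ("name", "const") or (kind == "op" and val in ("!", "("))

    def term(self) -> BoolExpr:
        factors = [self.factor()]
        while True:
            if self.peek() == ("op", "&"):
                self.next()
                factors.append(self.factor())
            elif self.dialect == "paper" and self._starts_factor():
                factors.append(self.factor())  # juxtaposition = AND
            else:
                break
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def factor(self) -> BoolExpr:
        kind, val = self.peek()
        if (kind, val) == ("op", "!"):
            self.next()
            return Not(self.factor())
        return self.atom()

    def atom(self) -> BoolExpr:
        kind, val = self.next()
        if kind == "name":
            return _NameRef(val)
        if kind == "const":
            return Const(int(val))
        if (kind, val) == ("op", "("):
            inner = self.expr()
            kind, val = self.next()
            if (kind, val) != ("op", ")"):
                raise ParseError("unbalanced parenthesis", self.line)
            return inner
        raise ParseError("expected a variable, constant or '('", self.line)


@dataclass(frozen=True)
class _NameRef(BoolExpr):
    """Placeholder leaf used before variable names are resolved to indices."""

    name: str

    def evaluate(self, bits):  # pragma: no cover - resolved before evaluation
        raise RuntimeError(f"unresolved variable {self.name!r}")

    def variables(self):  # pragma: no cover
        raise RuntimeError(f"unresolved variable {self.name!r}")

    def to_bnet(self, names):
        return self.name


def _resolve(expr: BoolExpr, index: dict[str, int], line: int | None) -> BoolExpr:
    if isinstance(expr, _NameRef):
        if expr.name not in index:
            raise ParseError(f"undeclared variable {expr.name!r}", line)
        return Var(index[expr.name])
    if isinstance(expr, Not):
        return Not(_resolve(expr.operand, index, line))
    if isinstance(expr, And):
        return And(tuple(_resolve(op, index, line) for op in expr.operands))
    if isinstance(expr, Or):
        return Or(tuple(_resolve(op, index, line) for op in expr.operands))
    return expr


def parse_expression(text: str, names: Sequence[str], dialect: str = "bnet",
                     line: int | None = None) -> BoolExpr:
    """Parse a single rule expression against a declared node list."""
    if dialect not in ("bnet", "paper"):
        raise ValueError(f"unknown dialect {dialect!r}")
    tokens = _tokenize(text, dialect, line)
    if not tokens:
        raise ParseError("empty expression", line)
    raw = _Parser(tokens, dialect, line).parse()
    return _resolve(raw, {name: i for i, name in enumerate(names)}, line)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

@dataclass
class BooleanNetwork:
    """An ordered set of named nodes with one update rule each."""

    nodes: list[str]
    rules: list[BoolExpr]

    def __post_init__(self):
        if len(self.nodes) < 1:
            raise ValueError("a network needs at least one node")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node names must be unique")
        if len(self.rules) != len(self.nodes):
            raise ValueError("exactly one rule per node is required")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def evaluate_rule(self, node_index: int, bits: Sequence[int]):
        """Truth value of one node's rule on a complete state.

        ``bits`` may also be a tuple of numpy arrays for bulk evaluation.
        """
        if not 0 <= node_index < self.n:
            raise IndexError(f"node index {node_index} out of range for n={self.n}")
        return self.rules[node_index].evaluate(bits)

    def step(self, bits: Sequence[int]) -> tuple[int, ...]:
        """One synchronous update of a full state."""
        return tuple(int(rule.evaluate(bits)) for rule in self.rules)

    @classmethod
    def from_rules(cls, rules: dict[str, str] | Iterable[tuple[str, str]],
                   dialect: str = "bnet") -> "BooleanNetwork":
        """Build a network from ``{target: expression}`` pairs in order."""
        pairs = list(rules.items()) if isinstance(rules, dict) else list(rules)
        names = [t for t, _ in pairs]
        exprs = [parse_expression(e, names, dialect) for _, e in pairs]
        return cls(names, exprs)


def parse_network(text: str, dialect: str = "bnet") -> BooleanNetwork:
    """Parse a rule file into a network.

    Accepts BoolNet ``targets, factors`` content: an optional header line,
    ``#`` comments, and one ``target, expression`` line per node.  Node order
    follows declaration order.
    """
    pairs: list[tuple[str, str, int]] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if re.fullmatch(r"targets\s*,\s*factors", stripped, flags=re.IGNORECASE):
            continue
        if "," not in stripped:
            raise ParseError("expected 'target, expression'", lineno)
        target, _, expr = stripped.partition(",")
        target = target.strip()
        if not target:
            raise ParseError("missing target name", lineno)
        if target in seen:
            raise ParseError(f"duplicate target {target!r}", lineno)
        seen.add(target)
        pairs.append((target, expr.strip(), lineno))
    if not pairs:
        raise ParseError("no rules found in input")
    names = [t for t, _, _ in pairs]
    rules = [parse_expression(e, names, dialect, line=ln) for _, e, ln in pairs]
    return BooleanNetwork(names, rules)


def serialize_network(net: BooleanNetwork, header: bool = True) -> str:
    """Render a network as BoolNet ``targets, factors`` text."""
    lines = ["targets, factors"] if header else []
    for name, rule in zip(net.nodes, net.rules):
        lines.append(f"{name}, {rule.to_bnet(net.nodes)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# State encoding: node 1 is the most significant bit
# ---------------------------------------------------------------------------

def encode_state(bits: Sequence[int]) -> int:
    """Binary encoding of a state, first node as most significant bit."""
    w = 0
    for b in bits:
        if b not in (0, 1):
            raise ValueError(f"state bits must be 0/1, got {b!r}")
        w = (w << 1) | b
    return w


def decode_state(w: int, n: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_state` for an ``n``-node network."""
    if not 0 <= w < (1 << n):
        raise ValueError(f"state {w} out of range for n={n}")
    return tuple((w >> (n - 1 - i)) & 1 for i in range(n))
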