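"""Integer transition maps and Boolean-semiring transition matrices.

The synchronous dynamics of an ``n``-node network is fully described by the
integer map ``f** : {0..2^n-1} -> {0..2^n-1}`` sending every encoded state to
its one-step image.  The equivalent matrix form is the 0/1 matrix ``M`` with
``M[i, j] = 1`` iff state ``j`` maps to state ``i``; iterating the dynamics
is then the Chapman-Kolmogorov power ``S(t) = M^t`` over the Boolean
semiring (OR of ANDs), applied to a one-hot initial column.

The integer map (a length-``2^n`` table) is the canonical representation;
the dense matrix is a derived view and is materialized on demand only.
Matrix powers are computed by composing the underlying map
(exponentiation-by-squaring on index tables), which is exact and avoids
``2^n x 2^n`` products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import BooleanNetwork, check_cap, STATE_SPACE_CAP

__all__ = [
    "IntegerMap",
    "TransitionMatrix",
    "build_integer_map",
    "map_to_matrix",
    "matrix_to_map",
    "compose_maps",
    "matrix_power",
    "trajectory",
]


@dataclass(frozen=True)
class IntegerMap:
    """A total function on ``{0 .. 2^n - 1}`` stored as an index table."""

    n: int
    image: np.ndarray  # int64, shape (2**n,)

    def __post_init__(self):
        image = np.ascontiguousarray(np.asarray(self.image, dtype=np.int64))
        object.__setattr__(self, "image", image)
        size = 1 << self.n
        if image.shape != (size,):
            raise ValueError(f"image table must have length 2^{self.n}")
        if image.size and (image.min() < 0 or image.max() >= size):
            raise ValueError("image values out of state-space range")

    def __call__(self, w: int) -> int:
        return int(self.image[w])

    @property
    def size(self) -> int:
        return 1 << self.n

    def as_pairs(self) -> list[tuple[int, int]]:
        return [(w, int(v)) for w, v in enumerate(self.image)]

    def as_dict(self) -> dict[int, int]:
        return dict(self.as_pairs())

    @classmethod
    def from_pairs(cls, n: int, pairs) -> "IntegerMap":
        image = np.full(1 << n, -1, dtype=np.int64)
        for w, v in dict(pairs).items():
            image[w] = v
        if (image < 0).any():
            raise ValueError("pairs do not define a total function")
        return cls(n, image)

    def power(self, t: int) -> "IntegerMap":
        """t-fold self-composition by exponentiation-by-squaring."""
        if t < 0:
            raise ValueError("power must be non-negative")
        result = np.arange(self.size, dtype=np.int64)
        base = self.image
        while t:
            if t & 1:
                result = base[result]
            base = base[base]
            t >>= 1
        return IntegerMap(self.n, result)

    def __eq__(self, other):
        return (isinstance(other, IntegerMap) and self.n == other.n
                and np.array_equal(self.image, other.image))

    def __hash__(self):
        return hash((self.n, self.image.tobytes()))


@dataclass(frozen=True)
class TransitionMatrix:
    """A 0/1 matrix over the Boolean semiring; column = source state.

    ``entries[i, j] = 1`` iff state ``j`` transitions to state ``i``, so that
    ``M @ u0`` with a one-hot column ``u0`` advances the dynamics one step.
    A matrix derived from a map is *functional*: exactly one 1 per column.
    """

    n: int
    entries: np.ndarray  # bool, shape (2**n, 2**n)

    def __post_init__(self):
        entries = np.asarray(self.entries, dtype=bool)
        object.__setattr__(self, "entries", entries)
        size = 1 << self.n
        if entries.shape != (size, size):
            raise ValueError(f"matrix must be 2^{self.n} x 2^{self.n}")

    @property
    def size(self) -> int:
        return 1 << self.n

    def is_functional(self) -> bool:
        return bool((self.entries.sum(axis=0) == 1).all())

    def matmul(self, other: "TransitionMatrix") -> "TransitionMatrix":
        """Boolean-semiring product (OR of ANDs)."""
        if self.n != other.n:
            raise ValueError("dimension mismatch")
        prod = (self.entries.astype(np.uint8) @ other.entries.astype(np.uint8)) > 0
        return TransitionMatrix(self.n, prod)

    def logical_or(self, other: "TransitionMatrix") -> "TransitionMatrix":
        if self.n != other.n:
            raise ValueError("dimension mismatch")
        return TransitionMatrix(self.n, self.entries | other.entries)

    def apply(self, u0: int) -> list[int]:
        """States reachable in one step from ``u0`` (image of a one-hot column)."""
        return [int(i) for i in np.nonzero(self.entries[:, u0])[0]]

    def to_rows(self) -> list[str]:
        """Rows as 0/1 strings, top row first."""
        return ["".join("1" if v else "0" for v in row) for row in self.entries]

    def to_bracket_string(self) -> str:
        """Row-major flattened 0/1 string in brackets, e.g. ``[0000100001100001]``."""
        return "[" + "".join(self.to_rows()) + "]"

    def to_csv(self) -> str:
        return "\n".join(",".join(str(int(v)) for v in row)
                         for row in self.entries) + "\n"

    def __eq__(self, other):
        return (isinstance(other, TransitionMatrix) and self.n == other.n
                and np.array_equal(self.entries, other.entries))

    def __hash__(self):
        return hash((self.n, np.packbits(self.entries).tobytes()))


def build_integer_map(net: BooleanNetwork, cap: int = STATE_SPACE_CAP) -> IntegerMap:
    """One synchronous step for every state, as an integer index table.

    All ``2^n`` states are evaluated at once: each node variable becomes a
    bit-sliced array over the enumerated state space and the rule ASTs are
    evaluated vectorized.
    """
    n = net.n
    check_cap(n, cap)
    states = np.arange(1 << n, dtype=np.int64)
    bits = tuple(((states >> (n - 1 - i)) & 1) for i in range(n))
    image = np.zeros(1 << n, dtype=np.int64)
    for i, rule in enumerate(net.rules):
        col = rule.evaluate(bits)
        # constant rules evaluate to a scalar
        col = np.broadcast_to(np.asarray(col, dtype=np.int64), states.shape)
        image |= col << (n - 1 - i)
    return IntegerMap(n, image)


def map_to_matrix(m: IntegerMap) -> TransitionMatrix:
    """Functional 0/1 matrix of a map: ``entry[m(w), w] = 1``."""
    size = m.size
    entries = np.zeros((size, size), dtype=bool)
    entries[m.image, np.arange(size)] = True
    return TransitionMatrix(m.n, entries)


def matrix_to_map(M: TransitionMatrix) -> IntegerMap:
    """Inverse of :func:`map_to_matrix`; requires a functional matrix."""
    if not M.is_functional():
        raise ValueError("matrix is not functional (one 1 per column required)")
    return IntegerMap(M.n, np.argmax(M.entries, axis=0).astype(np.int64))


def compose_maps(g: IntegerMap, f: IntegerMap) -> IntegerMap:
    """``g`` after ``f``: the map ``w -> g(f(w))``."""
    if g.n != f.n:
        raise ValueError("dimension mismatch")
    return IntegerMap(g.n, g.image[f.image])


def matrix_power(M: TransitionMatrix, t: int) -> TransitionMatrix:
    """Boolean-semiring power ``M^t`` (``M^0`` is the identity).

    For functional matrices this goes through the integer map, so the cost
    is ``O(2^n log t)`` instead of dense matrix products.
    """
    if t < 0:
        raise ValueError("power must be non-negative")
    if M.is_functional():
        return map_to_matrix(matrix_to_map(M).power(t))
    result = TransitionMatrix(M.n, np.eye(M.size, dtype=bool))
    base = M
    while t:
        if t & 1:
            result = result.matmul(base)
        base = base.matmul(base)
        t >>= 1
    return result


def trajectory(m: IntegerMap, u0: int, t_max: int) -> list[int]:
    """The orbit ``[u0, m(u0), m^2(u0), ...]`` of length ``t_max + 1``."""
    if not 0 <= u0 < m.size:
        raise ValueError(f"initial state {u0} out of range")
    out = [u0]
    w = u0
    for _ in range(t_max):
        w = int(m.image[w])
        out.append(w)
    return out
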