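"""Synchronous attractor landscapes via Boolean-semiring matrix powers.

Iterating the one-step transition matrix is the Chapman-Kolmogorov power
equation ``S(t) = M^t``; the synchronous scheme is thereby a degenerate
Markov chain whose jump probabilities are all 0 or 1.  Two regimes arise:

* fixed-point-only systems — the powers converge, and the stationary matrix
  ``S* = lim S(t)`` read column-wise IS the attractor landscape: a function
  pairing each initial state with its fixed point;
* systems with cycles — the powers become periodic after a transient, and
  the landscape is the entrywise logical OR of ``S(t)`` over one full
  period, a relation pairing each initial state with every state of the
  orbit it reaches.

The limit is detected exactly by hashing successive powers of the
underlying integer map until they repeat (the transient is at most ``2^n``),
not by evaluating the power at some large fixed ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attractors import AttractorAnalysis, analyze_map
from .statemap import IntegerMap, TransitionMatrix, map_to_matrix, matrix_to_map

__all__ = [
    "Landscape",
    "PowerOrbit",
    "power_orbit",
    "stationary_landscape",
    "landscape_relation",
    "landscape_from_analysis",
]


@dataclass(frozen=True)
class Landscape:
    """Relation pairing each initial state with its attractor state(s).

    ``entries[i, j] = 1`` iff initial state ``j`` reaches attractor state
    ``i`` — same column-is-source convention as the transition matrix.
    """

    n: int
    entries: np.ndarray  # bool, shape (2**n, 2**n)

    def __post_init__(self):
        entries = np.asarray(self.entries, dtype=bool)
        object.__setattr__(self, "entries", entries)
        size = 1 << self.n
        if entries.shape != (size, size):
            raise ValueError("landscape matrix has the wrong shape")
        if not entries.any(axis=0).all():
            raise ValueError("every initial state needs at least one image")

    @property
    def size(self) -> int:
        return 1 << self.n

    @property
    def matrix(self) -> TransitionMatrix:
        return TransitionMatrix(self.n, self.entries)

    def pairs(self) -> list[tuple[int, int]]:
        """Sorted ``(initial_state, attractor_state)`` pairs."""
        rows, cols = np.nonzero(self.entries)
        return sorted(zip(cols.tolist(), rows.tolist()))

    def is_function(self) -> bool:
        """True when every initial state has exactly one image (fixed-point
        only systems)."""
        return bool((self.entries.sum(axis=0) == 1).all())

    def as_map(self) -> IntegerMap:
        """The landscape as an integer map; requires a functional landscape."""
        if not self.is_function():
            raise ValueError("landscape with cyclic attractors is a relation, "
                             "not a function")
        return IntegerMap(self.n, np.argmax(self.entries, axis=0).astype(np.int64))

    def to_csv(self) -> str:
        """Two-column CSV of the Cartesian-plane plot data."""
        lines = ["initial_state,attractor_state"]
        lines += [f"{u},{v}" for u, v in self.pairs()]
        return "\n".join(lines) + "\n"

    def __eq__(self, other):
        return (isinstance(other, Landscape) and self.n == other.n
                and np.array_equal(self.entries, other.entries))

    def __hash__(self):
        return hash((self.n, np.packbits(self.entries).tobytes()))


@dataclass(frozen=True)
class PowerOrbit:
    """Eventual periodicity of the matrix powers: ``M^(T0 + p) = M^(T0)``."""

    transient: int
    period: int
    window: tuple[IntegerMap, ...]  # the maps f^t for t in {T0 .. T0+p-1}


def power_orbit(M: TransitionMatrix | IntegerMap) -> PowerOrbit:
    """Least transient ``T0`` and period ``p`` of the powers of ``M``.

    Computed on the integer map: successive powers are hashed until one
    repeats, which happens after at most ``2^n + p`` steps.
    """
    m = M if isinstance(M, IntegerMap) else matrix_to_map(M)
    seen: dict[bytes, int] = {}
    powers: list[IntegerMap] = []
    current = IntegerMap(m.n, np.arange(m.size, dtype=np.int64))  # f^0
    t = 0
    while True:
        key = current.image.tobytes()
        if key in seen:
            t0 = seen[key]
            period = t - t0
            return PowerOrbit(t0, period, tuple(powers[t0:t0 + period]))
        seen[key] = t
        powers.append(current)
        current = IntegerMap(m.n, m.image[current.image])
        t += 1


def stationary_landscape(M: TransitionMatrix | IntegerMap) -> Landscape:
    """The attractor landscape from the limit of the matrix powers.

    Period 1 gives the stationary matrix itself; otherwise the entrywise OR
    of ``M^t`` over one full period at/after the transient.
    """
    m = M if isinstance(M, IntegerMap) else matrix_to_map(M)
    orbit = power_orbit(m)
    entries = np.zeros((m.size, m.size), dtype=bool)
    for f_t in orbit.window:
        entries |= map_to_matrix(f_t).entries
    return Landscape(m.n, entries)


def landscape_relation(L: Landscape) -> list[tuple[int, int]]:
    """The landscape as sorted ``(initial, attractor-state)`` pairs; a
    function for fixed-point-only systems, a relation otherwise."""
    return L.pairs()


def landscape_from_analysis(analysis: AttractorAnalysis) -> Landscape:
    """Independent landscape construction from the functional-graph
    decomposition: each state is paired with every state of its attractor's
    orbit (used as the oracle cross-check for the matrix route)."""
    size = analysis.map.size
    entries = np.zeros((size, size), dtype=bool)
    for w in range(size):
        for c in analysis.attractors[analysis.assignment[w]].orbit:
            entries[c, w] = True
    return Landscape(analysis.map.n, entries)
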