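"""Attractor and basin analysis on the functional graph of an integer map.

Every total map on a finite state space decomposes into cycles plus trees
hanging off them: the cycles are the attractors (fixed points are cycles of
length 1, and are exactly the reflexive pairs ``(w, w)`` of the map), and
the tree feeding each cycle is its basin of attraction.  Basins partition
the state space.

Detection is a single iterative traversal with state coloring — each state
is walked at most twice, so the overall cost is ``O(2^n)`` — rather than
repeated map composition, which gives the same answer at bounded cost.
The traversal also records each state's transient length (distance to its
attractor orbit), which the canonical-form compaction step reuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .statemap import IntegerMap

__all__ = [
    "Attractor",
    "BasinMap",
    "AttractorAnalysis",
    "analyze_map",
    "find_fixed_points",
    "find_cycles",
    "compute_basins",
    "orbit_relation",
    "verify_union_decomposition",
]


@dataclass(frozen=True)
class Attractor:
    """A fixed point or cyclic orbit, canonically rotated to start at its
    minimal integer state."""

    orbit: tuple[int, ...]

    def __post_init__(self):
        if not self.orbit:
            raise ValueError("an attractor orbit cannot be empty")
        lo = self.orbit.index(min(self.orbit))
        object.__setattr__(self, "orbit", self.orbit[lo:] + self.orbit[:lo])

    @property
    def kind(self) -> str:
        return "fixed" if len(self.orbit) == 1 else "cyclic"

    @property
    def period(self) -> int:
        return len(self.orbit)

    def __repr__(self):
        return f"Attractor{self.orbit}"


@dataclass
class BasinMap:
    """Assignment of every state to its attractor; basins partition Ω."""

    attractors: list[Attractor]
    assignment: np.ndarray  # attractor index per state

    @property
    def basins(self) -> list[list[int]]:
        return [sorted(np.nonzero(self.assignment == k)[0].tolist())
                for k in range(len(self.attractors))]

    def basin_of(self, a: Attractor) -> list[int]:
        return self.basins[self.attractors.index(a)]

    def basin_sizes(self) -> list[int]:
        return [int((self.assignment == k).sum()) for k in range(len(self.attractors))]


@dataclass
class AttractorAnalysis:
    """Full functional-graph decomposition of a map."""

    map: IntegerMap
    attractors: list[Attractor]
    assignment: np.ndarray   # attractor index per state
    transient: np.ndarray    # steps until the trajectory enters its orbit

    @property
    def basin_map(self) -> BasinMap:
        return BasinMap(self.attractors, self.assignment)

    @property
    def max_transient(self) -> int:
        return int(self.transient.max()) if self.transient.size else 0

    def landscape_pairs(self) -> list[tuple[int, int]]:
        """Each initial state paired with every state of its attractor orbit."""
        pairs = []
        for w in range(self.map.size):
            for c in self.attractors[self.assignment[w]].orbit:
                pairs.append((w, c))
        return sorted(pairs)

    def signature(self):
        """Hashable landscape identity: orbit state-sets plus the per-state
        assignment.

        The landscape pairs each basin element with every orbit state, so an
        attractor's identity is its set of states; the traversal order within
        a cycle is not part of the landscape."""
        orbits = tuple(tuple(sorted(a.orbit)) for a in self.attractors)
        return orbits, self.assignment.tobytes()


def analyze_map(m: IntegerMap) -> AttractorAnalysis:
    """Detect all cycles, basins and transient lengths of a map."""
    size = m.size
    image = m.image
    assignment = np.full(size, -1, dtype=np.int64)
    transient = np.zeros(size, dtype=np.int64)
    # position of a state within the walk currently being explored; -1 = not
    # on the current walk (fresh walks bump the epoch instead of clearing)
    walk_pos = np.full(size, -1, dtype=np.int64)
    attractors: list[Attractor] = []

    for start in range(size):
        if assignment[start] >= 0:
            continue
        path = []
        w = start
        while assignment[w] < 0 and walk_pos[w] < 0:
            walk_pos[w] = len(path)
            path.append(w)
            w = int(image[w])
        if assignment[w] >= 0:
            # ran into an already-resolved region
            attr = int(assignment[w])
            base = int(transient[w])
            cut = len(path)
        else:
            # closed a new cycle within the current walk
            cut = int(walk_pos[w])
            orbit = tuple(path[cut:])
            attr = len(attractors)
            attractors.append(Attractor(orbit))
            for c in orbit:
                assignment[c] = attr
                transient[c] = 0
            base = 0
        for depth, state in enumerate(reversed(path[:cut]), start=1):
            assignment[state] = attr
            transient[state] = base + depth
        for state in path:
            walk_pos[state] = -1

    # stable report order: attractors sorted by minimal orbit element
    order = sorted(range(len(attractors)), key=lambda k: attractors[k].orbit[0])
    relabel = np.empty(len(attractors), dtype=np.int64)
    for new, old in enumerate(order):
        relabel[old] = new
    return AttractorAnalysis(
        map=m,
        attractors=[attractors[k] for k in order],
        assignment=relabel[assignment],
        transient=transient,
    )


def find_fixed_points(m: IntegerMap) -> set[int]:
    """The reflexive states ``{w : m(w) = w}`` — the fixed-point attractors."""
    states = np.arange(m.size, dtype=np.int64)
    return set(states[m.image == states].tolist())


def find_cycles(m: IntegerMap) -> list[Attractor]:
    """All cycles of the functional graph, fixed points included, sorted by
    minimal orbit element."""
    return analyze_map(m).attractors


def compute_basins(m: IntegerMap, attractors: list[Attractor]) -> BasinMap:
    """Partition the state space into basins of the given attractors.

    ``attractors`` must be exactly the cycles of ``m`` (in any order); the
    result uses the caller's order.
    """
    analysis = analyze_map(m)
    found = {a.orbit: k for k, a in enumerate(analysis.attractors)}
    if sorted(found) != sorted(a.orbit for a in attractors):
        raise ValueError("attractor list is inconsistent with the map's cycles")
    relabel = np.empty(len(attractors), dtype=np.int64)
    for new, a in enumerate(attractors):
        relabel[found[a.orbit]] = new
    return BasinMap(list(attractors), relabel[analysis.assignment])


def orbit_relation(a: Attractor, basin) -> set[tuple[int, int]]:
    """The complete bipartite relation basin x orbit.

    In the long-time limit every basin element visits every orbit state, so
    the landscape restricted to one cyclic attractor is this full relation.
    """
    return {(b, c) for b in basin for c in a.orbit}


def verify_union_decomposition(a: Attractor) -> bool:
    """Check that the orbit relation is the union of powers of the successor.

    With ``f`` the successor function on an orbit of period ``L``, the union
    ``f ∪ f^2 ∪ ... ∪ f^L`` must equal orbit x orbit — a cyclic attractor is
    generated by composing a single compatible function.
    """
    L = a.period
    succ = {a.orbit[k]: a.orbit[(k + 1) % L] for k in range(L)}
    union: set[tuple[int, int]] = set()
    current = dict(succ)
    for _ in range(L):
        union |= set(current.items())
        current = {w: succ[v] for w, v in current.items()}
    return union == {(u, v) for u in a.orbit for v in a.orbit}
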