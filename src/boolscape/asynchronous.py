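"""Deterministic periodic asynchronous updating.

Instead of updating every node at every step, each node ``i`` carries an
update period ``tau_i`` and is refreshed only at steps ``t`` with
``t mod tau_i = 0`` (steps are 1-based); alternatively an explicit cyclic
list of update subsets can be given.  Each step therefore applies a
*subset-update function*: the chosen nodes compute their rules while all
other bits are copied.  Over one hyperperiod (the lcm of the periods, or
the length of the explicit list) the composition of the step functions is a
single map ``G``, and the asynchronous attractors/basins are defined as the
attractors of ``G``.

Two headline properties fall out of the composition view:

* every synchronous fixed point is fixed under every subset-update
  function, hence under ``G`` — fixed points are invariant to the schedule;
* cyclic attractors and basin boundaries are not: they can disappear or be
  reshaped by the update order, and because composition is not commutative
  no unique canonical form exists for asynchronous systems.  This module
  therefore only reports landscapes and differences, never a canonical form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import reduce

import numpy as np

from .attractors import Attractor, AttractorAnalysis, analyze_map
from .network import BooleanNetwork, STATE_SPACE_CAP, check_cap
from .statemap import IntegerMap, build_integer_map, compose_maps
from .sync import Landscape, landscape_from_analysis

__all__ = [
    "UpdateSchedule",
    "subset_update_map",
    "schedule_steps",
    "hyperperiod_map",
    "AsyncResult",
    "async_landscape",
    "compare_schedules",
]


@dataclass(frozen=True)
class UpdateSchedule:
    """Node update periods, or an explicit cyclic list of update subsets."""

    periods: tuple[int, ...] | None = None
    explicit: tuple[frozenset[int], ...] | None = None

    def __post_init__(self):
        if (self.periods is None) == (self.explicit is None):
            raise ValueError("give either periods or an explicit subset list")
        if self.periods is not None:
            object.__setattr__(self, "periods", tuple(int(t) for t in self.periods))
            if any(t < 1 for t in self.periods):
                raise ValueError("update periods must be >= 1")
        else:
            object.__setattr__(
                self, "explicit",
                tuple(frozenset(int(i) for i in s) for s in self.explicit))
            if len(self.explicit) == 0:
                raise ValueError("explicit schedule cannot be empty")

    @classmethod
    def from_periods(cls, *periods: int) -> "UpdateSchedule":
        return cls(periods=tuple(periods))

    @classmethod
    def from_subsets(cls, subsets) -> "UpdateSchedule":
        return cls(explicit=tuple(frozenset(s) for s in subsets))

    @classmethod
    def synchronous(cls, n: int) -> "UpdateSchedule":
        return cls(periods=(1,) * n)

    @property
    def hyperperiod(self) -> int:
        if self.explicit is not None:
            return len(self.explicit)
        return math.lcm(*self.periods)

    def subsets(self, n: int) -> list[frozenset[int]]:
        """The update subset at each step ``1 .. hyperperiod``."""
        if self.explicit is not None:
            for s in self.explicit:
                if any(not 0 <= i < n for i in s):
                    raise ValueError("subset refers to a node out of range")
            return list(self.explicit)
        if len(self.periods) != n:
            raise ValueError("one period per node is required")
        return [frozenset(i for i, tau in enumerate(self.periods) if t % tau == 0)
                for t in range(1, self.hyperperiod + 1)]


def subset_update_map(net: BooleanNetwork, subset,
                      cap: int = STATE_SPACE_CAP) -> IntegerMap:
    """One step updating only ``subset``'s nodes; all other bits are copied."""
    n = net.n
    check_cap(n, cap)
    subset = frozenset(subset)
    if any(not 0 <= i < n for i in subset):
        raise IndexError("subset refers to a node out of range")
    states = np.arange(1 << n, dtype=np.int64)
    bits = tuple(((states >> (n - 1 - i)) & 1) for i in range(n))
    image = np.zeros(1 << n, dtype=np.int64)
    for i in range(n):
        if i in subset:
            col = np.broadcast_to(
                np.asarray(net.rules[i].evaluate(bits), dtype=np.int64),
                states.shape)
        else:
            col = bits[i]
        image = image | (col << (n - 1 - i))
    return IntegerMap(n, image)


def schedule_steps(sched: UpdateSchedule, net: BooleanNetwork,
                   cap: int = STATE_SPACE_CAP) -> list[IntegerMap]:
    """The subset-update function applied at each step of one hyperperiod."""
    return [subset_update_map(net, s, cap=cap) for s in sched.subsets(net.n)]


def hyperperiod_map(net: BooleanNetwork, sched: UpdateSchedule,
                    cap: int = STATE_SPACE_CAP) -> IntegerMap:
    """Composition of the step functions in step order (step 1 applied first)."""
    steps = schedule_steps(sched, net, cap=cap)
    return reduce(lambda acc, f: compose_maps(f, acc), steps[1:], steps[0])


@dataclass
class AsyncResult:
    """Attractor landscape of the hyperperiod map, with the synchronous
    comparison attached."""

    schedule: UpdateSchedule
    map: IntegerMap
    analysis: AttractorAnalysis
    sync_analysis: AttractorAnalysis

    @property
    def attractors(self) -> list[Attractor]:
        return self.analysis.attractors

    @property
    def basin_map(self):
        return self.analysis.basin_map

    @property
    def landscape(self) -> Landscape:
        return landscape_from_analysis(self.analysis)

    @property
    def preserved_attractors(self) -> list[Attractor]:
        sync = {a.orbit for a in self.sync_analysis.attractors}
        return [a for a in self.attractors if a.orbit in sync]

    @property
    def lost_attractors(self) -> list[Attractor]:
        """Synchronous attractors absent from the asynchronous landscape."""
        mine = {a.orbit for a in self.attractors}
        return [a for a in self.sync_analysis.attractors if a.orbit not in mine]

    def report(self) -> dict:
        return {
            "attractors": [list(a.orbit) for a in self.attractors],
            "basin_sizes": self.basin_map.basin_sizes(),
            "preserved_from_synchronous": [list(a.orbit)
                                           for a in self.preserved_attractors],
            "lost_from_synchronous": [list(a.orbit) for a in self.lost_attractors],
        }


def async_landscape(net: BooleanNetwork, sched: UpdateSchedule,
                    cap: int = STATE_SPACE_CAP) -> AsyncResult:
    """Solve the asynchronous system defined by a schedule.

    Builds the hyperperiod map ``G`` and analyses its functional graph;
    the synchronous analysis is attached for the preserved/lost report.
    """
    G = hyperperiod_map(net, sched, cap=cap)
    sync_analysis = analyze_map(build_integer_map(net, cap=cap))
    return AsyncResult(sched, G, analyze_map(G), sync_analysis)


def compare_schedules(net: BooleanNetwork, s1: UpdateSchedule,
                      s2: UpdateSchedule, cap: int = STATE_SPACE_CAP) -> dict:
    """Attractors preserved/lost and basin-size changes between two schedules."""
    r1 = async_landscape(net, s1, cap=cap)
    r2 = async_landscape(net, s2, cap=cap)
    orbits1 = {a.orbit for a in r1.attractors}
    orbits2 = {a.orbit for a in r2.attractors}
    shared = sorted(orbits1 & orbits2)
    sizes1 = {a.orbit: s for a, s in zip(r1.attractors, r1.basin_map.basin_sizes())}
    sizes2 = {a.orbit: s for a, s in zip(r2.attractors, r2.basin_map.basin_sizes())}
    return {
        "shared_attractors": [list(o) for o in shared],
        "only_in_first": [list(o) for o in sorted(orbits1 - orbits2)],
        "only_in_second": [list(o) for o in sorted(orbits2 - orbits1)],
        "basin_size_changes": {
            str(list(o)): [sizes1[o], sizes2[o]]
            for o in shared if sizes1[o] != sizes2[o]
        },
        "identical_landscape": bool(
            r1.analysis.signature() == r2.analysis.signature()),
    }
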