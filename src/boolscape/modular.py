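"""Modular solving of large networks via per-module semi-attractors.

For networks far beyond exhaustive reach, the state space is tamed by
partitioning the nodes into modules whose inter-module dependency graph is
acyclic.  Processing modules in topological order:

1. each module's external inputs are frozen at the values they take in the
   upstream modules' semi-attractors, and the module's *semi-attractors*
   (fixed states of the frozen module map) are collected over all upstream
   input combinations;
2. candidate global attractors are the cross product of per-module
   semi-attractor sets, concatenated in node order;
3. candidates are validated on the full network: a candidate survives iff
   every rule reproduces it (``F(s) = s``), which needs only one rule sweep
   per candidate — no full state-space enumeration;
4. basin sizes follow from the frozen modules' canonical forms: if every
   module's settled state depends only on a small set of *driver*
   variables ``D``, each validated attractor is reached from exactly
   ``2^(n - |D|)`` initial configurations, namely all states sharing its
   driver assignment.

Step 4 is reported together with its validity condition; when a frozen
module has cyclic attractors, or the attractor set does not factor through
the drivers, the count is refused rather than guessed.  Cyclic
semi-attractors are likewise unsupported: only fixed states are joined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from itertools import product

import numpy as np

from .network import (BoolExpr, BooleanNetwork, Const, Not, And, Or,
                      STATE_SPACE_CAP, Var, check_cap)
from .statemap import IntegerMap

__all__ = [
    "ModulePartition",
    "SemiAttractorSet",
    "ModularError",
    "consecutive_blocks",
    "validate_partition",
    "frozen_module_map",
    "frozen_module_network",
    "module_semi_attractors",
    "join_candidates",
    "validate_candidates",
    "basin_size_by_support",
    "BasinReport",
    "modular_solve",
    "ModularResult",
]


class ModularError(ValueError):
    """A modular-procedure precondition failed (cyclic dependency, empty
    semi-attractor set, or a basin count that support counting cannot give)."""


@dataclass(frozen=True)
class ModulePartition:
    """Disjoint node-index modules with an acyclic dependency structure."""

    modules: tuple[tuple[int, ...], ...]
    #: per module, the set of upstream module indices it reads from
    upstream: tuple[frozenset[int], ...]
    #: a topological order of the module indices
    topo_order: tuple[int, ...]

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def module_of(self, node: int) -> int:
        for k, mod in enumerate(self.modules):
            if node in mod:
                return k
        raise KeyError(node)

    def external_inputs(self, net: BooleanNetwork, k: int) -> tuple[int, ...]:
        """Global indices read by module ``k``'s rules but owned elsewhere."""
        own = set(self.modules[k])
        used: set[int] = set()
        for i in self.modules[k]:
            used |= net.rules[i].variables()
        return tuple(sorted(used - own))


def consecutive_blocks(net: BooleanNetwork, block_size: int) -> list[list[int]]:
    """Partition node indices into consecutive blocks of ``block_size``."""
    if block_size < 1:
        raise ValueError("block size must be >= 1")
    return [list(range(i, min(i + block_size, net.n)))
            for i in range(0, net.n, block_size)]


def validate_partition(net: BooleanNetwork, assignment) -> ModulePartition:
    """Check a module assignment and derive its dependency DAG.

    ``assignment`` is a list of node-index lists (or a ``{node_name:
    module_id}`` mapping).  Modules must be disjoint, cover every node, and
    must not depend on each other cyclically.
    """
    if isinstance(assignment, dict):
        by_mod: dict[int, list[int]] = {}
        index = {name: i for i, name in enumerate(net.nodes)}
        for name, mod in assignment.items():
            by_mod.setdefault(int(mod), []).append(index[name])
        modules = [sorted(by_mod[k]) for k in sorted(by_mod)]
    else:
        modules = [sorted(int(i) for i in mod) for mod in assignment]
    flat = [i for mod in modules for i in mod]
    if sorted(flat) != list(range(net.n)) or len(set(flat)) != len(flat):
        raise ModularError("modules must partition the node set")
    owner = {}
    for k, mod in enumerate(modules):
        for i in mod:
            owner[i] = k
    upstream = []
    for k, mod in enumerate(modules):
        ups = set()
        for i in mod:
            for v in net.rules[i].variables():
                if owner[v] != k:
                    ups.add(owner[v])
        upstream.append(frozenset(ups))
    try:
        topo = tuple(TopologicalSorter(
            {k: set(upstream[k]) for k in range(len(modules))}).static_order())
    except CycleError as exc:
        raise ModularError(
            "modules have a cyclic inter-module dependency; only acyclic "
            "partitions are supported") from exc
    return ModulePartition(tuple(tuple(m) for m in modules),
                           tuple(upstream), topo)


def _module_bits(net: BooleanNetwork, module: tuple[int, ...],
                 frozen: dict[int, int]):
    """Bit arrays (indexed by *global* node index) over the module's local
    state space, with external inputs clamped to constants."""
    k = len(module)
    states = np.arange(1 << k, dtype=np.int64)
    bits: list = [None] * net.n
    for local, g in enumerate(module):
        bits[g] = (states >> (k - 1 - local)) & 1
    for g, v in frozen.items():
        bits[g] = np.int64(v)
    return states, bits


def frozen_module_map(net: BooleanNetwork, module, frozen: dict[int, int],
                      cap: int = STATE_SPACE_CAP) -> IntegerMap:
    """The module's one-step map over its local states, with its external
    inputs clamped to the given constants."""
    module = tuple(module)
    k = len(module)
    check_cap(k, cap)
    states, bits = _module_bits(net, module, frozen)
    image = np.zeros(1 << k, dtype=np.int64)
    for local, g in enumerate(module):
        col = np.broadcast_to(
            np.asarray(net.rules[g].evaluate(bits), dtype=np.int64),
            states.shape)
        image |= col << (k - 1 - local)
    return IntegerMap(k, image)


def _substitute(expr: BoolExpr, mapping: dict[int, BoolExpr]) -> BoolExpr:
    if isinstance(expr, Var):
        return mapping[expr.index]
    if isinstance(expr, Not):
        return Not(_substitute(expr.operand, mapping))
    if isinstance(expr, And):
        return And(tuple(_substitute(op, mapping) for op in expr.operands))
    if isinstance(expr, Or):
        return Or(tuple(_substitute(op, mapping) for op in expr.operands))
    return expr


def frozen_module_network(net: BooleanNetwork, module,
                          frozen: dict[int, int]) -> BooleanNetwork:
    """A standalone network for one module, external inputs substituted by
    constants — the object whose canonical form the basin analysis uses."""
    module = tuple(module)
    mapping: dict[int, BoolExpr] = {g: Var(local) for local, g in enumerate(module)}
    mapping.update({g: Const(v) for g, v in frozen.items()})
    rules = [_substitute(net.rules[g], mapping) for g in module]
    return BooleanNetwork([net.nodes[g] for g in module], rules)


@dataclass
class SemiAttractorSet:
    """Per-module fixed states under frozen upstream inputs.

    ``states[k]`` is the union over input combinations; ``by_input[k]``
    keeps the provenance: frozen-input assignment -> fixed local states
    (bit tuples over the module's nodes, module order).
    """

    partition: ModulePartition
    states: list[list[tuple[int, ...]]]
    by_input: list[dict[tuple[tuple[int, int], ...], list[tuple[int, ...]]]]

    def counts(self) -> list[int]:
        return [len(s) for s in self.states]


def module_semi_attractors(net: BooleanNetwork, part: ModulePartition,
                           cap: int = STATE_SPACE_CAP) -> SemiAttractorSet:
    """Fixed states of every module under every upstream input combination.

    Modules are processed in topological order; the input combinations of a
    module are the cross product of its upstream modules' semi-attractors,
    restricted to the variables the module actually reads.
    """
    n_mod = part.n_modules
    states: list[list[tuple[int, ...]] | None] = [None] * n_mod
    by_input: list[dict | None] = [None] * n_mod
    for k in part.topo_order:
        module = part.modules[k]
        width = len(module)
        check_cap(width, cap)
        ext = part.external_inputs(net, k)
        # distinct frozen-input vectors drawn from upstream semi-attractors
        if ext:
            feeders = sorted({part.module_of(g) for g in ext})
            combos: set[tuple[int, ...]] = set()
            for choice in product(*(states[f] for f in feeders)):
                value = {}
                for f, local_state in zip(feeders, choice):
                    for local, g in enumerate(part.modules[f]):
                        value[g] = local_state[local]
                combos.add(tuple(value[g] for g in ext))
            inputs = sorted(combos)
        else:
            inputs = [()]
        seen: dict[tuple[tuple[int, int], ...], list[tuple[int, ...]]] = {}
        union: set[tuple[int, ...]] = set()
        for vec in inputs:
            frozen = dict(zip(ext, vec))
            m = frozen_module_map(net, module, frozen, cap=cap)
            idx = np.arange(m.size, dtype=np.int64)
            fixed = idx[m.image == idx]
            locals_ = [tuple(int((w >> (width - 1 - j)) & 1)
                             for j in range(width)) for w in fixed.tolist()]
            seen[tuple(sorted(frozen.items()))] = sorted(locals_)
            union |= set(locals_)
        states[k] = sorted(union)
        by_input[k] = seen
    return SemiAttractorSet(part, [s for s in states], [b for b in by_input])


def join_candidates(semis: SemiAttractorSet) -> list[tuple[int, ...]]:
    """Cross product of per-module semi-attractors, concatenated in node
    order, as full-network candidate states (bit tuples)."""
    part = semis.partition
    n = sum(len(m) for m in part.modules)
    for k, s in enumerate(semis.states):
        if not s:
            raise ModularError(f"module {k} has no semi-attractor; the frozen "
                               "module has no fixed state (cyclic semi-"
                               "attractors are unsupported)")
    out = []
    for choice in product(*semis.states):
        full = [0] * n
        for mod, local_state in zip(part.modules, choice):
            for local, g in enumerate(mod):
                full[g] = local_state[local]
        out.append(tuple(full))
    return out


def validate_candidates(net: BooleanNetwork,
                        candidates) -> list[tuple[int, ...]]:
    """Keep exactly the candidates with ``F(s) = s`` on the full network.

    All candidates are checked in one vectorized rule sweep (one array per
    node over the candidate axis).
    """
    candidates = list(candidates)
    if not candidates:
        return []
    arr = np.asarray(candidates, dtype=np.int64)  # (n_candidates, n)
    bits = tuple(arr[:, i] for i in range(net.n))
    keep = np.ones(len(candidates), dtype=bool)
    for i in range(net.n):
        col = np.broadcast_to(
            np.asarray(net.rules[i].evaluate(bits), dtype=np.int64),
            (len(candidates),))
        keep &= col == arr[:, i]
    return [candidates[j] for j in np.nonzero(keep)[0]]


@dataclass
class BasinReport:
    """Basin sizes derived from the drivers of the module canonical forms."""

    drivers: tuple[int, ...]              # global node indices
    driver_names: tuple[str, ...]
    basin_size: int                       # per attractor: 2^(n - |drivers|)
    conditions: list[dict[str, int]]      # per attractor, driver assignment
    attractors: list[tuple[int, ...]]

    def total(self) -> int:
        return self.basin_size * len(self.attractors)

    def to_json_dict(self) -> dict:
        return {
            "drivers": list(self.driver_names),
            "basin_size": self.basin_size,
            "attractors": ["".join(map(str, a)) for a in self.attractors],
            "conditions": self.conditions,
        }


def _settled_map(net, module, frozen, cap) -> np.ndarray | None:
    """Image table of the settled (compacted) frozen-module map, or ``None``
    when a cyclic attractor survives freezing.

    Uses pointer doubling: ``m^(2^k)`` with ``2^k >= 2^width`` exceeds every
    transient, so its image is exactly the set of orbit states.  When all of
    those are reflexive the module is fixed-point-only and the doubled map
    already sends every state to its fixed point."""
    m = frozen_module_map(net, module, frozen, cap=cap)
    settled = m.power(m.size)
    orbit_states = np.unique(settled.image)
    if not (m.image[orbit_states] == orbit_states).all():
        return None
    return settled.image


def _support(settled_image: np.ndarray, width: int) -> set[int]:
    """Local variables the settled map actually depends on.

    Exact minimization keeps a variable iff the function depends on it, so
    this is the union of the supports of the module's canonical-form rules:
    variable ``j`` is in the support iff flipping bit ``j`` of the input
    changes any output bit."""
    idx = np.arange(settled_image.size)
    support = set()
    for j in range(width):
        flipped = settled_image[idx ^ (1 << (width - 1 - j))]
        if (settled_image != flipped).any():
            support.add(j)
    return support


def basin_size_by_support(net: BooleanNetwork, part: ModulePartition,
                          semis: SemiAttractorSet | None = None,
                          cap: int = STATE_SPACE_CAP) -> BasinReport:
    """Basin sizes from the driver variables of the module canonical forms.

    Each frozen module's settled state is an exact function of a support
    set of local variables (plus its inputs); drivers accumulate through
    the dependency DAG.  With ``D`` the union of driver variables, every
    validated attractor is reached from the ``2^(n - |D|)`` states sharing
    its driver assignment — valid only when each driver assignment selects
    exactly one attractor, which is verified before reporting.
    """
    if semis is None:
        semis = module_semi_attractors(net, part, cap=cap)
    drivers: dict[int, set[int]] = {}
    for k in part.topo_order:
        module = part.modules[k]
        width = len(module)
        local_support: set[int] = set()
        settled_by_input = {}
        for key in semis.by_input[k]:
            settled = _settled_map(net, module, dict(key), cap)
            if settled is None:
                raise ModularError(
                    f"module {k} has a cyclic attractor under frozen inputs "
                    f"{dict(key)}; basin counting by support is not defined")
            settled_by_input[key] = settled
            local_support |= _support(settled, width)
        mod_drivers = {module[j] for j in local_support}
        # does the settled behaviour depend on the frozen input values?
        keys = sorted(settled_by_input)
        input_dependent: set[int] = set()
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                if not np.array_equal(settled_by_input[keys[a]],
                                      settled_by_input[keys[b]]):
                    diff = {g for (g, va), (h, vb) in
                            zip(keys[a], keys[b]) if va != vb}
                    input_dependent |= diff
        for g in input_dependent:
            drivers_of_feeder = drivers[part.module_of(g)]
            mod_drivers |= drivers_of_feeder
        drivers[k] = mod_drivers

    D = tuple(sorted(set().union(*drivers.values()) if drivers else set()))
    attractors = validate_candidates(net, join_candidates(semis))
    restrictions = [tuple(a[g] for g in D) for a in attractors]
    if len(set(restrictions)) != len(attractors) or len(attractors) != 2 ** len(D):
        raise ModularError(
            "attractor set does not factor through the driver variables; "
            "basin sizes are not computable by support counting")
    return BasinReport(
        drivers=D,
        driver_names=tuple(net.nodes[g] for g in D),
        basin_size=2 ** (net.n - len(D)),
        conditions=[{net.nodes[g]: int(a[g]) for g in D} for a in attractors],
        attractors=attractors,
    )


@dataclass
class ModularResult:
    """End-to-end result of the modular procedure."""

    partition: ModulePartition
    semi_attractors: SemiAttractorSet
    candidates: list[tuple[int, ...]]
    attractors: list[tuple[int, ...]]
    basin_report: BasinReport | None

    def to_json_dict(self) -> dict:
        return {
            "modules": [list(m) for m in self.partition.modules],
            "semi_attractor_counts": self.semi_attractors.counts(),
            "n_candidates": len(self.candidates),
            "attractors": ["".join(map(str, a)) for a in self.attractors],
            "basins": (self.basin_report.to_json_dict()
                       if self.basin_report else None),
        }


def modular_solve(net: BooleanNetwork, assignment,
                  basins: bool = True,
                  cap: int = STATE_SPACE_CAP) -> ModularResult:
    """Full pipeline: partition -> semi-attractors -> join -> validate
    (-> basin counting)."""
    part = validate_partition(net, assignment)
    semis = module_semi_attractors(net, part, cap=cap)
    candidates = join_candidates(semis)
    attractors = validate_candidates(net, candidates)
    report = None
    if basins:
        try:
            report = basin_size_by_support(net, part, semis, cap=cap)
        except ModularError:
            report = None
    return ModularResult(part, semis, candidates, attractors, report)
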