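"""Shared fixtures and independent brute-force oracles.

The oracle helpers deliberately avoid the library's vectorized map/matrix
machinery: they step states one at a time through the rule ASTs and find
attractors by plain trajectory iteration, so that the fast implementations
are checked against straightforward enumeration.
"""

from __future__ import annotations

import pytest

from boolscape import fixture
from boolscape.network import BooleanNetwork, decode_state, encode_state


def naive_step(net: BooleanNetwork, w: int) -> int:
    """One synchronous step computed state-by-state, no numpy."""
    bits = decode_state(w, net.n)
    return encode_state([int(rule.evaluate(bits)) for rule in net.rules])


def naive_map_dict(net: BooleanNetwork) -> dict[int, int]:
    return {w: naive_step(net, w) for w in range(1 << net.n)}


def naive_attractor_of(mapping: dict[int, int], w: int) -> tuple[int, ...]:
    """The orbit reached from ``w``, found by walking until a repeat and
    canonically rotated to start at its minimal state."""
    size = len(mapping)
    for _ in range(size):
        w = mapping[w]
    orbit = [w]
    v = mapping[w]
    while v != w:
        orbit.append(v)
        v = mapping[v]
    lo = orbit.index(min(orbit))
    return tuple(orbit[lo:] + orbit[:lo])


def naive_landscape_pairs(mapping: dict[int, int]) -> list[tuple[int, int]]:
    """Each state paired with every state of the orbit it reaches."""
    return sorted((w, c) for w in mapping
                  for c in naive_attractor_of(mapping, w))


@pytest.fixture
def e1():
    return fixture("E1")


@pytest.fixture
def e4():
    return fixture("E4")


@pytest.fixture
def e8():
    return fixture("E8")


@pytest.fixture
def e11():
    return fixture("E11")


@pytest.fixture
def e13():
    return fixture("E13")


@pytest.fixture
def e19():
    return fixture("E19")
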