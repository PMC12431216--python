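"""Built-in example networks and seeded random network generation.

The named fixtures are the small worked networks used throughout the
documentation and test suite: chains, cross-couplings and their simplified
(canonical) counterparts, plus the 9-node two-chain network and its 200-node
extension used by the modular solver.  Each fixture is rebuilt from its rule
text on every call and verified against a hard-coded truth-table digest, so
a silent transcription error cannot go unnoticed.

``random_network`` draws, per node, a uniformly random truth table over a
random subset of regulators — the standard random Boolean network ensemble —
and is fully reproducible from its seed.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .network import And, BooleanNetwork, Const, Not, Or, Var, parse_network
from .statemap import build_integer_map

__all__ = ["fixture", "fixture_names", "random_network"]


def _chain_200() -> BooleanNetwork:
    # nodes 1-3 copy x1's chain, node 4 is self-sustaining, and every later
    # node copies its predecessor
    names = [f"x{k}" for k in range(1, 201)]
    rules = [Var(0), Var(0), Var(1), Var(3)] + [Var(k - 2) for k in range(5, 201)]
    return BooleanNetwork(names, rules)


_RULES = {
    # three-node chain driven by x3; two fixed points 0 and 7
    "E1": "x1, x2 & x3\nx2, x3\nx3, x3",
    # its canonical form: every node copies x3
    "E2": "x1, x3\nx2, x3\nx3, x3",
    # two-node network with stationary limit (fixed points 2 and 3)
    "E4": "x1, x1 | x2\nx2, (!x1 & !x2) | (x1 & x2)",
    # two-node cross-coupling: fixed points 0 and 3 plus the 2-cycle {1, 2}
    "E8": "x1, x2\nx2, x1",
    # two-node network whose only attractor is the cycle {2, 3}
    "E11": "x1, x1 | x2\nx2, !x2",
    # its canonical form
    "E12": "x1, 1\nx2, !x2",
    # three-node network with cycle {2, 3} and fixed point 7
    "E13": "x1, x1\nx2, x2 | x3\nx3, (x1 | !x3) & (x2 | !x3)",
    # its canonical form
    "E14": "x1, x1\nx2, 1\nx3, x1 | !x3",
    # nine-node two-chain network: x1 drives nodes 1-3, x4 drives 4-9
    "E19": ("x1, x1\nx2, x1\nx3, x2\nx4, x4\nx5, x4\nx6, x5\n"
            "x7, x6\nx8, x7\nx9, x8"),
}

_BUILDERS = {name: (lambda text=text: parse_network(text))
             for name, text in _RULES.items()}
_BUILDERS["E20"] = _chain_200

# sha256 of the integer-map table (n <= 16) or of every node's one-step rule
# evaluated over a fixed probe set (E20); regenerate with scripts/acceptance.py
# neighbourhood tooling if a fixture is ever edited deliberately
_DIGESTS = {
    "E1": "c357daf7cd3f45fab2fc53932307717503fa04fe37c14cbbbb7595711b692d50",
    "E2": "3d21adf05999b4e14d518c0f391fc98c2c41a7ccfabc7010441af1417367c4c1",
    "E4": "c323a0f168d63ec3e8b94a1f60cfc9e38a42fc746b9ff89f0f0696bad59c5e57",
    "E8": "270880408f621afcdac5746cf5533e2b8401ea562fd868ffc805571b7b64765f",
    "E11": "f7920445a3049320a53ef24855118008abdedca6bf176ab2c66b0507cb8a17ad",
    "E12": "a117cd363aa6c5cdb7088d09255d7f1d5bc062ba6480ce060e7f3299c5128f37",
    "E13": "f2db59b61353660792b5f7e4506af9987154894ae2555005507eecf71d008e75",
    "E14": "09ba2dbc7cbdf73ef6973077eadfc4a6d5b0401817cc7408b3b37e708702f2e2",
    "E19": "511ec5be86c6cfb6b382c2bcb7a43f4148c645f084cf709b0e1a17c9891696c0",
    "E20": "0b8383d64aa063d081dfccf1e86639428b2bc5904f5c96d31e8cf6f86b157073",
}


def _digest(net: BooleanNetwork) -> str:
    if net.n <= 16:
        payload = build_integer_map(net).image.tobytes()
    else:
        # probe the rules on a fixed pseudo-random state sample
        rng = np.random.default_rng(0)
        probes = rng.integers(0, 2, size=(64, net.n), dtype=np.int64)
        bits = tuple(probes[:, i] for i in range(net.n))
        cols = [np.broadcast_to(np.asarray(r.evaluate(bits), dtype=np.int64), (64,))
                for r in net.rules]
        payload = np.stack(cols).tobytes()
    return hashlib.sha256(payload).hexdigest()


def fixture_names() -> list[str]:
    return sorted(_BUILDERS)


def fixture(name: str, verify: bool = True) -> BooleanNetwork:
    """A named built-in network, semantically verified against its digest."""
    if name not in _BUILDERS:
        raise KeyError(f"unknown fixture {name!r}; known: {fixture_names()}")
    net = _BUILDERS[name]()
    if verify:
        expected = _DIGESTS.get(name)
        if expected is not None and _digest(net) != expected:
            raise AssertionError(f"fixture {name!r} failed its semantic "
                                 "self-check")
    return net


def random_network(n: int, max_inputs: int, seed: int) -> BooleanNetwork:
    """A random Boolean network: each node gets a uniform truth table over
    up to ``max_inputs`` randomly chosen regulators.

    Identical seeds give identical networks.  Rules are materialized as the
    sum of the truth table's minterms (constants for degenerate tables).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= max_inputs <= n:
        raise ValueError("max_inputs must be in 1..n")
    rng = np.random.default_rng(seed)
    names = [f"x{k}" for k in range(1, n + 1)]
    rules = []
    for _ in range(n):
        k = int(rng.integers(1, max_inputs + 1))
        regulators = sorted(rng.choice(n, size=k, replace=False).tolist())
        table = rng.integers(0, 2, size=1 << k)
        if not table.any():
            rules.append(Const(0))
            continue
        if table.all():
            rules.append(Const(1))
            continue
        terms = []
        for row in np.nonzero(table)[0]:
            lits = [Var(g) if (row >> (k - 1 - j)) & 1 else Not(Var(g))
                    for j, g in enumerate(regulators)]
            terms.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
        rules.append(terms[0] if len(terms) == 1 else Or(tuple(terms)))
    return BooleanNetwork(names, rules)
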