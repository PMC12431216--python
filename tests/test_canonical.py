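"""Basin compaction, minterm extraction, exact minimization, canonical form."""

import numpy as np
import pytest

from boolscape import (DNF, build_integer_map, canonical_network,
                       check_equivalence, compact_map, fixture, minimize_dnf,
                       minterms_from_map, random_network, stationary_landscape,
                       verify_union_decomposition)
from boolscape.attractors import analyze_map, find_cycles
from boolscape.canonical import MintermTable
from boolscape.statemap import IntegerMap


def same_truth_tables(a, b):
    return np.array_equal(build_integer_map(a).image, build_integer_map(b).image)


class TestCompaction:
    def test_e13_compacted_map_matches_printed_form(self, e13):
        compacted = compact_map(build_integer_map(e13))
        assert compacted.as_dict() == {0: 3, 1: 2, 2: 3, 3: 2,
                                       4: 7, 5: 7, 6: 7, 7: 7}

    def test_e11_compacted_map(self, e11):
        compacted = compact_map(build_integer_map(e11))
        assert compacted.as_dict() == {0: 3, 1: 2, 2: 3, 3: 2}

    def test_e1_compaction_sends_everything_to_fixed_points(self, e1):
        compacted = compact_map(build_integer_map(e1))
        assert compacted.as_dict() == {0: 0, 1: 7, 2: 0, 3: 7,
                                       4: 0, 5: 7, 6: 0, 7: 7}

    def test_compaction_preserves_cycles_at_full_length(self):
        for seed in range(10):
            net = random_network(n=5, max_inputs=3, seed=6000 + seed)
            m = build_integer_map(net)
            compacted = compact_map(m)
            # same attractor state-sets, each still a full-length cycle
            # (the traversal order may change; the landscape does not)
            orig = {frozenset(a.orbit) for a in find_cycles(m)}
            assert {frozenset(a.orbit)
                    for a in find_cycles(compacted)} == orig
            for a in find_cycles(compacted):
                assert verify_union_decomposition(a)
            # every state lands on an orbit in one application
            orbit_states = {w for orbit in orig for w in orbit}
            assert set(compacted.image.tolist()) <= orbit_states


class TestMinterms:
    def test_e1_landscape_minterms_are_the_odd_states(self, e1):
        landscape_fn = stationary_landscape(build_integer_map(e1)).as_map()
        table = minterms_from_map(landscape_fn)
        assert table.minterms == ((1, 3, 5, 7),) * 3

    def test_compacted_e13_second_node_is_always_on(self, e13):
        table = minterms_from_map(compact_map(build_integer_map(e13)))
        assert table.minterms[1] == tuple(range(8))

    def test_zero_map_has_empty_minterms(self):
        table = minterms_from_map(IntegerMap(2, np.zeros(4, dtype=np.int64)))
        assert table.minterms == ((), ())


class TestMinimization:
    def test_single_literal_extraction(self):
        # states with the last bit set reduce to that single variable
        dnf = minimize_dnf(MintermTable(3, (((1, 3, 5, 7)), (), ())))
        assert dnf.nodes[0] == (((2, True),),)

    def test_compacted_e13_minimizes_to_printed_rules(self, e13):
        dnf = minimize_dnf(minterms_from_map(compact_map(build_integer_map(e13))))
        exprs = dnf.exprs()
        assert [e.to_bnet(["x1", "x2", "x3"]) for e in exprs] == \
            ["x1", "1", "x1 | !x3"]

    def test_single_minterm_is_kept_verbatim(self):
        dnf = minimize_dnf(MintermTable(2, (((2,)), ())))
        assert dnf.nodes[0] == (((0, True), (1, False)),)

    def test_constants_for_full_and_empty_sets(self):
        dnf = minimize_dnf(MintermTable(2, ((0, 1, 2, 3), ())))
        assert dnf.nodes == (1, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_minimization_is_exact(self, seed):
        # minimized DNF must reproduce minterm membership on every state
        rng = np.random.default_rng(seed)
        n = 4
        members = tuple(sorted(rng.choice(16, size=rng.integers(1, 15),
                                          replace=False).tolist()))
        dnf = minimize_dnf(MintermTable(n, (members, (), (), ())))
        expr = dnf.expr(0)
        for w in range(16):
            bits = tuple((w >> (n - 1 - i)) & 1 for i in range(n))
            assert expr.evaluate(bits) == (1 if w in members else 0)


class TestCanonicalNetwork:
    @pytest.mark.parametrize("name,ref", [("E1", "E2"), ("E11", "E12"),
                                          ("E13", "E14")])
    def test_reproduces_published_simplifications(self, name, ref):
        net = fixture(name)
        simplified = canonical_network(net)
        # per-node truth tables equal the reference simplified network
        assert same_truth_tables(simplified, fixture(ref))
        assert check_equivalence(net, simplified)
        assert check_equivalence(net, fixture(ref))

    def test_equivalence_guarantee_on_random_networks(self):
        for seed in range(25):
            n = 2 + seed % 5
            net = random_network(n=n, max_inputs=min(3, n), seed=7000 + seed)
            assert check_equivalence(net, canonical_network(net))


class TestEquivalence:
    def test_different_dynamics_detected(self, e8):
        from boolscape.network import parse_network
        ident = parse_network("x1, x1\nx2, x2")
        assert not check_equivalence(e8, ident)

    def test_node_mismatch_rejected(self, e8, e13):
        with pytest.raises(ValueError, match="node count and order"):
            check_equivalence(e8, e13)

    def test_equivalence_is_landscape_not_map_equality(self, e1):
        # E1 and E2 have different one-step maps but identical landscapes
        e2 = fixture("E2")
        assert not same_truth_tables(e1, e2)
        assert check_equivalence(e1, e2)
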