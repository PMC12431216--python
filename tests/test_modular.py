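"""Modular semi-attractor procedure: partition, join, validate, basin counts."""

import pytest

from boolscape import (ModularError, analyze_map, basin_size_by_support,
                       build_integer_map, consecutive_blocks, find_fixed_points,
                       fixture, join_candidates, modular_solve,
                       module_semi_attractors, validate_candidates,
                       validate_partition)
from boolscape.canonical import canonical_network
from boolscape.modular import frozen_module_network
from boolscape.network import parse_network


def bits(s):
    return tuple(int(c) for c in s)


class TestPartition:
    def test_e19_three_blocks_form_a_chain_dag(self, e19):
        part = validate_partition(e19, consecutive_blocks(e19, 3))
        assert part.modules == ((0, 1, 2), (3, 4, 5), (6, 7, 8))
        assert part.upstream == (frozenset(), frozenset(), frozenset({1}))

    def test_e20_ten_blocks_of_twenty(self):
        e20 = fixture("E20")
        part = validate_partition(e20, consecutive_blocks(e20, 20))
        assert part.n_modules == 10
        assert all(len(m) == 20 for m in part.modules)

    def test_mutually_dependent_modules_rejected(self):
        net = parse_network("a, b\nb, a")
        with pytest.raises(ModularError, match="cyclic"):
            validate_partition(net, [[0], [1]])

    def test_incomplete_cover_rejected(self, e19):
        with pytest.raises(ModularError, match="partition"):
            validate_partition(e19, [[0, 1, 2]])

    def test_name_based_assignment(self, e19):
        part = validate_partition(e19, {f"x{k}": (k - 1) // 3
                                        for k in range(1, 10)})
        assert part.modules == ((0, 1, 2), (3, 4, 5), (6, 7, 8))


class TestSemiAttractors:
    def test_e19_modules_each_settle_to_all_zero_or_all_one(self, e19):
        part = validate_partition(e19, consecutive_blocks(e19, 3))
        semis = module_semi_attractors(e19, part)
        for states in semis.states:
            assert states == [bits("000"), bits("111")]

    def test_downstream_module_follows_its_frozen_input(self, e19):
        part = validate_partition(e19, consecutive_blocks(e19, 3))
        semis = module_semi_attractors(e19, part)
        by_input = semis.by_input[2]  # module {x7, x8, x9}, input x6
        assert by_input[(5, 0),] == [bits("000")]
        assert by_input[(5, 1),] == [bits("111")]

    def test_single_module_partition_reduces_to_fixed_points(self, e13):
        part = validate_partition(e13, [[0, 1, 2]])
        semis = module_semi_attractors(e13, part)
        fps = find_fixed_points(build_integer_map(e13))
        assert {int("".join(map(str, s)), 2) for s in semis.states[0]} == fps

    def test_frozen_module_canonical_form_collapses_to_the_driver(self, e19):
        # module {x7,x8,x9} frozen at x6=1 settles to the constant 111
        part = validate_partition(e19, consecutive_blocks(e19, 3))
        frozen = frozen_module_network(e19, part.modules[2], {5: 1})
        canon = canonical_network(frozen)
        assert [r.to_bnet(canon.nodes) for r in canon.rules] == ["1", "1", "1"]


class TestJoinAndValidate:
    def test_e19_join_gives_eight_candidates(self, e19):
        result = modular_solve(e19, consecutive_blocks(e19, 3))
        assert len(result.candidates) == 8
        assert result.candidates[0] == bits("000000000")
        assert result.candidates[-1] == bits("111111111")

    def test_e19_validation_keeps_four_true_attractors(self, e19):
        result = modular_solve(e19, consecutive_blocks(e19, 3))
        assert ["".join(map(str, a)) for a in result.attractors] == \
            ["000000000", "000111111", "111000000", "111111111"]

    def test_true_attractors_are_a_subset_of_candidates(self):
        for name, block in [("E13", 3), ("E19", 3)]:
            net = fixture(name)
            result = modular_solve(net, consecutive_blocks(net, block))
            assert set(result.attractors) <= set(result.candidates)

    def test_candidates_violating_a_rule_are_excluded(self, e19):
        # 000000111 breaks x7+ = x6 at the module boundary
        kept = validate_candidates(e19, [bits("000000111"), bits("000111111")])
        assert kept == [bits("000111111")]

    def test_e19_brute_force_confirms_the_modular_answer(self, e19):
        analysis = analyze_map(build_integer_map(e19))
        brute = {a.orbit[0] for a in analysis.attractors}
        result = modular_solve(e19, consecutive_blocks(e19, 3))
        modular = {int("".join(map(str, a)), 2) for a in result.attractors}
        assert modular == brute
        assert analysis.basin_map.basin_sizes() == [128] * 4


class TestBasinCounting:
    def test_e19_drivers_and_basin_sizes(self, e19):
        part = validate_partition(e19, consecutive_blocks(e19, 3))
        report = basin_size_by_support(e19, part)
        assert report.driver_names == ("x1", "x4")
        assert report.basin_size == 128
        assert report.total() == 2 ** 9

    def test_e19_reachability_conditions(self, e19):
        part = validate_partition(e19, consecutive_blocks(e19, 3))
        report = basin_size_by_support(e19, part)
        conditions = {"".join(map(str, a)): c
                      for a, c in zip(report.attractors, report.conditions)}
        assert conditions["000111111"] == {"x1": 0, "x4": 1}

    def test_single_self_copy_node_has_unit_basins(self):
        net = parse_network("x1, x1")
        part = validate_partition(net, [[0]])
        report = basin_size_by_support(net, part)
        assert report.driver_names == ("x1",)
        assert report.basin_size == 1

    def test_cyclic_frozen_module_is_refused(self, e8):
        part = validate_partition(e8, [[0, 1]])
        with pytest.raises(ModularError, match="cyclic attractor"):
            basin_size_by_support(e8, part)


class TestLargeNetwork:
    def test_e20_counts(self):
        e20 = fixture("E20")
        result = modular_solve(e20, consecutive_blocks(e20, 20), basins=False)
        assert result.semi_attractors.counts() == [4] + [2] * 9
        assert len(result.candidates) == 2048
        assert len(result.attractors) == 4

    def test_e20_basins_follow_the_two_drivers(self):
        e20 = fixture("E20")
        part = validate_partition(e20, consecutive_blocks(e20, 20))
        report = basin_size_by_support(e20, part)
        assert report.driver_names == ("x1", "x4")
        assert report.basin_size == 2 ** 198
        assert report.total() == 2 ** 200
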