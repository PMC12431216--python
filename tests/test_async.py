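"""Deterministic periodic asynchronous updating and schedule comparison."""

import pytest

from boolscape import (UpdateSchedule, analyze_map, async_landscape,
                       build_integer_map, compare_schedules, find_fixed_points,
                       hyperperiod_map, random_network, schedule_steps,
                       subset_update_map)


class TestSubsetUpdate:
    @pytest.mark.parametrize("subset,expected", [
        (frozenset(), {0: 0, 1: 1, 2: 2, 3: 3}),
        (frozenset({0}), {0: 0, 1: 3, 2: 0, 3: 3}),
        (frozenset({1}), {0: 0, 1: 0, 2: 3, 3: 3}),
        (frozenset({0, 1}), {0: 0, 1: 2, 2: 1, 3: 3}),
    ])
    def test_printed_subset_functions_of_the_cross_coupling(self, e8, subset,
                                                            expected):
        assert subset_update_map(e8, subset).as_dict() == expected

    def test_invalid_index_rejected(self, e8):
        with pytest.raises(IndexError):
            subset_update_map(e8, {5})


class TestSchedules:
    def test_period_rule_generates_the_expected_subsets(self, e8):
        sched = UpdateSchedule.from_periods(2, 3)
        assert sched.hyperperiod == 6
        assert sched.subsets(2) == [frozenset(), {0}, {1}, {0}, frozenset(),
                                    {0, 1}]

    def test_explicit_schedule_lists_its_maps_in_order(self, e8):
        sched = UpdateSchedule.from_subsets([[0], [1]])
        steps = schedule_steps(sched, e8)
        assert steps[0].as_dict() == {0: 0, 1: 3, 2: 0, 3: 3}
        assert steps[1].as_dict() == {0: 0, 1: 0, 2: 3, 3: 3}

    def test_all_periods_one_is_synchronous(self, e8):
        sched = UpdateSchedule.synchronous(2)
        assert sched.subsets(2) == [frozenset({0, 1})]
        assert hyperperiod_map(e8, sched) == build_integer_map(e8)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            UpdateSchedule.from_periods(0, 2)
        with pytest.raises(ValueError):
            UpdateSchedule.from_subsets([])
        with pytest.raises(ValueError):
            UpdateSchedule(periods=(1,), explicit=(frozenset(),))


class TestAsyncLandscape:
    def test_cycle_disappears_but_fixed_points_survive(self, e8):
        result = async_landscape(e8, UpdateSchedule.from_periods(2, 3))
        assert {a.orbit for a in result.attractors} == {(0,), (3,)}
        assert [a.orbit for a in result.lost_attractors] == [(1, 2)]

    def test_synchronous_periods_reproduce_the_synchronous_landscape(self, e13):
        result = async_landscape(e13, UpdateSchedule.synchronous(3))
        sync = analyze_map(build_integer_map(e13))
        assert result.analysis.signature() == sync.signature()

    def test_composition_equals_stepwise_trajectory(self, e13):
        sched = UpdateSchedule.from_periods(2, 1, 3)
        steps = schedule_steps(sched, e13)
        G = hyperperiod_map(e13, sched)
        for w in range(8):
            v = w
            for f in steps:
                v = f(v)
            assert G(w) == v

    def test_synchronous_fixed_points_fixed_under_every_subset(self):
        # the headline asynchronous invariance, over seeded random instances
        from itertools import chain, combinations
        for seed in range(10):
            net = random_network(n=4, max_inputs=3, seed=8000 + seed)
            fps = find_fixed_points(build_integer_map(net))
            subsets = chain.from_iterable(
                combinations(range(4), r) for r in range(5))
            for subset in subsets:
                f = subset_update_map(net, subset)
                assert all(f(w) == w for w in fps)

    def test_fixed_points_invariant_under_random_schedules(self):
        for seed in range(10):
            net = random_network(n=3, max_inputs=3, seed=9000 + seed)
            sync_fps = find_fixed_points(build_integer_map(net))
            sched = UpdateSchedule.from_periods(1 + seed % 3, 2, 1 + seed % 2)
            result = async_landscape(net, sched)
            async_fps = {a.orbit[0] for a in result.attractors
                         if a.kind == "fixed"}
            assert sync_fps <= async_fps


class TestCompareSchedules:
    def test_reversed_update_order_reshapes_basins(self, e8):
        # swapping the node periods keeps both fixed points but moves
        # basin membership
        s1 = UpdateSchedule.from_periods(2, 3)
        s2 = UpdateSchedule.from_periods(3, 2)
        report = compare_schedules(e8, s1, s2)
        assert report["shared_attractors"] == [[0], [3]]
        assert not report["identical_landscape"]

    def test_identical_schedules_show_no_difference(self, e8):
        s = UpdateSchedule.from_periods(2, 3)
        report = compare_schedules(e8, s, s)
        assert report["identical_landscape"]
        assert report["only_in_first"] == report["only_in_second"] == []
        assert report["basin_size_changes"] == {}

    def test_cycle_present_only_synchronously(self, e8):
        report = compare_schedules(e8, UpdateSchedule.synchronous(2),
                                   UpdateSchedule.from_periods(2, 3))
        assert report["only_in_first"] == [[1, 2]]
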