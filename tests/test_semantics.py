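"""Transition semantics: successors, exploration, witnesses, tag decoding."""

import random

import pytest

from nbckit.network import (
    DIAGONAL,
    DOWN,
    FaultSpec,
    FaultType,
    JunctionKind,
    apply_fault,
    build_excov_network,
    build_sat_clause_network,
    build_ssp_network,
)
from nbckit.problems import (
    SSPInstance,
    oracle_subset_sums,
    random_cnf3,
    random_excov,
    random_ssp,
)
from nbckit.semantics import (
    GridState,
    exit_columns,
    explore,
    follow,
    initial_state,
    path_tags,
    successors,
    tags_to_elements,
    witness_path,
)


class TestGridSuccessors:
    def test_split_offers_both_directions(self, fig1_net):
        succ = successors(initial_state(fig1_net), fig1_net)
        assert {(s.x, s.y, s.dir) for s in succ} == {(0, 1, DOWN), (1, 1, DIAGONAL)}

    def test_split_diagonal_collects_tag(self, fig1_net):
        succ = successors(initial_state(fig1_net, tagged=True), fig1_net)
        by_dir = {s.dir: s for s in succ}
        assert by_dir[DOWN].tags == frozenset()
        assert by_dir[DIAGONAL].tags == {0}

    def test_pass_preserves_direction(self, fig1_net):
        (s,) = successors(GridState(1, 1, DIAGONAL, False), fig1_net)
        assert (s.x, s.y, s.dir) == (2, 2, DIAGONAL)

    def test_force_down_overrides_incoming_diagonal(self, cover_net, cover_instance):
        s4_row = sum(cover_net.elements[:3])
        (s,) = successors(GridState(6, s4_row, DIAGONAL, False), cover_net)
        assert (s.x, s.dir) == (6, DOWN)

    def test_unaddressable_state_rejected(self, fig1_net):
        with pytest.raises(ValueError):
            successors(GridState(5, 2, DOWN, False), fig1_net)

    def test_row_and_column_conservation(self):
        # along every edge y increments by 1 and x by 0 or 1
        for seed in range(10):
            net = build_ssp_network(random_ssp(4, 9, seed=seed))
            g = explore(net)
            for s, succs in g.edges.items():
                for t in succs:
                    assert t.y == s.y + 1 or (s.flag and not succs)
                    assert t.x - s.x in (0, 1)


class TestExploration:
    def test_single_binary_choice(self):
        net = build_ssp_network(SSPInstance([4]))
        assert exit_columns(explore(net)) == {0, 4}

    def test_worked_set_exit_support(self, fig1_net):
        assert len(exit_columns(explore(fig1_net))) == 8

    def test_exits_equal_oracle_sums(self):
        inst = SSPInstance([2, 3, 5])
        net = build_ssp_network(inst)
        assert exit_columns(explore(net)) == oracle_subset_sums(inst)

    def test_tagged_exit_states_are_position_consistent(self):
        inst = SSPInstance([2, 3, 5])
        net = build_ssp_network(inst)
        g = explore(net, tagged=True)
        for s in g.exit_states():
            assert sum(net.element_of_tag(t) for t in s.tags) == s.x


class TestWitnessPaths:
    def test_witness_tags_name_the_summands(self, fig1_net):
        g = explore(fig1_net)
        path = witness_path(g, lambda s: s.flag and s.x == 11)
        assert path is not None and path[0] == g.initial
        assert tags_to_elements(fig1_net, path_tags(path, fig1_net)) == [2, 9]

    def test_unreachable_output_has_no_witness(self, fig1_net):
        g = explore(fig1_net)
        assert witness_path(g, lambda s: s.flag and s.x == 1) is None

    def test_initial_state_is_a_trivial_witness(self, fig1_net):
        g = explore(fig1_net)
        assert witness_path(g, lambda s: s == g.initial) == [g.initial]

    def test_follow_resolves_decisions(self, fig1_net):
        path = follow(fig1_net, {0: 1, 2: 0, 7: 1})
        assert path[-1].x == 11 and path[-1].flag

    def test_all_down_path_has_no_tags(self, fig1_net):
        path = follow(fig1_net, {r: 0 for r in fig1_net.split_rows})
        assert path[-1].x == 0
        assert path_tags(path, fig1_net) == frozenset()

    def test_cover_path_reaches_universe_output(self, cover_net):
        g = explore(cover_net)
        path = witness_path(g, lambda s: s.flag and s.x == 15)
        assert path is not None

    def test_invalid_step_rejected(self, fig1_net):
        bad = [GridState(0, 0, None, False), GridState(0, 2, DOWN, False)]
        with pytest.raises(ValueError, match="invalid step"):
            path_tags(bad, fig1_net)


class TestFaultSemantics:
    def test_pass_as_split_never_shrinks_exits(self):
        rng = random.Random(0)
        for trial in range(25):
            net = build_ssp_network(random_ssp(4, 8, seed=trial))
            base = exit_columns(explore(net))
            pass_cells = [
                (y, x)
                for y in range(net.max)
                for x in range(y + 1)
                if net.kind_at(y, x) is JunctionKind.PASS
            ]
            cell = rng.choice(pass_cells)
            faulted = apply_fault(net, FaultSpec(cell, FaultType.PASS_AS_SPLIT))
            assert base <= exit_columns(explore(faulted))

    def test_split_forced_never_grows_exits(self):
        # forcing a split removes one nondeterministic branch, so the faulty
        # behaviour is a subset of the designed behaviour
        rng = random.Random(1)
        for trial in range(25):
            net = build_ssp_network(random_ssp(4, 8, seed=100 + trial))
            base = exit_columns(explore(net))
            split_cells = [
                (y, x)
                for y in net.split_rows
                for x in range(y + 1)
                if net.kind_at(y, x) is JunctionKind.SPLIT
            ]
            cell = rng.choice(split_cells)
            faulted = apply_fault(
                net, FaultSpec(cell, FaultType.SPLIT_FORCED, rng.randint(0, 1))
            )
            assert exit_columns(explore(faulted)) <= base

    def test_pass_forced_can_deflect_onto_new_exits(self):
        # forcing a pass junction is NOT shrinking-only: agents arriving with
        # the opposite direction are deflected onto undesigned trajectories
        net = build_ssp_network(SSPInstance([2, 3, 5]))
        faulted = apply_fault(net, FaultSpec((3, 1), FaultType.PASS_FORCED, 0))
        base = exit_columns(explore(net))
        new = exit_columns(explore(faulted))
        assert new - base  # invalid sums appear (here 1 and 6)


class TestClauseNetworkSemantics:
    def test_saturating_counters_stay_in_range(self):
        f = random_cnf3(5, 15, seed=4)
        g = explore(build_sat_clause_network(f))
        for s in g.edges:
            assert all(0 <= c <= 3 for c in s.counters)

    def test_satisfying_exit_exists_iff_oracle_sat(self):
        from nbckit.problems import oracle_sat

        for seed in range(20):
            f = random_cnf3(6, 18, seed=seed)
            g = explore(build_sat_clause_network(f))
            found = any(
                s.flag and all(c > 0 for c in s.counters) for s in g.edges
            )
            assert found == oracle_sat(f)[0]
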