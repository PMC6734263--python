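"""Asynchronous STG construction, deadlocks and input restriction."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from metaflex.dynamics import (
    build_stg,
    input_restricted_stg,
    stable_states,
    state_from_label,
    state_label,
    successors,
)
from metaflex.logic_core import Clamp, context_of
from metaflex.model_fixtures import input_combinations, random_network


def naive_successors(state, net, params):
    """Oracle: recompute each entity's target from scratch, jump one step."""
    out = set()
    for i, name in enumerate(net.entity_order):
        present = frozenset(
            e.source
            for e in net.regulators(name)
            if state[net.index(e.source)] >= e.threshold
        )
        k = params.K[name][present]
        if k > state[i]:
            out.add(state[:i] + (state[i] + 1,) + state[i + 1 :])
        elif k < state[i]:
            out.add(state[:i] + (state[i] - 1,) + state[i + 1 :])
    return out


class TestToySuccessors:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("011", {"111", "001"}),
            ("000", set()),
            ("110", {"010", "100"}),
        ],
    )
    def test_successor_sets(self, toy, label, expected):
        net, params = toy
        succ = successors(state_from_label(label), net, params)
        assert {state_label(s) for s in succ} == expected

    def test_state_at_target_is_deadlocked(self, toy):
        net, params = toy
        assert successors((0, 0, 0), net, params) == set()


class TestToyStg:
    def test_eight_states_twelve_transitions(self, toy):
        net, params = toy
        stg = build_stg(net, params)
        assert stg.n_states == 8
        assert stg.n_transitions == 12

    def test_unique_deadlock_000(self, toy):
        net, params = toy
        stg = build_stg(net, params)
        assert {state_label(s) for s in stable_states(stg)} == {"000"}

    def test_p1_ectopic_moves_deadlock_to_100(self, toy):
        net, params = toy
        stg = build_stg(net, params, clamps=[Clamp("P1", 1)])
        assert stg.n_states == 8
        assert {state_label(s) for s in stable_states(stg)} == {"100"}

    def test_reachable_restriction_from_all_active(self, toy):
        """Initialising at 111 under ectopic P1 yields the four-state
        funnel into the shifted deadlock."""
        net, params = toy
        stg = build_stg(
            net, params, clamps=[Clamp("P1", 1)], initial_states=[(1, 1, 1)]
        )
        assert {state_label(s) for s in stg.states} == {"111", "101", "110", "100"}

    def test_reachable_subset_of_full(self, toy):
        net, params = toy
        full = build_stg(net, params)
        reach = build_stg(net, params, initial_states=[(0, 1, 0)])
        assert reach.states <= full.states
        assert reach.transitions <= full.transitions

    def test_state_cap_guard(self, toy):
        net, params = toy
        with pytest.raises(ValueError, match="exceeds cap"):
            build_stg(net, params, max_states=4)


class TestInputRestriction:
    def test_four_combinations_partition_the_state_space(
        self, full_net, full_params
    ):
        params = full_params["M1"]
        seen = set()
        for combo in input_combinations():
            sub = input_restricted_stg(full_net, params, combo.as_dict())
            assert sub.n_states == 256
            assert not (sub.states & seen)
            seen |= sub.states
        assert len(seen) == 1024

    def test_unknown_input_entity_rejected(self, toy):
        net, params = toy
        with pytest.raises(KeyError):
            input_restricted_stg(net, params, {"Glucose": 1})

    def test_clamped_inputs_never_move(self, full_net, full_params):
        sub = input_restricted_stg(
            full_net, full_params["M1"], {"Glucose": 1, "Circulating Fatty Acids": 0}
        )
        g = full_net.index("Glucose")
        c = full_net.index("Circulating Fatty Acids")
        for a, b in sub.transitions:
            assert a[g] == b[g] == 1
            assert a[c] == b[c] == 0


class TestInvariants:
    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_transitions_are_unit_hamming_steps(self, seed):
        net, params = random_network(seed, n_entities=4)
        stg = build_stg(net, params)
        for a, b in stg.transitions:
            diffs = [abs(x - y) for x, y in zip(a, b)]
            assert sum(diffs) == 1

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_successors_agree_with_naive_oracle(self, seed):
        net, params = random_network(seed, n_entities=4, edge_density=0.6)
        stg = build_stg(net, params)
        for s in stg.states:
            assert successors(s, net, params) == naive_successors(s, net, params)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_clamped_entity_only_moves_toward_its_clamp(self, seed):
        """A clamped entity converges: no transition increases its distance
        to the clamp level, and at the clamp level it never moves again."""
        net, params = random_network(seed, n_entities=4)
        name = net.entity_order[0]
        stg = build_stg(net, params, clamps=[Clamp(name, 0)])
        i = net.index(name)
        for a, b in stg.transitions:
            assert abs(b[i] - 0) <= abs(a[i] - 0)
            if a[i] == 0:
                assert b[i] == 0

    def test_serialization_is_bit_identical_across_builds(self, toy):
        import networkx as nx

        net, params = toy
        payloads = []
        for _ in range(2):
            stg = build_stg(net, params)
            buf = io.BytesIO()
            nx.write_graphml(stg.to_networkx(), buf)
            payloads.append(buf.getvalue())
        assert payloads[0] == payloads[1]
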