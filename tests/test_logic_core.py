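"""Networks, resource contexts and admissible-parameterization enumeration."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from metaflex.logic_core import (
    Clamp,
    Entity,
    Parameterization,
    RegulatoryEdge,
    RegulatoryNetwork,
    admissible_tables,
    context_of,
    enumerate_admissible_parameterizations,
    is_admissible,
    model_from_json,
    model_to_json,
    restrict_parameterization,
    validate_network,
)
from metaflex.model_fixtures import random_network


def brute_force_tables(net, entity):
    """Oracle: filter ALL value maps by pairwise monotonicity re-check."""
    contexts = net.contexts(entity)
    regs = net.regulators(entity)
    keep = []
    for values in itertools.product(
        range(net.max_level(entity) + 1), repeat=len(contexts)
    ):
        tab = dict(zip(contexts, values))
        ok = True
        for ctx in contexts:
            for e in regs:
                if e.source in ctx:
                    continue
                bigger = ctx | {e.source}
                if e.is_activator and tab[frozenset(bigger)] < tab[ctx]:
                    ok = False
                if not e.is_activator and tab[frozenset(bigger)] > tab[ctx]:
                    ok = False
        if ok:
            keep.append(tab)
    return keep


class TestValidation:
    def test_toy_network_is_valid(self, toy):
        net, _ = toy
        assert validate_network(net) == []

    def test_unknown_endpoint_reported(self):
        net = RegulatoryNetwork(
            [Entity("A")], [RegulatoryEdge("A", "X", "activator")]
        )
        violations = validate_network(net)
        assert len(violations) == 1 and "X" in violations[0]

    def test_duplicate_edge_reported(self):
        net = RegulatoryNetwork(
            [Entity("A"), Entity("B")],
            [
                RegulatoryEdge("A", "B", "activator"),
                RegulatoryEdge("A", "B", "inhibitor"),
            ],
        )
        assert any("duplicate edge" in v for v in validate_network(net))


class TestContexts:
    @pytest.mark.parametrize(
        "state, expected",
        [
            ((1, 0, 1), {"P1"}),
            ((0, 0, 0), set()),
            ((1, 1, 0), {"P1", "P2"}),
        ],
    )
    def test_context_of_p3(self, toy, state, expected):
        net, _ = toy
        assert context_of(state, "P3", net) == expected

    def test_unknown_entity_raises(self, toy):
        net, _ = toy
        with pytest.raises(KeyError):
            context_of((0, 0, 0), "P9", net)


class TestEnumeration:
    def test_toy_total_is_36(self, toy):
        net, _ = toy
        assert sum(1 for _ in enumerate_admissible_parameterizations(net)) == 36

    def test_factor_counts(self, toy):
        """3 monotone tables for one activator, 6 for activator+inhibitor,
        2 for a free entity: 3 * 6 * 2 = 36."""
        net, _ = toy
        assert len(admissible_tables(net, "P1")) == 3
        assert len(admissible_tables(net, "P2")) == 2
        assert len(admissible_tables(net, "P3")) == 6

    def test_isolated_boolean_entity_has_two_tables(self):
        net = RegulatoryNetwork([Entity("A")], [])
        assert [t[frozenset()] for t in admissible_tables(net, "A")] == [0, 1]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_networks(self, seed):
        net, _ = random_network(seed, n_entities=3, edge_density=0.7)
        for name in net.entity_order:
            if len(net.regulators(name)) <= 3:
                mine = [tuple(sorted((tuple(sorted(c)), v) for c, v in t.items()))
                        for t in admissible_tables(net, name)]
                oracle = [tuple(sorted((tuple(sorted(c)), v) for c, v in t.items()))
                          for t in brute_force_tables(net, name)]
                assert sorted(mine) == sorted(oracle)

    def test_every_enumerated_parameterization_is_admissible(self, toy):
        net, _ = toy
        for p in enumerate_admissible_parameterizations(net):
            assert is_admissible(p, net)

    def test_enumeration_order_is_deterministic(self, toy):
        net, _ = toy
        first = [p.key() for p in enumerate_admissible_parameterizations(net)]
        second = [p.key() for p in enumerate_admissible_parameterizations(net)]
        assert first == second

    def test_regulator_limit_guard(self):
        names = [f"R{i}" for i in range(14)] + ["T"]
        net = RegulatoryNetwork(
            [Entity(n) for n in names],
            [RegulatoryEdge(f"R{i}", "T", "activator") for i in range(14)],
        )
        with pytest.raises(ValueError, match="enumeration refused"):
            admissible_tables(net, "T")


class TestClamps:
    def test_ectopic_clamp_overrides_every_context(self, toy):
        net, params = toy
        clamped = restrict_parameterization(params, [Clamp("P1", 1)])
        assert all(v == 1 for v in clamped.K["P1"].values())
        assert clamped.K["P3"] == params.K["P3"]

    def test_restriction_is_idempotent(self, toy):
        _, params = toy
        once = restrict_parameterization(params, [Clamp("P1", 0)])
        twice = restrict_parameterization(once, [Clamp("P1", 0)])
        assert once.key() == twice.key()

    def test_conflicting_clamps_rejected(self, toy):
        _, params = toy
        with pytest.raises(ValueError, match="conflicting"):
            restrict_parameterization(
                params, [Clamp("P1", 0), Clamp("P1", 1)]
            )


class TestModelFiles:
    def test_round_trip(self, toy):
        net, params = toy
        text = model_to_json(net, params, clamps=[Clamp("P1", 1)])
        net2, params2, clamps2 = model_from_json(text)
        assert net2.entity_order == net.entity_order
        assert [(e.source, e.target, e.sign) for e in net2.edges] == [
            (e.source, e.target, e.sign) for e in net.edges
        ]
        assert params2.key() == params.key()
        assert clamps2 == [Clamp("P1", 1)]

    def test_unknown_fields_rejected(self):
        with pytest.raises(ValueError, match="unknown model-file fields"):
            model_from_json('{"entities": [], "extra": 1}')


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_random_parameterizations_lie_in_admissible_set(seed):
    net, params = random_network(seed, n_entities=3, edge_density=0.6)
    assert is_admissible(params, net)
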