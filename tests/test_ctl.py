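"""CTL parsing, fixpoint model checking and parameter-set filtering."""

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from metaflex.ctl import (
    CTLSyntaxError,
    bind_check,
    check,
    filter_parameterizations,
    holds,
    iter_atoms,
    parse_ctl,
    read_properties_file,
    write_properties_file,
)
from metaflex.dynamics import build_stg, state_from_label, state_label
from metaflex.logic_core import enumerate_admissible_parameterizations
from metaflex.model_fixtures import (
    TOY_PROPERTY,
    VERIFICATION_PROPERTIES,
    random_network,
)


def totalized_digraph(stg):
    g = nx.DiGraph()
    g.add_nodes_from(stg.states)
    g.add_edges_from(stg.transitions)
    for s in stg.states:
        if g.out_degree(s) == 0:
            g.add_edge(s, s)
    return g


def oracle_ef(stg, goal):
    """Independent EF: forward reachability on the raw digraph."""
    g = totalized_digraph(stg)
    return {s for s in stg.states if s in goal or (nx.descendants(g, s) & goal)}


def oracle_eg(stg, hold):
    """Independent EG: states that can reach a cycle inside the hold set."""
    sub = totalized_digraph(stg).subgraph(hold).copy()
    cyclic = set()
    for comp in nx.strongly_connected_components(sub):
        if len(comp) > 1 or sub.has_edge(next(iter(comp)), next(iter(comp))):
            cyclic |= comp
    return {
        s
        for s in sub.nodes
        if s in cyclic or (nx.descendants(sub, s) & cyclic)
    }


class TestParser:
    def test_toy_property_structure(self):
        f = parse_ctl(TOY_PROPERTY)
        assert str(f).count("EX") == 2 and str(f).count("EG") == 2

    def test_round_trip_canonical_form(self):
        f = parse_ctl("AG(x=1)")
        assert parse_ctl(str(f)) == f

    def test_multiword_and_hyphenated_atoms(self):
        f = parse_ctl("Fatty Acids=1 & Acetyl-CoA=0")
        names = sorted(str(a) for a in iter_atoms(f))
        assert names == ["Acetyl-CoA=0", "Fatty Acids=1"]

    def test_verification_properties_parse_and_bind(self, full_net):
        for text in VERIFICATION_PROPERTIES.values():
            f = parse_ctl(text)
            bind_check(f, full_net)  # raises on unknown atom/level

    def test_syntax_error_reports_position(self):
        with pytest.raises(CTLSyntaxError, match="position"):
            parse_ctl("AG(x=1")

    def test_unknown_entity_rejected_at_bind_time(self, toy):
        net, _ = toy
        with pytest.raises(KeyError):
            bind_check(parse_ctl("Q7=1"), net)

    def test_properties_file_round_trip(self):
        text = write_properties_file(
            {"a": "AG(P1=0)", "b": "(P2=1) -> EF(P2=0)"}
        )
        props = read_properties_file(text)
        assert set(props) == {"a", "b"}
        assert props["a"] == parse_ctl("AG(P1=0)")


class TestToyChecking:
    def test_atom_satisfaction(self, toy):
        net, params = toy
        stg = build_stg(net, params)
        sat = {state_label(s) for s in check(stg, "P2=1")}
        assert sat == {"010", "011", "110", "111"}

    def test_eg_is_the_sustained_cycle(self, toy):
        """EG(P2=1) holds exactly on the four-state cycle: the only infinite
        P2-preserving paths circulate there (confirmed by the cycle-reach
        oracle)."""
        net, params = toy
        stg = build_stg(net, params)
        sat = check(stg, "EG(P2=1)")
        assert {state_label(s) for s in sat} == {"010", "011", "110", "111"}
        assert sat == oracle_eg(stg, check(stg, "P2=1"))

    def test_toy_property_holds_everywhere(self, toy):
        net, params = toy
        stg = build_stg(net, params)
        assert holds(stg, TOY_PROPERTY)

    def test_deadlock_totalization_makes_eg_hold(self, toy):
        net, params = toy
        stg = build_stg(net, params)
        sat = {state_label(s) for s in check(stg, "EG(P1=0 & P2=0 & P3=0)")}
        assert sat == {"000"}

    def test_frozen_p3_breaks_the_property(self, toy):
        """With K_P3 forced to 0 no P2-preserving cycle survives."""
        net, params = toy
        frozen = params.copy()
        frozen.K["P3"] = {c: 0 for c in frozen.K["P3"]}
        stg = build_stg(net, frozen)
        assert not holds(stg, TOY_PROPERTY)

    def test_initial_states_mode(self, toy):
        net, params = toy
        stg = build_stg(net, params)
        assert holds(stg, "EF(P1=0 & P2=0 & P3=0)", mode="initial_states",
                     initial_states=[(1, 1, 1)])
        assert not holds(stg, "P2=1", mode="initial_states",
                         initial_states=[(0, 0, 0)])


class TestDualities:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_quantifier_dualities(self, seed):
        net, params = random_network(seed, n_entities=4)
        stg = build_stg(net, params)
        phi = f"{net.entity_order[0]}=1"
        for a, b in [
            (f"AG({phi})", f"!(EF(!({phi})))"),
            (f"AF({phi})", f"!(EG(!({phi})))"),
            (f"AX({phi})", f"!(EX(!({phi})))"),
        ]:
            assert check(stg, a) == check(stg, b)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_ef_matches_reachability_oracle(self, seed):
        net, params = random_network(seed, n_entities=4)
        stg = build_stg(net, params)
        phi = f"{net.entity_order[-1]}=0"
        assert check(stg, f"EF({phi})") == oracle_ef(stg, check(stg, phi))

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_eg_matches_cycle_oracle(self, seed):
        net, params = random_network(seed, n_entities=4)
        stg = build_stg(net, params)
        phi = f"{net.entity_order[0]}=0"
        assert check(stg, f"EG({phi})") == oracle_eg(stg, check(stg, phi))


class TestFiltering:
    def test_two_of_thirty_six(self, toy):
        net, table1 = toy
        sats = filter_parameterizations(net, TOY_PROPERTY)
        assert len(sats) == 2
        assert any(p.key() == table1.key() for p in sats)

    def test_trivial_formula_keeps_all(self, toy):
        net, _ = toy
        sats = filter_parameterizations(net, "true")
        assert len(sats) == 36

    def test_filter_result_rechecks_true(self, toy):
        net, _ = toy
        keys = {p.key() for p in enumerate_admissible_parameterizations(net)}
        for p in filter_parameterizations(net, TOY_PROPERTY):
            assert p.key() in keys
            assert holds(build_stg(net, p), TOY_PROPERTY)
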