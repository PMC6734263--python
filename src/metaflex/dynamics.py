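"""Asynchronous state transition graphs (STGs).

States are tuples of integer levels in the network's canonical entity order,
labelled by concatenating the digits (``"101"``, ``"0001000010"``).  Between
two successive states exactly one entity changes, by one level, toward the
target given by its logical parameters — the asynchronous unitary update.
A state with no outgoing transition is a deadlock (stable steady state).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .logic_core import (
    Clamp,
    Parameterization,
    RegulatoryNetwork,
    context_of,
    restrict_parameterization,
)

State = tuple

DEFAULT_STATE_CAP = 1 << 22


def state_label(state: Sequence[int]) -> str:
    return "".join(str(v) for v in state)


def state_from_label(label: str) -> State:
    return tuple(int(ch) for ch in label)


def successors(
    state: Sequence[int],
    net: RegulatoryNetwork,
    params: Parameterization,
    clamps: Iterable[Clamp] = (),
    frozen: frozenset[str] = frozenset(),
) -> set[State]:
    """Asynchronous successors: one per entity off-target, stepping one unit.

    ``frozen`` entities never move (used for input-restricted state spaces);
    ``clamps`` instead redirect the target level, so a clamped entity still
    transitions toward its clamp from any starting level.
    """
    clamps = tuple(clamps)
    if clamps:
        params = restrict_parameterization(params, clamps)
    out: set[State] = set()
    state = tuple(state)
    for i, name in enumerate(net.entity_order):
        if name in frozen:
            continue
        target = params.target(name, context_of(state, name, net))
        level = state[i]
        if target == level:
            continue
        step = 1 if target > level else -1
        out.add(state[:i] + (level + step,) + state[i + 1 :])
    return out


@dataclass
class StateTransitionGraph:
    """All configurations (or a reachable restriction) plus asynchronous moves."""

    net: RegulatoryNetwork
    params: Parameterization
    states: frozenset[State]
    transitions: frozenset[tuple[State, State]]
    clamps: tuple[Clamp, ...] = ()
    frozen: frozenset[str] = frozenset()
    initial_states: frozenset[State] | None = None

    _succ: dict[State, set[State]] | None = field(
        default=None, repr=False, compare=False
    )

    def successor_map(self) -> dict[State, set[State]]:
        if self._succ is None:
            succ: dict[State, set[State]] = {s: set() for s in self.states}
            for a, b in self.transitions:
                succ[a].add(b)
            self._succ = succ
        return self._succ

    def predecessor_map(self) -> dict[State, set[State]]:
        pred: dict[State, set[State]] = {s: set() for s in self.states}
        for a, b in self.transitions:
            pred[b].add(a)
        return pred

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        order = self.net.entity_order
        for s in sorted(self.states):
            attrs = {f"level_{name}": s[i] for i, name in enumerate(order)}
            g.add_node(state_label(s), **attrs)
        for a, b in sorted(self.transitions):
            (i,) = [k for k in range(len(a)) if a[k] != b[k]]
            g.add_edge(
                state_label(a),
                state_label(b),
                entity=order[i],
                direction="up" if b[i] > a[i] else "down",
            )
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_dot(self, path) -> None:
        _write_dot(self.to_networkx(), path)


def _write_dot(g: nx.DiGraph, path) -> None:
    # plain DOT writer; avoids the optional pygraphviz/pydot dependency
    with open(path, "w") as fh:
        fh.write("digraph {\n")
        for n in g.nodes:
            fh.write(f'  "{n}";\n')
        for a, b in g.edges:
            fh.write(f'  "{a}" -> "{b}";\n')
        fh.write("}\n")


def _full_space(
    net: RegulatoryNetwork, fixed: Mapping[str, int]
) -> Iterable[State]:
    ranges = []
    for name in net.entity_order:
        if name in fixed:
            ranges.append((fixed[name],))
        else:
            ranges.append(tuple(range(net.max_level(name) + 1)))
    return itertools.product(*ranges)


def build_stg(
    net: RegulatoryNetwork,
    params: Parameterization,
    clamps: Iterable[Clamp] = (),
    initial_states: Iterable[Sequence[int]] | None = None,
    fixed: Mapping[str, int] | None = None,
    max_states: int = DEFAULT_STATE_CAP,
) -> StateTransitionGraph:
    """Build the asynchronous STG.

    Without ``initial_states`` the graph covers every configuration (with
    ``fixed`` coordinates held constant); with them, the forward-reachable
    closure.  ``clamps`` fold knockout/ectopic restrictions into the
    parameters before construction.
    """
    clamps = tuple(clamps)
    if clamps:
        params = restrict_parameterization(params, clamps)
    fixed = dict(fixed or {})
    frozen = frozenset(fixed)

    n_conf = 1
    for name in net.entity_order:
        if name not in fixed:
            n_conf *= net.max_level(name) + 1
    if initial_states is None and n_conf > max_states:
        raise ValueError(f"state space of {n_conf} states exceeds cap {max_states}")

    transitions: set[tuple[State, State]] = set()
    if initial_states is None:
        states = set(map(tuple, _full_space(net, fixed)))
        for s in states:
            for t in successors(s, net, params, frozen=frozen):
                transitions.add((s, t))
        init = None
    else:
        init = frozenset(tuple(s) for s in initial_states)
        states = set(init)
        frontier = list(states)
        while frontier:
            if len(states) > max_states:
                raise ValueError(f"reachable space exceeds cap {max_states}")
            s = frontier.pop()
            for t in successors(s, net, params, frozen=frozen):
                transitions.add((s, t))
                if t not in states:
                    states.add(t)
                    frontier.append(t)
    return StateTransitionGraph(
        net=net,
        params=params,
        states=frozenset(states),
        transitions=frozenset(transitions),
        clamps=clamps,
        frozen=frozen,
        initial_states=init,
    )


def stable_states(stg: StateTransitionGraph) -> set[State]:
    """States with no outgoing transition (deadlocks / stable steady states)."""
    succ = stg.successor_map()
    return {s for s in stg.states if not succ[s]}


def input_restricted_stg(
    net: RegulatoryNetwork,
    params: Parameterization,
    inputs: Mapping[str, int],
    max_states: int = DEFAULT_STATE_CAP,
) -> StateTransitionGraph:
    """Drop the input self-loops, fix the inputs, and build the restricted STG.

    The inputs' self-edges are removed so the fixed coordinates generate no
    transitions; the state space covers only the free entities (e.g. the four
    256-state graphs of the ten-entity model).
    """
    for name in inputs:
        net.entity(name)  # raises on unknown input
    reduced = net.without_edges((n, n) for n in inputs)
    # re-key the clamped inputs' tables to the reduced regulator sets
    K = {e: dict(t) for e, t in params.K.items()}
    for name, level in inputs.items():
        K[name] = {ctx: level for ctx in reduced.contexts(name)}
    return build_stg(
        reduced,
        Parameterization(K),
        fixed=dict(inputs),
        max_states=max_states,
    )
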