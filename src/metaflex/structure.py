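"""Hierarchical transition graphs (HTGs): acyclic quotients of STGs.

Nontrivial strongly connected components collapse to single nodes —
``ct#n`` when the component can still be left (transient), ``ca#n`` when it
cannot (terminal, i.e. a cyclic attractor).  Deadlock states become
``ss-<label>`` nodes.  The remaining acyclic states are grouped into
irreversible components ``i#n``; a component containing a state with no
incoming STG transition is *rooted* (the system can start there but never
return).  HTG nodes partition the STG's states and the quotient is acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import networkx as nx
import pandas as pd

from .dynamics import State, StateTransitionGraph, state_label

Kind = Literal[
    "transient_scc", "terminal_scc", "irreversible", "rooted_irreversible",
    "stable_state",
]

_PREFIX = {
    "transient_scc": "ct#",
    "terminal_scc": "ca#",
    "irreversible": "i#",
    "rooted_irreversible": "i#",
}


@dataclass(frozen=True)
class HTGNode:
    kind: Kind
    members: frozenset
    label: str

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HierarchicalTransitionGraph:
    nodes: tuple[HTGNode, ...]
    edges: frozenset  # pairs of HTGNode
    stg: StateTransitionGraph

    def node_of(self, state: State) -> HTGNode:
        for node in self.nodes:
            if state in node.members:
                return node
        raise KeyError(state)

    def out_degree(self, node: HTGNode) -> int:
        return sum(1 for a, _ in self.edges if a is node or a == node)

    def in_degree(self, node: HTGNode) -> int:
        return sum(1 for _, b in self.edges if b is node or b == node)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(
                n.label,
                kind=n.kind,
                size=n.size,
                members=" ".join(sorted(state_label(s) for s in n.members)),
            )
        for a, b in self.edges:
            g.add_edge(a.label, b.label)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def scc_decompose(stg: StateTransitionGraph) -> list[frozenset]:
    """Maximal SCCs of the STG, deterministically ordered.

    Singleton states are trivial components (no self-transitions are stored).
    Order: decreasing size, then smallest member label.
    """
    g = nx.DiGraph()
    g.add_nodes_from(stg.states)
    g.add_edges_from(stg.transitions)
    comps = [frozenset(c) for c in nx.strongly_connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(state_label(s) for s in c)))
    return comps


def _group_trivial_wcc(
    trivial: set[frozenset], cond_edges: set[tuple[frozenset, frozenset]]
) -> list[set[frozenset]]:
    """Maximal weakly-connected sets of trivial condensation vertices."""
    g = nx.Graph()
    g.add_nodes_from(trivial)
    for a, b in cond_edges:
        if a in trivial and b in trivial:
            g.add_edge(a, b)
    return [set(c) for c in nx.connected_components(g)]


def _group_trivial_by_reachable(
    trivial: set[frozenset],
    cond: nx.DiGraph,
) -> list[set[frozenset]]:
    """Group trivial vertices by the identical set of reachable collapsed
    components (nontrivial SCCs and deadlock states)."""
    collapsed = {v for v in cond.nodes if v not in trivial}
    reach: dict[frozenset, frozenset] = {}
    for v in sorted(trivial, key=lambda c: min(state_label(s) for s in c)):
        seen = set()
        stack = [v]
        while stack:
            u = stack.pop()
            for w in cond.successors(u):
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        reach[v] = frozenset(seen & collapsed)
    groups: dict[frozenset, set[frozenset]] = {}
    for v, key in reach.items():
        groups.setdefault(key, set()).add(v)
    return list(groups.values())


def build_htg(
    stg: StateTransitionGraph,
    grouping: Literal["reachable", "wcc"] = "reachable",
) -> HierarchicalTransitionGraph:
    """Collapse an STG into its hierarchical transition graph.

    ``grouping`` selects how acyclic non-deadlock states merge into ``i#``
    nodes.  The default ``"reachable"`` groups trivial states that reach the
    same set of collapsed components (nontrivial SCCs and deadlocks) — the
    refinement used by the reference HTG implementation, which reproduces
    the two-node structure of the glucose-only input condition.  ``"wcc"``
    instead takes maximal weakly-connected sets of trivial condensation
    vertices (a strictly finer partition on some graphs).
    """
    comps = scc_decompose(stg)
    succ = stg.successor_map()
    pred = stg.predecessor_map()

    comp_of: dict[State, frozenset] = {}
    for c in comps:
        for s in c:
            comp_of[s] = c

    cond = nx.DiGraph()
    cond.add_nodes_from(comps)
    for a, b in stg.transitions:
        ca, cb = comp_of[a], comp_of[b]
        if ca is not cb and ca != cb:
            cond.add_edge(ca, cb)

    blocks: list[tuple[Kind, frozenset]] = []
    trivial_acyclic: set[frozenset] = set()
    for c in comps:
        if len(c) > 1:
            kind: Kind = (
                "terminal_scc" if cond.out_degree(c) == 0 else "transient_scc"
            )
            blocks.append((kind, c))
        else:
            (s,) = c
            if not succ[s]:
                blocks.append(("stable_state", c))
            else:
                trivial_acyclic.add(c)

    if grouping == "reachable":
        groups = _group_trivial_by_reachable(trivial_acyclic, cond)
    elif grouping == "wcc":
        groups = _group_trivial_wcc(trivial_acyclic, set(cond.edges))
    else:  # pragma: no cover
        raise ValueError(f"unknown grouping rule {grouping!r}")

    for group in groups:
        members = frozenset(s for c in group for s in c)
        rooted = any(not pred[s] for s in members)
        blocks.append(("rooted_irreversible" if rooted else "irreversible", members))

    # deterministic node order: kind, size desc, smallest member label
    kind_rank = {
        "transient_scc": 0,
        "terminal_scc": 1,
        "rooted_irreversible": 2,
        "irreversible": 3,
        "stable_state": 4,
    }
    blocks.sort(
        key=lambda kb: (
            kind_rank[kb[0]],
            -len(kb[1]),
            min(state_label(s) for s in kb[1]),
        )
    )

    base_labels = []
    for kind, members in blocks:
        if kind == "stable_state":
            (s,) = members
            base_labels.append(f"ss-{state_label(s)}")
        else:
            base_labels.append(f"{_PREFIX[kind]}{len(members)}")
    counts: dict[str, int] = {}
    for lbl in base_labels:
        counts[lbl] = counts.get(lbl, 0) + 1
    seen: dict[str, int] = {}
    nodes = []
    for (kind, members), lbl in zip(blocks, base_labels):
        if counts[lbl] > 1:
            seen[lbl] = seen.get(lbl, 0) + 1
            lbl = f"{lbl} ({seen[lbl]})"
        nodes.append(HTGNode(kind=kind, members=members, label=lbl))

    node_of: dict[State, HTGNode] = {}
    for node in nodes:
        for s in node.members:
            node_of[s] = node
    edges = set()
    for a, b in stg.transitions:
        na, nb = node_of[a], node_of[b]
        if na is not nb:
            edges.add((na, nb))
    return HierarchicalTransitionGraph(
        nodes=tuple(nodes), edges=frozenset(edges), stg=stg
    )


def htg_summary(htg: HierarchicalTransitionGraph) -> pd.DataFrame:
    """One row per HTG node: label, kind, size, out/in degree."""
    rows = []
    for n in htg.nodes:
        rows.append(
            {
                "label": n.label,
                "kind": n.kind,
                "size": n.size,
                "out_degree": htg.out_degree(n),
                "in_degree": htg.in_degree(n),
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "kind", "size", "out_degree", "in_degree"]
    )


def conserved_substructure(
    htgs: Sequence[HierarchicalTransitionGraph],
) -> tuple[list[frozenset], list[tuple[frozenset, frozenset]]]:
    """Nodes (as member-state sets) and edges present in every HTG.

    Nodes match by exact state-set equality; an edge is conserved iff both
    endpoints are conserved and the edge occurs in every HTG.
    """
    if not htgs:
        return [], []
    member_sets = [set(n.members for n in h.nodes) for h in htgs]
    common = set.intersection(*member_sets)
    edge_sets = [
        {(a.members, b.members) for a, b in h.edges} for h in htgs
    ]
    common_edges = set.intersection(*edge_sets)
    conserved_edges = [
        (a, b) for a, b in common_edges if a in common and b in common
    ]
    key = lambda ms: min(state_label(s) for s in ms)
    return (
        sorted(common, key=key),
        sorted(conserved_edges, key=lambda e: (key(e[0]), key(e[1]))),
    )
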