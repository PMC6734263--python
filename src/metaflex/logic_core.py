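"""Core types of the discrete (kinetic logic) modelling formalism.

A regulatory network is a signed directed graph over discrete entities.
Each entity holds an integer level in ``[0, max_level]`` and evolves toward a
target level given by its logical parameters ``K``: a complete table mapping
each *resource context* (the subset of regulators currently supplying their
interaction) to a target level.  Admissible parameterizations respect
sign-monotonicity: adding an activator to a context never lowers the target,
adding an inhibitor never raises it.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

ACTIVATOR = "activator"
INHIBITOR = "inhibitor"

_SIGN_ALIASES = {
    "activator": ACTIVATOR,
    "+": ACTIVATOR,
    "inhibitor": INHIBITOR,
    "-": INHIBITOR,
}


@dataclass(frozen=True)
class Entity:
    """A discrete model component with levels ``0 .. max_level``."""

    name: str
    max_level: int = 1

    def __post_init__(self) -> None:
        if self.max_level < 0:
            raise ValueError(f"max_level of {self.name!r} must be >= 0")


@dataclass(frozen=True)
class RegulatoryEdge:
    """A signed interaction; active when the source is at or above ``threshold``."""

    source: str
    target: str
    sign: str
    threshold: int = 1

    def __post_init__(self) -> None:
        sign = _SIGN_ALIASES.get(self.sign)
        if sign is None:
            raise ValueError(f"unknown edge sign {self.sign!r}")
        object.__setattr__(self, "sign", sign)
        if self.threshold < 1:
            raise ValueError("edge threshold must be >= 1")

    @property
    def is_activator(self) -> bool:
        return self.sign == ACTIVATOR


@dataclass(frozen=True)
class Clamp:
    """Fix an entity's target level in every context (knockout = 0, ectopic = max)."""

    entity: str
    level: int


class RegulatoryNetwork:
    """Signed interaction graph with a canonical entity order for state labels."""

    def __init__(self, entities: Sequence[Entity], edges: Sequence[RegulatoryEdge]):
        self.entities: tuple[Entity, ...] = tuple(entities)
        self.edges: tuple[RegulatoryEdge, ...] = tuple(edges)
        self.entity_order: tuple[str, ...] = tuple(e.name for e in self.entities)
        self._index: dict[str, int] = {n: i for i, n in enumerate(self.entity_order)}
        self._by_name: dict[str, Entity] = {e.name: e for e in self.entities}
        # regulators sorted by canonical entity order; defines context bit order
        self._regulators: dict[str, tuple[RegulatoryEdge, ...]] = {
            n: () for n in self.entity_order
        }
        for name in self.entity_order:
            incoming = [e for e in self.edges if e.target == name]
            incoming.sort(key=lambda e: self._index.get(e.source, len(self._index)))
            self._regulators[name] = tuple(incoming)

    # -- lookups ---------------------------------------------------------
    def entity(self, name: str) -> Entity:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown entity {name!r}") from None

    def index(self, name: str) -> int:
        return self._index[name]

    def max_level(self, name: str) -> int:
        return self.entity(name).max_level

    def regulators(self, name: str) -> tuple[RegulatoryEdge, ...]:
        if name not in self._by_name:
            raise KeyError(f"unknown entity {name!r}")
        return self._regulators[name]

    def regulator_names(self, name: str) -> tuple[str, ...]:
        return tuple(e.source for e in self.regulators(name))

    def contexts(self, name: str) -> list[frozenset[str]]:
        """All resource contexts of an entity, ordered by subset bitmask."""
        regs = self.regulator_names(name)
        out = []
        for mask in range(1 << len(regs)):
            out.append(frozenset(r for i, r in enumerate(regs) if mask >> i & 1))
        return out

    def without_edges(self, drop: Iterable[tuple[str, str]]) -> "RegulatoryNetwork":
        dropset = set(drop)
        return RegulatoryNetwork(
            self.entities,
            [e for e in self.edges if (e.source, e.target) not in dropset],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RegulatoryNetwork({len(self.entities)} entities, "
            f"{len(self.edges)} edges)"
        )


Context = frozenset
State = tuple  # levels in entity_order


@dataclass
class Parameterization:
    """Complete logical-parameter table ``K[entity][context] -> target level``."""

    K: dict[str, dict[frozenset[str], int]]

    def target(self, entity: str, context: frozenset[str]) -> int:
        return self.K[entity][context]

    def copy(self) -> "Parameterization":
        return Parameterization({e: dict(t) for e, t in self.K.items()})

    def key(self) -> tuple:
        """Hashable canonical form (for set membership / determinism tests)."""
        return tuple(
            (e, tuple(sorted((tuple(sorted(c)), v) for c, v in tab.items())))
            for e, tab in sorted(self.K.items())
        )


def validate_network(net: RegulatoryNetwork) -> list[str]:
    """Check type invariants; returns a list of human-readable violations."""
    problems: list[str] = []
    seen_names: set[str] = set()
    for ent in net.entities:
        if ent.name in seen_names:
            problems.append(f"duplicate entity name {ent.name!r}")
        seen_names.add(ent.name)
    seen_pairs: set[tuple[str, str]] = set()
    for edge in net.edges:
        for endpoint in (edge.source, edge.target):
            if endpoint not in seen_names:
                problems.append(
                    f"edge {edge.source}->{edge.target} references unknown "
                    f"entity {endpoint!r}"
                )
        pair = (edge.source, edge.target)
        if pair in seen_pairs:
            problems.append(f"duplicate edge {edge.source}->{edge.target}")
        seen_pairs.add(pair)
        if edge.source in seen_names and edge.threshold > net.max_level(edge.source):
            problems.append(
                f"edge {edge.source}->{edge.target} threshold {edge.threshold} "
                f"exceeds source max_level {net.max_level(edge.source)}"
            )
    for ent in net.entities:
        if ent.max_level < 1 and any(e.source == ent.name for e in net.edges):
            problems.append(
                f"entity {ent.name!r} has outgoing edges but max_level < 1"
            )
    return problems


def context_of(
    state: Mapping[str, int] | Sequence[int],
    entity: str,
    net: RegulatoryNetwork,
) -> frozenset[str]:
    """Resource context of ``entity`` in ``state``: regulators at/above threshold."""
    if isinstance(state, Mapping):
        level = state.__getitem__
    else:
        if len(state) != len(net.entity_order):
            raise ValueError("state dimension does not match network")
        level = lambda name: state[net.index(name)]
    return frozenset(
        e.source for e in net.regulators(entity) if level(e.source) >= e.threshold
    )


def _monotone(
    values: Sequence[int], regs: Sequence[RegulatoryEdge]
) -> bool:
    """Snoussi check on a context-indexed value vector (bitmask order)."""
    n = len(regs)
    for mask in range(1 << n):
        for i in range(n):
            if mask >> i & 1:
                continue
            bigger = mask | (1 << i)
            if regs[i].is_activator:
                if values[bigger] < values[mask]:
                    return False
            else:
                if values[bigger] > values[mask]:
                    return False
    return True


def admissible_tables(
    net: RegulatoryNetwork, entity: str, max_regulators: int = 12
) -> list[dict[frozenset[str], int]]:
    """All sign-monotone K tables for one entity, in deterministic order.

    Order is lexicographic over the value vector indexed by context bitmask
    (empty context first), values increasing.
    """
    regs = net.regulators(entity)
    if len(regs) > max_regulators:
        raise ValueError(
            f"{entity!r} has {len(regs)} regulators; enumeration refused "
            f"(limit {max_regulators})"
        )
    contexts = net.contexts(entity)
    levels = range(net.max_level(entity) + 1)
    tables = []
    for values in itertools.product(levels, repeat=len(contexts)):
        if _monotone(values, regs):
            tables.append(dict(zip(contexts, values)))
    return tables


def enumerate_admissible_parameterizations(
    net: RegulatoryNetwork, max_regulators: int = 12
) -> Iterator[Parameterization]:
    """Yield every parameterization satisfying totality, range and monotonicity.

    Deterministic order: cartesian product over entities in canonical order,
    each entity's tables in the order of :func:`admissible_tables`.
    """
    per_entity = [
        admissible_tables(net, name, max_regulators) for name in net.entity_order
    ]
    for combo in itertools.product(*per_entity):
        yield Parameterization(dict(zip(net.entity_order, combo)))


def count_admissible_parameterizations(net: RegulatoryNetwork) -> int:
    out = 1
    for name in net.entity_order:
        out *= len(admissible_tables(net, name))
    return out


def is_admissible(p: Parameterization, net: RegulatoryNetwork) -> bool:
    """Re-check totality, range and monotonicity of an arbitrary parameterization."""
    for name in net.entity_order:
        tab = p.K.get(name)
        if tab is None:
            return False
        contexts = net.contexts(name)
        if set(tab) != set(contexts):
            return False
        values = [tab[c] for c in contexts]
        if any(v < 0 or v > net.max_level(name) for v in values):
            return False
        if not _monotone(values, net.regulators(name)):
            return False
    return True


def restrict_parameterization(
    p: Parameterization, clamps: Iterable[Clamp]
) -> Parameterization:
    """Clamp entities to fixed target levels in every context (KO/ectopic)."""
    levels: dict[str, int] = {}
    for c in clamps:
        if c.entity in levels and levels[c.entity] != c.level:
            raise ValueError(f"conflicting clamps on {c.entity!r}")
        levels[c.entity] = c.level
    out = p.copy()
    for entity, level in levels.items():
        if entity not in out.K:
            raise KeyError(f"unknown entity {entity!r}")
        out.K[entity] = {ctx: level for ctx in out.K[entity]}
    return out


# -- JSON model files ------------------------------------------------------

def _context_key(ctx: frozenset[str]) -> str:
    return ",".join(sorted(ctx))


def model_to_json(
    net: RegulatoryNetwork,
    params: Parameterization | None = None,
    clamps: Sequence[Clamp] = (),
) -> str:
    doc: dict = {
        "entities": [
            {"name": e.name, "max_level": e.max_level} for e in net.entities
        ],
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "sign": e.sign,
                "threshold": e.threshold,
            }
            for e in net.edges
        ],
    }
    if params is not None:
        doc["parameters"] = {
            ent: {_context_key(c): v for c, v in sorted(
                tab.items(), key=lambda kv: (len(kv[0]), _context_key(kv[0]))
            )}
            for ent, tab in params.K.items()
        }
    if clamps:
        doc["clamps"] = [{"entity": c.entity, "level": c.level} for c in clamps]
    return json.dumps(doc, indent=1)


def model_from_json(
    text: str,
) -> tuple[RegulatoryNetwork, Parameterization | None, list[Clamp]]:
    doc = json.loads(text)
    allowed = {"entities", "edges", "parameters", "clamps"}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"unknown model-file fields: {sorted(unknown)}")
    net = RegulatoryNetwork(
        [Entity(d["name"], d.get("max_level", 1)) for d in doc["entities"]],
        [
            RegulatoryEdge(
                d["source"], d["target"], d["sign"], d.get("threshold", 1)
            )
            for d in doc.get("edges", [])
        ],
    )
    params = None
    if "parameters" in doc:
        K: dict[str, dict[frozenset[str], int]] = {}
        for ent, tab in doc["parameters"].items():
            K[ent] = {
                frozenset(k.split(",")) if k else frozenset(): int(v)
                for k, v in tab.items()
            }
        params = Parameterization(K)
    clamps = [Clamp(d["entity"], int(d["level"])) for d in doc.get("clamps", [])]
    return net, params, clamps
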