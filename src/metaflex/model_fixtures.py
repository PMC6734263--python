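"""Encoded models: the three-entity toy network, the ten-entity
metabolic-flexibility network with its four PDK parameterizations and
verification properties, and a seeded random-network generator for
property-based testing.

The metabolic-flexibility network links glycolysis, fatty-acid oxidation,
fatty-acid synthesis and the TCA cycle around the PDC-PDK switch: pyruvate
dehydrogenase kinases (PDK) inactivate the pyruvate dehydrogenase complex
(PDC) by phosphorylation, moving acetyl-CoA production from the glucose
route (glycolysis -> pyruvate -> PDC) to the fatty-acid route (beta
oxidation via carnitine transport, blocked by malonyl-CoA).  The two inputs,
Glucose and Circulating Fatty Acids, carry inhibitory self-loops so their
availability fluctuates freely.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .ctl import CTLFormula, parse_ctl
from .logic_core import (
    Entity,
    Parameterization,
    RegulatoryEdge,
    RegulatoryNetwork,
)

# canonical entity order; state labels concatenate levels in this order, so
# the starvation deadlock reads "0001000010": PDC (position 4) and AMPK
# (position 9) at level 1
ENTITY_ORDER = (
    "Glucose",
    "Pyruvate",
    "PDK",
    "PDC",
    "Acetyl-CoA",
    "Citrate",
    "Malonyl-CoA",
    "Fatty Acids",
    "AMPK",
    "Circulating Fatty Acids",
)

INPUT_ENTITIES = ("Glucose", "Circulating Fatty Acids")


def toy_model() -> tuple[RegulatoryNetwork, Parameterization]:
    """Three-entity illustration: P3 activates P1, P2 activates P3, P1 inhibits P3.

    The parameters give the inhibitor precedence on P3 and decay to every
    entity lacking its activators, producing an eight-state STG with a
    four-state cycle and deadlock 000.
    """
    net = RegulatoryNetwork(
        [Entity("P1"), Entity("P2"), Entity("P3")],
        [
            RegulatoryEdge("P3", "P1", "activator"),
            RegulatoryEdge("P2", "P3", "activator"),
            RegulatoryEdge("P1", "P3", "inhibitor"),
        ],
    )
    params = Parameterization(
        {
            "P1": {frozenset(): 0, frozenset({"P3"}): 1},
            "P2": {frozenset(): 0},
            "P3": {
                frozenset(): 0,
                frozenset({"P1"}): 0,
                frozenset({"P2"}): 1,
                frozenset({"P1", "P2"}): 0,
            },
        }
    )
    return net, params


TOY_PROPERTY = "((P2=1) -> EX(EG(P2=1))) & ((P2=1) -> EX(EG(P2=0)))"


def metabolic_flexibility_network() -> RegulatoryNetwork:
    """The ten-entity, nineteen-edge regulatory network of cellular
    metabolic flexibility (all entities Boolean)."""
    a, i = "activator", "inhibitor"
    edges = [
        RegulatoryEdge("Glucose", "Pyruvate", a),           # glucose uptake -> glycolysis
        RegulatoryEdge("Pyruvate", "PDK", i),               # allosteric inhibition of PDK
        RegulatoryEdge("PDK", "PDC", i),                    # PDC inactivation by phosphorylation
        RegulatoryEdge("PDC", "Acetyl-CoA", a),             # pyruvate decarboxylation
        RegulatoryEdge("Pyruvate", "Acetyl-CoA", a),        # pyruvate consumed by PDC
        RegulatoryEdge("Acetyl-CoA", "PDK", a),             # NADH/ATP-mediated activation
        RegulatoryEdge("Acetyl-CoA", "Citrate", a),         # entry into the TCA cycle
        RegulatoryEdge("Citrate", "Pyruvate", i),           # PFK inhibition by citrate
        RegulatoryEdge("Citrate", "Malonyl-CoA", a),        # ACC-mediated carboxylation
        RegulatoryEdge("Malonyl-CoA", "Fatty Acids", a),    # fatty-acid synthesis
        RegulatoryEdge("Citrate", "Fatty Acids", a),        # cytoplasmic acetyl-CoA supply
        RegulatoryEdge("Fatty Acids", "Acetyl-CoA", a),     # beta oxidation via carnitine transport
        RegulatoryEdge("Malonyl-CoA", "Acetyl-CoA", i),     # carnitine-transport block
        RegulatoryEdge("Acetyl-CoA", "AMPK", i),            # high ATP suppresses AMPK
        RegulatoryEdge("AMPK", "Malonyl-CoA", i),           # AMPK inhibits ACC
        RegulatoryEdge("Fatty Acids", "PDK", a),            # PPARgamma-mediated activation
        RegulatoryEdge("Circulating Fatty Acids", "Fatty Acids", a),  # FA uptake
        RegulatoryEdge("Circulating Fatty Acids", "Circulating Fatty Acids", i),
        RegulatoryEdge("Glucose", "Glucose", i),
    ]
    return RegulatoryNetwork([Entity(n) for n in ENTITY_ORDER], edges)


@dataclass(frozen=True)
class PDKVariant:
    """One hypothesis for how PDK's activators interact with its inhibitor.

    ``bits`` is the truth table over (Pyruvate, Acetyl-CoA, Fatty Acids)
    presence, indexed by the bitmask ``P | A<<1 | F<<2``.
    """

    id: str
    description: str
    bits: tuple[int, ...]

    def rule(self, P: int, A: int, F: int) -> int:
        return self.bits[(P & 1) | (A & 1) << 1 | (F & 1) << 2]

    def table(self, net: RegulatoryNetwork) -> dict[frozenset[str], int]:
        out = {}
        for ctx in net.contexts("PDK"):
            out[ctx] = self.rule(
                int("Pyruvate" in ctx),
                int("Acetyl-CoA" in ctx),
                int("Fatty Acids" in ctx),
            )
        return out


def _bits(fn) -> tuple[int, ...]:
    return tuple(
        int(fn(mask & 1, mask >> 1 & 1, mask >> 2 & 1)) for mask in range(8)
    )


def pdk_variants() -> tuple[PDKVariant, PDKVariant, PDKVariant, PDKVariant]:
    return (
        PDKVariant(
            "M1",
            "Pyruvate always blocks PDK activity when present",
            _bits(lambda P, A, F: not P and (A or F)),
        ),
        PDKVariant(
            "M2",
            "activators collectively override pyruvate inhibition",
            _bits(lambda P, A, F: (A and F) or (not P and (A or F))),
        ),
        PDKVariant(
            "M3",
            "acetyl-CoA-mediated activation bypasses pyruvate",
            _bits(lambda P, A, F: A or (not P and F)),
        ),
        PDKVariant(
            "M4",
            "fatty-acid-mediated activation bypasses pyruvate",
            _bits(lambda P, A, F: F or (not P and A)),
        ),
    )


def base_parameterization(
    variant: PDKVariant, net: RegulatoryNetwork | None = None
) -> Parameterization:
    """Logical parameters of the full model under one PDK variant.

    Non-PDK entities follow the biochemistry of their incoming edges:
    inhibitors dominate where a block is physical (PDK on PDC, malonyl-CoA
    on carnitine transport, AMPK on ACC, citrate on PFK); acetyl-CoA needs
    both the enzyme (PDC) and its substrate (pyruvate) on the glucose route;
    the inputs oscillate via their self-inhibition.
    """
    if net is None:
        net = metabolic_flexibility_network()

    def boolean_rule(entity: str, fn) -> dict[frozenset[str], int]:
        return {
            ctx: int(fn(ctx)) for ctx in net.contexts(entity)
        }

    K = {
        # inputs: self-inhibition -> 0 and 1 both transient (oscillator)
        "Glucose": boolean_rule("Glucose", lambda c: "Glucose" not in c),
        "Circulating Fatty Acids": boolean_rule(
            "Circulating Fatty Acids",
            lambda c: "Circulating Fatty Acids" not in c,
        ),
        "Pyruvate": boolean_rule(
            "Pyruvate", lambda c: "Glucose" in c and "Citrate" not in c
        ),
        "PDK": variant.table(net),
        "PDC": boolean_rule("PDC", lambda c: "PDK" not in c),
        "Acetyl-CoA": boolean_rule(
            "Acetyl-CoA",
            lambda c: ("PDC" in c and "Pyruvate" in c)
            or ("Fatty Acids" in c and "Malonyl-CoA" not in c),
        ),
        "Citrate": boolean_rule("Citrate", lambda c: "Acetyl-CoA" in c),
        "Malonyl-CoA": boolean_rule(
            "Malonyl-CoA", lambda c: "Citrate" in c and "AMPK" not in c
        ),
        "Fatty Acids": boolean_rule(
            "Fatty Acids",
            lambda c: "Circulating Fatty Acids" in c
            or ("Citrate" in c and "Malonyl-CoA" in c),
        ),
        "AMPK": boolean_rule("AMPK", lambda c: "Acetyl-CoA" not in c),
    }
    return Parameterization(K)


@dataclass(frozen=True)
class InputCombination:
    name: str
    glucose: int
    circulating_fa: int

    def as_dict(self) -> dict[str, int]:
        return {
            "Glucose": self.glucose,
            "Circulating Fatty Acids": self.circulating_fa,
        }


def input_combinations() -> tuple[InputCombination, ...]:
    """The four input conditions: glucose only, both, fatty acids only, neither."""
    return (
        InputCombination("Input 1", 1, 0),
        InputCombination("Input 2", 1, 1),
        InputCombination("Input 3", 0, 1),
        InputCombination("Input 4", 0, 0),
    )


# Verification properties of the full model (checked in every state; the
# guarded implications are vacuously true where their antecedent fails).
VERIFICATION_PROPERTIES: dict[str, str] = {
    "Glucose Oxidation": (
        "((Glucose=1 & Pyruvate=0 & Citrate=0) -> EX(Glucose=1 & Pyruvate=1))"
        " & ((Pyruvate=1 & PDC=1 & Acetyl-CoA=0)"
        " -> EX(Pyruvate=1 & PDC=1 & Acetyl-CoA=1))"
    ),
    "Fatty acid Oxidation": (
        "((Fatty Acids=1 & Malonyl-CoA=0 & Acetyl-CoA=0)"
        " -> EX(Fatty Acids=1 & Malonyl-CoA=0 & Acetyl-CoA=1))"
    ),
    "Presence of PDK": (
        "((PDK=1 & PDC=1 & Pyruvate=1 & (Fatty Acids=0 | Malonyl-CoA=1)"
        " & Acetyl-CoA=1)"
        " -> EF(PDK=1 & PDC=0 & (Fatty Acids=0 | Malonyl-CoA=1) & Acetyl-CoA=0))"
        " & ((PDK=1 & (PDC=0 | Pyruvate=0) & Fatty Acids=1 & Malonyl-CoA=0"
        " & Acetyl-CoA=0)"
        " -> EX(PDK=1 & (PDC=0 | Pyruvate=0) & Fatty Acids=1 & Malonyl-CoA=0"
        " & Acetyl-CoA=1))"
    ),
    "Absence of PDK": (
        "((PDK=0 & PDC=1 & Pyruvate=1 & (Fatty Acids=0 | Malonyl-CoA=1)"
        " & Acetyl-CoA=0)"
        " -> EX(PDK=0 & PDC=1 & Pyruvate=1 & (Fatty Acids=0 | Malonyl-CoA=1)"
        " & Acetyl-CoA=1))"
        " & ((PDK=0 & PDC=1 & Pyruvate=1 & Malonyl-CoA=0 & Acetyl-CoA=1)"
        " -> EF(PDK=0 & PDC=1 & Pyruvate=1 & Malonyl-CoA=1 & Acetyl-CoA=1))"
    ),
}


def verification_properties() -> dict[str, CTLFormula]:
    """The four named verification formulae, parsed."""
    return {name: parse_ctl(text) for name, text in VERIFICATION_PROPERTIES.items()}


def random_network(
    seed: int,
    n_entities: int = 4,
    edge_density: float = 0.5,
    sign_bias: float = 0.5,
) -> tuple[RegulatoryNetwork, Parameterization]:
    """Seeded random Boolean network plus one admissible parameterization.

    Used as the test generator: every returned parameterization is drawn
    uniformly from the sign-monotone tables of each entity, so it lies in
    the output of the admissible enumerator by construction.
    """
    rng = random.Random(seed)
    names = [f"N{i}" for i in range(n_entities)]
    edges = []
    for src in names:
        for dst in names:
            if rng.random() < edge_density:
                sign = "activator" if rng.random() < sign_bias else "inhibitor"
                edges.append(RegulatoryEdge(src, dst, sign))
    net = RegulatoryNetwork([Entity(n) for n in names], edges)
    K = {}
    for name in names:
        K[name] = _sample_monotone_table(net, name, rng)
    return net, Parameterization(K)


def _sample_monotone_table(
    net: RegulatoryNetwork, entity: str, rng: random.Random
) -> dict[frozenset[str], int]:
    """Draw one sign-monotone table without enumerating the table space.

    Contexts are mapped to a "positive mask" (activators present plus
    inhibitors absent), under which monotonicity is plain subset
    monotonicity; values are drawn and then raised to the running maximum of
    the immediate sub-masks, visiting masks by increasing popcount.
    """
    regs = net.regulators(entity)
    max_level = net.max_level(entity)
    n = len(regs)

    def positive_mask(ctx_mask: int) -> int:
        pm = 0
        for i, e in enumerate(regs):
            present = ctx_mask >> i & 1
            if (present and e.is_activator) or (not present and not e.is_activator):
                pm |= 1 << i
        return pm

    values: dict[int, int] = {}
    for pm in sorted(range(1 << n), key=lambda m: (bin(m).count("1"), m)):
        floor = 0
        for i in range(n):
            if pm >> i & 1:
                floor = max(floor, values[pm & ~(1 << i)])
        values[pm] = max(floor, rng.randint(0, max_level))

    table = {}
    reg_names = [e.source for e in regs]
    for ctx_mask in range(1 << n):
        ctx = frozenset(r for i, r in enumerate(reg_names) if ctx_mask >> i & 1)
        table[ctx] = values[positive_mask(ctx_mask)]
    return table
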