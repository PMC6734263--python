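"""End-to-end analyses of the metabolic-flexibility model: parameter-set
verification, network analysis (STG/HTG statistics and cross-model conserved
substructures), perturbation scenarios, and a one-command reproduction run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .ctl import check, holds, parse_ctl
from .dynamics import (
    StateTransitionGraph,
    build_stg,
    input_restricted_stg,
    stable_states,
    state_label,
)
from .logic_core import Clamp, Parameterization, model_to_json, restrict_parameterization
from .model_fixtures import (
    INPUT_ENTITIES,
    InputCombination,
    PDKVariant,
    base_parameterization,
    input_combinations,
    metabolic_flexibility_network,
    pdk_variants,
    verification_properties,
)
from .structure import build_htg, conserved_substructure, htg_summary, scc_decompose

# CTL-expressed perturbation outcomes.  Checked from the all-inactive initial
# state of each scenario's reachability-restricted STG, so "reachable" means
# reachable from the resting cell under the given input condition.
PERTURBATION_PROPERTIES: dict[str, str] = {
    # acetyl-CoA fed from the glucose route and the fatty-acid route at once
    "dual_source_acetyl_coa": (
        "EF(Pyruvate=1 & PDC=1 & Fatty Acids=1 & Malonyl-CoA=0 & Acetyl-CoA=1)"
    ),
    "glucose_driven_acetyl_coa": "EF(Pyruvate=1 & PDC=1 & Acetyl-CoA=1)",
    "fatty_acid_driven_acetyl_coa": (
        "EF(Fatty Acids=1 & Malonyl-CoA=0 & Acetyl-CoA=1 & PDC=0)"
    ),
    "acetyl_coa_producible": "EF(Acetyl-CoA=1)",
    # the system can lock into persistent PDK activity with PDC disabled
    "locks_into_persistent_pdk": "EF(AG(PDK=1 & PDC=0))",
}

PERTURBATION_SCENARIOS: dict[str, Clamp | None] = {
    "baseline": None,
    "PDK knockout": Clamp("PDK", 0),
    "PDK ectopic": Clamp("PDK", 1),
    "AMPK knockout": Clamp("AMPK", 0),
    "AMPK ectopic": Clamp("AMPK", 1),
}


def perturbation_stg(
    params: Parameterization,
    combo: InputCombination,
    clamp: Clamp | None = None,
    net=None,
) -> StateTransitionGraph:
    """Reachability-restricted STG for a perturbation scenario.

    Input self-loops are removed and the inputs held at the combination's
    levels; the perturbed entity (if any) is clamped; all free entities start
    at level 0 (the clamped entity at its clamp level).
    """
    if net is None:
        net = metabolic_flexibility_network()
    reduced = net.without_edges((n, n) for n in INPUT_ENTITIES)
    fixed = combo.as_dict()
    K = {e: dict(t) for e, t in params.K.items()}
    for name, level in fixed.items():
        K[name] = {ctx: level for ctx in reduced.contexts(name)}
    p = Parameterization(K)
    if clamp is not None:
        p = restrict_parameterization(p, [clamp])
    init = tuple(
        fixed.get(
            name, clamp.level if clamp is not None and clamp.entity == name else 0
        )
        for name in net.entity_order
    )
    return build_stg(reduced, p, initial_states=[init], fixed=fixed)


def run_verification(variants=None, properties=None) -> pd.DataFrame:
    """Model-check every verification property on every PDK variant's full STG.

    Returns a boolean matrix (rows: variants, columns: properties); the
    all-states satisfaction convention is used, so each guarded implication
    must hold in each of the 1,024 configurations.
    """
    net = metabolic_flexibility_network()
    variants = variants if variants is not None else pdk_variants()
    properties = properties if properties is not None else verification_properties()
    rows = {}
    for v in variants:
        stg = build_stg(net, base_parameterization(v, net))
        rows[v.id] = {name: holds(stg, f) for name, f in properties.items()}
    return pd.DataFrame(
        rows.values(), index=list(rows), columns=list(properties), dtype=object
    ).astype(bool) if properties else pd.DataFrame(index=list(rows))


def verification_counterexamples(variant: PDKVariant) -> dict[str, list[str]]:
    """States violating each verification property (empty lists when satisfied)."""
    net = metabolic_flexibility_network()
    stg = build_stg(net, base_parameterization(variant, net))
    out = {}
    for name, f in verification_properties().items():
        sat = check(stg, f)
        out[name] = sorted(state_label(s) for s in stg.states - sat)
    return out


def run_network_analysis(variants=None) -> dict:
    """STG sizes, HTG structure per input condition, and conserved substructures.

    Returns ``{"stg_stats": DataFrame, "htg_stats": DataFrame,
    "conserved": DataFrame, "input_deadlocks": DataFrame}``.
    """
    net = metabolic_flexibility_network()
    variants = variants if variants is not None else pdk_variants()
    stg_rows, htg_rows, dead_rows = [], [], []
    htgs_by_input: dict[str, list] = {c.name: [] for c in input_combinations()}
    for v in variants:
        params = base_parameterization(v, net)
        stg = build_stg(net, params)
        largest = max(len(c) for c in scc_decompose(stg))
        stg_rows.append(
            {
                "variant": v.id,
                "states": stg.n_states,
                "transitions": stg.n_transitions,
                "largest_scc": largest,
            }
        )
        for combo in input_combinations():
            sub = input_restricted_stg(net, params, combo.as_dict())
            htg = build_htg(sub)
            htgs_by_input[combo.name].append(htg)
            summary = htg_summary(htg)
            for _, row in summary.iterrows():
                htg_rows.append(
                    {"variant": v.id, "input": combo.name, **row.to_dict()}
                )
            dead_rows.append(
                {
                    "variant": v.id,
                    "input": combo.name,
                    "states": sub.n_states,
                    "deadlocks": ";".join(
                        sorted(state_label(s) for s in stable_states(sub))
                    ),
                }
            )
    conserved_rows = []
    for combo in input_combinations():
        nodes, edges = conserved_substructure(htgs_by_input[combo.name])
        ref = htgs_by_input[combo.name][0]
        by_members = {n.members: n for n in ref.nodes}
        for members in nodes:
            node = by_members[members]
            conserved_rows.append(
                {
                    "input": combo.name,
                    "label": node.label,
                    "kind": node.kind,
                    "size": len(members),
                    "conserved_out_edges": sum(
                        1 for a, _ in edges if a == members
                    ),
                }
            )
    return {
        "stg_stats": pd.DataFrame(stg_rows),
        "htg_stats": pd.DataFrame(htg_rows),
        "input_deadlocks": pd.DataFrame(dead_rows),
        "conserved": pd.DataFrame(
            conserved_rows,
            columns=["input", "label", "kind", "size", "conserved_out_edges"],
        ),
        "htgs_by_input": htgs_by_input,
    }


def run_perturbations(variants=None) -> pd.DataFrame:
    """Outcome profile of every (scenario, input, variant) combination.

    Each perturbation outcome is a CTL property checked from the scenario's
    initial state (see :data:`PERTURBATION_PROPERTIES`).  The release check
    for the PDK-ectopic stall additionally verifies that unclamping PDK from
    any state reached under the clamp restores glucose-driven acetyl-CoA.
    """
    net = metabolic_flexibility_network()
    variants = variants if variants is not None else pdk_variants()
    parsed = {k: parse_ctl(t) for k, t in PERTURBATION_PROPERTIES.items()}
    rows = []
    for v in variants:
        params = base_parameterization(v, net)
        for combo in input_combinations():
            for scen, clamp in PERTURBATION_SCENARIOS.items():
                stg = perturbation_stg(params, combo, clamp, net)
                row = {
                    "variant": v.id,
                    "input": combo.name,
                    "scenario": scen,
                    "reachable_states": stg.n_states,
                }
                for key, f in parsed.items():
                    row[key] = holds(stg, f, mode="initial_states")
                rows.append(row)
    return pd.DataFrame(rows)


def pdk_ectopic_release_restores_glucose_route(
    variant: PDKVariant, net=None
) -> bool:
    """From every state reachable under the PDK-ectopic clamp with glucose
    only, the released system can again produce glucose-driven acetyl-CoA."""
    if net is None:
        net = metabolic_flexibility_network()
    params = base_parameterization(variant, net)
    combo = input_combinations()[0]  # glucose only
    stalled = perturbation_stg(params, combo, Clamp("PDK", 1), net)
    released = perturbation_stg(params, combo, None, net)
    reduced = released.net
    rel = build_stg(
        reduced,
        released.params,
        initial_states=stalled.states,
        fixed=combo.as_dict(),
    )
    return holds(
        rel,
        PERTURBATION_PROPERTIES["glucose_driven_acetyl_coa"],
        mode="initial_states",
        initial_states=stalled.states,
    )


def _hash_params(params: Parameterization) -> str:
    return hashlib.sha256(repr(params.key()).encode()).hexdigest()[:12]


@dataclass
class AnalysisReport:
    verification: pd.DataFrame
    stg_stats: pd.DataFrame
    htg_stats: pd.DataFrame
    input_deadlocks: pd.DataFrame
    conserved: pd.DataFrame
    perturbations: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    mismatches: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        doc = {
            "verification": self.verification.to_dict(),
            "stg_stats": self.stg_stats.to_dict(orient="records"),
            "htg_stats": self.htg_stats.to_dict(orient="records"),
            "input_deadlocks": self.input_deadlocks.to_dict(orient="records"),
            "conserved": self.conserved.to_dict(orient="records"),
            "perturbations": self.perturbations.to_dict(orient="records"),
            "provenance": self.provenance,
            "mismatches": self.mismatches,
        }
        return json.dumps(doc, indent=1, default=bool)


# Reference values the reproduction run checks itself against: the toy
# example's quantities and the full model's structural counts under the
# count-validated reconstruction of the logical parameters (docs/methods.md
# discusses the two reference counts that provably cannot be reproduced).
EXPECTED = {
    "toy_states": 8,
    "toy_transitions": 12,
    "toy_deadlock": "000",
    "toy_enumeration": 36,
    "toy_satisfying": 2,
    "full_states": 1024,
    "full_transitions": 6144,
    "input_states": 256,
    "input4_deadlock": "0001000010",
    "input1_nodes": 2,
    "input1_roots": {"M1": 31, "M2": 33, "M3": 39, "M4": 29},
    "input2_nodes": {"M1": 4, "M2": 4, "M3": 4, "M4": 10},
    "largest_scc": {"M1": 992, "M2": 992, "M3": 944, "M4": 1024},
}


def reproduce_all(out_dir, fmt: str = "graphml", variants=None) -> AnalysisReport:
    """Regenerate every analysis, export graphs and write a report.

    Writes ``report.json``, ``report.md``, model files and STG/HTG exports
    under ``out_dir``; mismatches against the expected structural counts are
    recorded in the report (and should be empty on a clean run).
    """
    from .model_fixtures import toy_model, TOY_PROPERTY
    from .ctl import filter_parameterizations
    from .logic_core import enumerate_admissible_parameterizations

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mismatches: list[str] = []

    def expect(name, got, want):
        if got != want:
            mismatches.append(f"{name}: expected {want!r}, got {got!r}")

    # toy example
    toy_net, toy_params = toy_model()
    toy_stg = build_stg(toy_net, toy_params)
    expect("toy states", toy_stg.n_states, EXPECTED["toy_states"])
    expect("toy transitions", toy_stg.n_transitions, EXPECTED["toy_transitions"])
    expect(
        "toy deadlock",
        sorted(state_label(s) for s in stable_states(toy_stg)),
        [EXPECTED["toy_deadlock"]],
    )
    n_total = sum(1 for _ in enumerate_admissible_parameterizations(toy_net))
    expect("toy enumeration", n_total, EXPECTED["toy_enumeration"])
    sats = filter_parameterizations(toy_net, TOY_PROPERTY)
    expect("toy satisfying sets", len(sats), EXPECTED["toy_satisfying"])
    (out / "toy.json").write_text(model_to_json(toy_net, toy_params))

    net = metabolic_flexibility_network()
    variants = variants if variants is not None else pdk_variants()
    verification = run_verification(variants)
    for vid, row in verification.iterrows():
        for prop, ok in row.items():
            expect(f"verification {vid} / {prop}", bool(ok), True)

    analysis = run_network_analysis(variants)
    for _, row in analysis["stg_stats"].iterrows():
        expect(f"{row['variant']} states", row["states"], EXPECTED["full_states"])
        expect(
            f"{row['variant']} transitions",
            row["transitions"],
            EXPECTED["full_transitions"],
        )
        expect(
            f"{row['variant']} largest SCC",
            row["largest_scc"],
            EXPECTED["largest_scc"][row["variant"]],
        )
    for _, row in analysis["input_deadlocks"].iterrows():
        expect(
            f"{row['variant']} {row['input']} states",
            row["states"],
            EXPECTED["input_states"],
        )
        if row["input"] == "Input 4":
            expect(
                f"{row['variant']} Input 4 deadlock",
                row["deadlocks"],
                EXPECTED["input4_deadlock"],
            )
    htg_nodes = analysis["htg_stats"].groupby(["variant", "input"]).size()
    for vid in [v.id for v in variants]:
        if vid in EXPECTED["input1_roots"]:
            expect(
                f"{vid} Input 1 HTG nodes",
                int(htg_nodes.get((vid, "Input 1"), 0)),
                EXPECTED["input1_nodes"],
            )
            roots = analysis["htg_stats"].query(
                "variant == @vid and input == 'Input 1' "
                "and kind == 'rooted_irreversible'"
            )["size"]
            expect(
                f"{vid} Input 1 root size",
                list(roots),
                [EXPECTED["input1_roots"][vid]],
            )
            expect(
                f"{vid} Input 2 HTG nodes",
                int(htg_nodes.get((vid, "Input 2"), 0)),
                EXPECTED["input2_nodes"][vid],
            )

    perturbations = run_perturbations(variants)

    # graph exports (model 1's full STG plus every input-condition HTG)
    params_m1 = base_parameterization(variants[0], net)
    stg_m1 = build_stg(net, params_m1)
    if fmt == "graphml":
        stg_m1.write_graphml(out / "stg_model1.graphml")
    else:
        stg_m1.write_dot(out / "stg_model1.dot")
    for combo_name, htgs in analysis["htgs_by_input"].items():
        for v, htg in zip(variants, htgs):
            stem = f"htg_{v.id}_{combo_name.replace(' ', '').lower()}"
            if fmt == "graphml":
                htg.write_graphml(out / f"{stem}.graphml")
            else:
                from .dynamics import _write_dot

                _write_dot(htg.to_networkx(), out / f"{stem}.dot")
    for v in variants:
        (out / f"metaflex_{v.id.lower()}.json").write_text(
            model_to_json(net, base_parameterization(v, net))
        )
    from .ctl import write_properties_file
    from .model_fixtures import VERIFICATION_PROPERTIES

    (out / "toy.ctl").write_text(
        write_properties_file({"P2 maintenance and decay": TOY_PROPERTY})
    )
    (out / "verification.ctl").write_text(
        write_properties_file(dict(VERIFICATION_PROPERTIES))
    )
    (out / "perturbation.ctl").write_text(
        write_properties_file(dict(PERTURBATION_PROPERTIES))
    )

    report = AnalysisReport(
        verification=verification,
        stg_stats=analysis["stg_stats"],
        htg_stats=analysis["htg_stats"],
        input_deadlocks=analysis["input_deadlocks"],
        conserved=analysis["conserved"],
        perturbations=perturbations,
        provenance={
            "package": "metaflex",
            "model_hashes": {
                v.id: _hash_params(base_parameterization(v, net)) for v in variants
            },
        },
        mismatches=mismatches,
    )
    (out / "report.json").write_text(report.to_json())
    (out / "report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: AnalysisReport) -> str:
    lines = ["# Metabolic-flexibility model: reproduction report", ""]
    lines += ["## Verification matrix", "", report.verification.to_markdown(), ""]
    lines += ["## STG statistics", "", report.stg_stats.to_markdown(index=False), ""]
    lines += [
        "## Input-condition deadlocks",
        "",
        report.input_deadlocks.to_markdown(index=False),
        "",
    ]
    lines += [
        "## Conserved substructures (all four PDK variants)",
        "",
        report.conserved.to_markdown(index=False),
        "",
    ]
    lines += [
        "## Perturbation outcomes",
        "",
        report.perturbations.to_markdown(index=False),
        "",
    ]
    if report.mismatches:
        lines += ["## MISMATCHES", ""] + [f"- {m}" for m in report.mismatches]
    else:
        lines += ["All structural counts matched the expected values."]
    return "\n".join(lines) + "\n"
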