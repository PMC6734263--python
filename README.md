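# metaflex — logical modelling of cellular metabolic flexibility

Cellular metabolic flexibility is the capacity to switch the substrate
fuelling oxidative metabolism — acetyl-CoA production for the TCA cycle —
between glucose (glycolysis → pyruvate → pyruvate dehydrogenase complex,
PDC) and fatty acids (β-oxidation via carnitine transport).  The switch is
driven by the pyruvate dehydrogenase kinases (PDK), which inactivate PDC by
phosphorylation.  `metaflex` models this system in the discrete
kinetic-logic formalism and analyses it exhaustively: it is aimed at
systems biologists who want executable, checkable versions of the
qualitative arguments usually made with pathway cartoons.

The package provides a complete engine plus the encoded models:

- **`logic_core`** — signed regulatory networks, resource contexts, logical
  parameters `K_v : 2^{regulators(v)} → [0, max_v]`, and enumeration of all
  parameterizations admissible under the sign-monotonicity (Snoussi)
  constraints;
- **`dynamics`** — asynchronous unitary state transition graphs (STGs),
  deadlock detection, knockout/ectopic clamps, input-restricted state
  spaces, GraphML/DOT export;
- **`structure`** — SCC condensation and hierarchical transition graphs
  (HTGs) with the `ct#/ca#/i#/ss-` node taxonomy, plus cross-model
  conserved-substructure comparison;
- **`ctl`** — a CTL parser and explicit-state fixpoint model checker
  (`EX AX EF AF EG AG` over atoms `Entity=level`), and SMBioNet-style
  filtering of enumerated parameter sets by a property;
- **`model_fixtures`** — the three-entity toy network, the ten-entity
  metabolic-flexibility network (19 edges) with four PDK regulation
  hypotheses M1–M4 and their verification properties, and a seeded
  random-network generator for property-based testing;
- **`pipeline`** — the end-to-end analyses (verification matrix, network
  analysis, perturbation scenarios) and a one-command reproduction.

The numbered scripts under `analysis/` narrate the study end to end;
`docs/methods.md` documents the formalism, the parameter reconstruction and
its validation, and known limitations.

## Worked example

```python
from metaflex import (build_stg, build_htg, stable_states, state_label,
                      enumerate_admissible_parameterizations,
                      filter_parameterizations, Clamp)
from metaflex.model_fixtures import toy_model, TOY_PROPERTY

net, params = toy_model()          # P3 -> P1 (+), P2 -> P3 (+), P1 -> P3 (-)
stg = build_stg(net, params)
print(stg.n_states, stg.n_transitions)               # 8 12
print([state_label(s) for s in stable_states(stg)])  # ['000']
print([n.label for n in build_htg(stg).nodes])       # ['ct#4', 'i#3', 'ss-000']

total = sum(1 for _ in enumerate_admissible_parameterizations(net))
sats = filter_parameterizations(net, TOY_PROPERTY)
print(total, len(sats))                              # 36 2
```

The eight-state STG funnels through a four-state cycle (`ct#4`, sustained
while P2 stays available) into the deadlock `000`; of the 36 sign-monotone
parameter sets of this network, exactly 2 let P2 both maintain its level
along some path and decay along another — one of them being the published
table returned by `toy_model()`.

For the full model:

```python
from metaflex.pipeline import run_verification, run_network_analysis
print(run_verification())
print(run_network_analysis()["stg_stats"])
```

```
    Glucose Oxidation  Fatty acid Oxidation  Presence of PDK  Absence of PDK
M1               True                  True             True            True
M2               True                  True             True            True
M3               True                  True             True            True
M4               True                  True             True            True
  variant  states  transitions  largest_scc
0      M1    1024         6144          992
1      M2    1024         6144          992
2      M3    1024         6144          944
3      M4    1024         6144         1024
```

All four hypotheses for PDK regulation satisfy the four encoded behaviours
(16/16 checks), so each is a biologically plausible switch.  Every variant
yields 1,024 states and 6,144 transitions; the fluctuating Glucose and
Circulating-Fatty-Acids inputs fuse most of the state space into one giant
SCC (`largest_scc`).  Clamping the inputs to their four 0/1 combinations
splits the dynamics into four 256-state STGs whose HTGs expose the
structure: under glucose only, a rooted irreversible component draining
into a terminal SCC; under starvation, the unique deadlock
`ss-0001000010` — only PDC and AMPK left active, the model's picture of
approaching cell death.  Perturbations of the two non-metabolite
inhibitors close the argument: knocking out PDK lets acetyl-CoA flow from
both substrates at once, ectopic PDK under glucose starves the cell until
the clamp is released, and ectopic AMPK acts *through* PDK, locking the
system into fatty-acid-only metabolism (`EF(AG(PDK=1 & PDC=0))`).

The command-line entry point wraps the same machinery:

```sh
metaflex reproduce --out out/            # full reproduction + graph exports
metaflex verify --model out/toy.json --property out/toy.ctl --enumerate
metaflex verify --model out/metaflex_m1.json --property out/verification.ctl
```

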