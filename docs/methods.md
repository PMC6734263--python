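# Methods

## The modelling formalism

`metaflex` implements discrete (kinetic-logic) modelling of regulatory
networks.  A network is a signed directed graph over entities; each entity
`v` holds an integer level in `[0, max_level_v]` (Boolean throughout the
shipped models).  An edge `u -> v` with threshold `t` *supplies* its
interaction in a state when `level(u) >= t`.  The *resource context* of `v`
is the set of its regulators currently supplying their edges, and the
logical parameters `K_v : context -> target level` give the level toward
which `v` tends.  Dynamics are asynchronous and unitary: a transition
changes exactly one entity by exactly one level toward its target, so a
state has one successor per off-target entity and a state with every entity
on target is a deadlock (stable steady state).  The state transition graph
(STG) over `n` Boolean entities has `2^n` states; a guard (default `2^22`
states) refuses accidental state-space explosions.

Levels encode *availability* (able to perform its function), not
concentration.  This is what makes allosteric inhibition (pyruvate on PDK,
malonyl-CoA on carnitine transport) representable by a plain inhibitory
edge.

## Admissible parameterizations

The enumerator generates every complete `K` satisfying range and the
sign-monotonicity (Snoussi) constraints: adding an activator to a context
never lowers `K`, adding an inhibitor never raises it.  No observability
("every edge must matter somewhere") constraint is imposed — with it, the
three-entity example below would admit 12 or fewer parameter sets instead
of the 36 the verification analysis is built on.  Enumeration order is
deterministic: entities in canonical order, each entity's tables ordered
lexicographically over the value vector indexed by context bitmask.
Entities with more than 12 regulators are refused (the per-entity table
space is doubly exponential).

Hand-authored tables additionally follow the decay convention: in the
all-absent context an entity degrades (`K = 0`); the enumerator itself does
not impose this.

## CTL model checking

Formulae combine atoms `Entity=level` with `!  & | ->` and the six
quantifier-operator pairs `EX AX EF AF EG AG`.  Checking is explicit-state
fixpoint labelling (EX by pre-image, EG as a greatest fixpoint, EF via
least-fixpoint backward chaining, the A-forms by duality) over a totalized
view of the STG in which deadlocks carry an implicit self-loop — the
standard Kripke convention, needed so `EG phi` can hold in a deadlock.
Model-level satisfaction defaults to the *all-states* convention (the
formula holds in every configuration); the guarded-implication style of the
shipped properties makes them vacuously true where their antecedents fail.
An *initial-states* convention is available and is used for the
perturbation scenarios, where reachability from the resting state is what
matters.  The checker is deliberately explicit-state: the models here have
at most `2^10` states, far below where symbolic techniques pay off.

Parameter-set verification composes the two machines: enumerate every
admissible parameterization, build each STG, and keep the sets whose
dynamics satisfy the property.

## Hierarchical transition graphs

The HTG is an acyclic quotient of the STG.  Nontrivial SCCs become single
nodes — `ct#n` (transient, exits exist) or `ca#n` (terminal, a cyclic
attractor).  Deadlocks become `ss-<state>` nodes.  The remaining acyclic
states are grouped into irreversible components `i#n`; a component
containing a state with no incoming STG transition is *rooted*.  Label
collisions get ` (k)` ordinals in deterministic order.

Two grouping rules for the acyclic states are implemented.  The default,
`reachable`, merges trivial states that reach exactly the same set of
collapsed components (nontrivial SCCs and deadlocks); the alternative,
`wcc`, takes maximal weakly connected sets of trivial condensation
vertices.  The rules agree on the toy example, but only `reachable`
reproduces the reference two-node structure of the glucose-only input
condition of the full model (the `wcc` rule splits its 31-state root into
16 + 15); it was therefore made the default.

## The metabolic-flexibility model

Ten Boolean entities in canonical label order: Glucose, Pyruvate, PDK, PDC,
Acetyl-CoA, Citrate, Malonyl-CoA, Fatty Acids, AMPK, Circulating Fatty
Acids — so the starvation deadlock reads `ss-0001000010` (PDC and AMPK at
level 1).  Nineteen edges connect glycolysis, fatty-acid oxidation,
fatty-acid synthesis and the TCA cycle; the two inputs (Glucose,
Circulating Fatty Acids) carry inhibitory self-loops making each oscillate
between 0 and 1, which models fluctuating nutrient availability.  The
pyruvate-consumption interaction is encoded as an activating edge
Pyruvate -> Acetyl-CoA: the glucose route needs both the enzyme (PDC) and
its substrate (pyruvate), and without the substrate edge no sign-monotone
acetyl-CoA table can make the glucose route verifiable while keeping the
starvation deadlock stable.

Non-PDK entity rules (Boolean form of the `K` tables):

| entity | rule |
| --- | --- |
| Pyruvate | `Glucose AND NOT Citrate` |
| PDC | `NOT PDK` |
| Acetyl-CoA | `(PDC AND Pyruvate) OR (Fatty Acids AND NOT Malonyl-CoA)` |
| Citrate | `Acetyl-CoA` |
| Malonyl-CoA | `Citrate AND NOT AMPK` |
| Fatty Acids | `Circulating FA OR (Citrate AND Malonyl-CoA)` |
| AMPK | `NOT Acetyl-CoA` |
| inputs | oscillators (`K({}) = 1`, `K({self}) = 0`) |

PDK has an inhibitor (Pyruvate) and two activators (Acetyl-CoA via TCA
products, Fatty Acids via PPARγ), giving four regulation hypotheses, all
sign-monotone and pairwise distinct (with `P, A, F` for the three
regulators):

- **M1** `NOT P AND (A OR F)` — pyruvate always blocks;
- **M2** `(A AND F) OR (NOT P AND (A OR F))` — the activators jointly
  override pyruvate;
- **M3** `A OR (NOT P AND F)` — acetyl-CoA bypasses pyruvate;
- **M4** `F OR (NOT P AND A)` — fatty acids bypass pyruvate.

### Count-validated reconstruction

The non-PDK tables above are a reconstruction constrained by the edge
biochemistry, the decay convention, the four verification properties and
the structural reference counts.  The validation procedure enumerated every
sign-monotone alternative of the underdetermined tables (2,000 candidate
bases) and scored each against the reference counts (6,144 transitions;
992-state giant SCC; Input-1 root sizes; Input-2 node counts; the unique
starvation deadlock).  Exactly one base — the one above — reproduces all
M1/M2 anchors; the reconstruction is therefore unique within the admissible
space, not a convenient choice.

Two reference values could not be reproduced, and provably cannot be under
any sign-monotone PDK table combined with this (unique) base: (i) the
giant input-fluctuation SCC has 992 states for M1 and M2 only — every
acetyl-CoA-bypass-class table yields 944 and every fatty-acid-bypass-class
table fuses all 1,024 states; (ii) the Input-1 (glucose-only) rooted
component sizes come out 39 for M3 and 29 for M4, whereas the reference
pairing is 29/39 — yet a 29-state root always co-occurs with the
ten-node Input-2 HTG that unambiguously characterizes the fatty-acid
bypass (M4), so the reference pairing of 29/39 with M3/M4 is not realizable
by any admissible parameterization.  The corresponding acceptance tests
assert the reference pairing and are left failing by design; every other
structural count (including the 31/33 roots, the 4/4/4/10 Input-2 node
counts with M4's five irreversible + five SCC split, and the conserved
substructures per input) is reproduced exactly.

## Perturbation scenarios

Knockouts clamp an entity's `K` to 0 in every context, ectopic activity to
its maximum.  A clamped entity still *converges* to its clamp from any
starting level (so the toy's ectopic-P1 STG keeps all eight states and
funnels into `100`); input restriction instead removes the input
self-loops and freezes the input coordinates, producing the four 256-state
STGs.  Scenarios start from the resting state (free entities at 0, inputs
at their combination levels, the clamped entity at its clamp) and use the
forward-reachable STG.  Outcomes are CTL properties checked from that
initial state, recorded in `pipeline.PERTURBATION_PROPERTIES` so the
formalization can be amended without code changes; "dual-source
acetyl-CoA" is `EF(Pyruvate=1 & PDC=1 & Fatty Acids=1 & Malonyl-CoA=0 &
Acetyl-CoA=1)`, and "locks into fatty-acid metabolism" is
`EF(AG(PDK=1 & PDC=0))` — the system can reach a region it never leaves in
which PDK is persistently active and PDC disabled.

## The random-network generator

`model_fixtures.random_network(seed, ...)` produces seeded random signed
Boolean networks (independent Bernoulli edges, configurable density and
activator bias) together with a parameterization drawn uniformly from each
entity's admissible tables.  It is the workhorse of the property-based
tests: transition unit-step laws, CTL dualities against independent
reachability/cycle oracles, and HTG partition/acyclicity laws.  It emulates
network *shape*, not biology: no degree structure, no input stratification,
no multi-level entities — so passing property tests certifies the engine's
semantics, not the realism of any particular biological model.

## Problem sizes and limitations

Every shipped analysis is desk-scale: the largest graph is the 1,024-state
STG (milliseconds to build; the whole reproduction runs in seconds on one
CPU).  Property tests use 4–5-entity random networks with fixed seeds.
Known limitations: explicit-state checking only (no BDDs, no fairness, no
CTL*), no synchronous or priority-class update schemes, no parameter
inference from data, and the multi-valued (non-Boolean) code paths are
exercised by the unitary-step machinery but not by the shipped models,
which are all Boolean.
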