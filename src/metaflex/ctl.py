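"""Computation tree logic over state transition graphs.

Formulae combine atoms ``Entity=level`` with ``!``, ``&``, ``|``, ``->`` and
the six path quantifiers ``EX AX EF AF EG AG``.  Checking is explicit-state
fixpoint labelling over a totalized view of the STG in which every deadlock
state carries an implicit self-loop, so that ``EG phi`` holds in a deadlock
satisfying ``phi`` — the standard Kripke-structure convention.

Entity names may contain hyphens and internal spaces (``Acetyl-CoA=1``,
``Fatty Acids=0``), matching the notation used in the verification
properties of the metabolic-flexibility model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal

from .dynamics import StateTransitionGraph, State
from .logic_core import (
    Parameterization,
    RegulatoryNetwork,
    enumerate_admissible_parameterizations,
)

# -- AST -------------------------------------------------------------------


class CTLFormula:
    def __and__(self, other: "CTLFormula") -> "CTLFormula":
        return And(self, other)

    def __or__(self, other: "CTLFormula") -> "CTLFormula":
        return Or(self, other)

    def __invert__(self) -> "CTLFormula":
        return Not(self)


@dataclass(frozen=True)
class Atom(CTLFormula):
    entity: str
    level: int

    def __str__(self) -> str:
        return f"{self.entity}={self.level}"


@dataclass(frozen=True)
class Bool(CTLFormula):
    value: bool

    def __str__(self) -> str:
        return "true" if self.value else "false"


@dataclass(frozen=True)
class Not(CTLFormula):
    operand: CTLFormula

    def __str__(self) -> str:
        return f"!({self.operand})"


@dataclass(frozen=True)
class And(CTLFormula):
    left: CTLFormula
    right: CTLFormula

    def __str__(self) -> str:
        return f"({self.left} & {self.right})"


@dataclass(frozen=True)
class Or(CTLFormula):
    left: CTLFormula
    right: CTLFormula

    def __str__(self) -> str:
        return f"({self.left} | {self.right})"


@dataclass(frozen=True)
class Implies(CTLFormula):
    left: CTLFormula
    right: CTLFormula

    def __str__(self) -> str:
        return f"({self.left} -> {self.right})"


@dataclass(frozen=True)
class Temporal(CTLFormula):
    op: Literal["EX", "AX", "EF", "AF", "EG", "AG"]
    operand: CTLFormula

    def __str__(self) -> str:
        return f"{self.op}({self.operand})"


TEMPORAL_OPS = ("EX", "AX", "EF", "AF", "EG", "AG")


# -- parser ----------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<arrow>->)|(?P<punct>[()&|!~])|(?P<int>\d+)|(?P<eq>=)"
    r"|(?P<word>[A-Za-z_][A-Za-z0-9_\-+]*))"
)


class CTLSyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise CTLSyntaxError(f"unexpected character {text[pos]!r}", pos)
        for kind, value in m.groupdict().items():
            if value is not None:
                tokens.append((kind, value, m.start()))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


class _Parser:
    """Recursive descent: implication (right assoc) < or < and < unary."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.i]

    def advance(self) -> tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str, value: str | None = None) -> tuple[str, str, int]:
        tok = self.advance()
        if tok[0] != kind or (value is not None and tok[1] != value):
            raise CTLSyntaxError(
                f"expected {value or kind}, found {tok[1]!r}", tok[2]
            )
        return tok

    def parse(self) -> CTLFormula:
        formula = self.implication()
        tok = self.peek()
        if tok[0] != "end":
            raise CTLSyntaxError(f"trailing input {tok[1]!r}", tok[2])
        return formula

    def implication(self) -> CTLFormula:
        left = self.disjunction()
        if self.peek()[0] == "arrow":
            self.advance()
            return Implies(left, self.implication())
        return left

    def disjunction(self) -> CTLFormula:
        out = self.conjunction()
        while self.peek()[:2] == ("punct", "|"):
            self.advance()
            out = Or(out, self.conjunction())
        return out

    def conjunction(self) -> CTLFormula:
        out = self.unary()
        while self.peek()[:2] == ("punct", "&"):
            self.advance()
            out = And(out, self.unary())
        return out

    def unary(self) -> CTLFormula:
        kind, value, pos = self.peek()
        if kind == "punct" and value in "!~":
            self.advance()
            return Not(self.unary())
        if kind == "punct" and value == "(":
            self.advance()
            inner = self.implication()
            self.expect("punct", ")")
            return inner
        if kind == "word":
            if value in TEMPORAL_OPS:
                self.advance()
                return Temporal(value, self.unary())
            if value in ("true", "false"):
                self.advance()
                return Bool(value == "true")
            return self.atom()
        raise CTLSyntaxError(f"unexpected token {value!r}", pos)

    def atom(self) -> CTLFormula:
        # entity names may span several words ("Fatty Acids"); consume words
        # up to the '='
        words = [self.expect("word")[1]]
        while self.peek()[0] == "word":
            words.append(self.advance()[1])
        self.expect("eq")
        level = int(self.expect("int")[1])
        return Atom(" ".join(words), level)


def parse_ctl(text: str) -> CTLFormula:
    """Parse a CTL formula; raises :class:`CTLSyntaxError` with a position."""
    return _Parser(text).parse()


def bind_check(formula: CTLFormula, net: RegulatoryNetwork) -> None:
    """Verify every atom references a known entity and an in-range level."""
    for atom in iter_atoms(formula):
        ent = net.entity(atom.entity)  # raises KeyError for unknown names
        if not 0 <= atom.level <= ent.max_level:
            raise ValueError(
                f"atom {atom}: level outside [0, {ent.max_level}]"
            )


def iter_atoms(formula: CTLFormula) -> Iterable[Atom]:
    if isinstance(formula, Atom):
        yield formula
    elif isinstance(formula, Not):
        yield from iter_atoms(formula.operand)
    elif isinstance(formula, Temporal):
        yield from iter_atoms(formula.operand)
    elif isinstance(formula, (And, Or, Implies)):
        yield from iter_atoms(formula.left)
        yield from iter_atoms(formula.right)


# -- model checking --------------------------------------------------------


class KripkeView:
    """STG with totalized transitions: deadlocks receive a self-loop."""

    def __init__(self, stg: StateTransitionGraph):
        self.stg = stg
        self.states = stg.states
        succ = {s: set(t) for s, t in stg.successor_map().items()}
        for s, t in succ.items():
            if not t:
                t.add(s)
        self.succ = succ
        pred: dict[State, set[State]] = {s: set() for s in self.states}
        for a, ts in succ.items():
            for b in ts:
                pred[b].add(a)
        self.pred = pred

    def preimage(self, target: set[State]) -> set[State]:
        out: set[State] = set()
        for s in target:
            out |= self.pred[s]
        return out


def check(stg: StateTransitionGraph, formula: CTLFormula | str) -> set[State]:
    """Exact satisfying set of ``formula`` by fixpoint labelling."""
    if isinstance(formula, str):
        formula = parse_ctl(formula)
    return _sat(KripkeView(stg), formula)


def _sat(view: KripkeView, f: CTLFormula) -> set[State]:
    if isinstance(f, Bool):
        return set(view.states) if f.value else set()
    if isinstance(f, Atom):
        idx = view.stg.net.index(f.entity)
        return {s for s in view.states if s[idx] == f.level}
    if isinstance(f, Not):
        return set(view.states) - _sat(view, f.operand)
    if isinstance(f, And):
        return _sat(view, f.left) & _sat(view, f.right)
    if isinstance(f, Or):
        return _sat(view, f.left) | _sat(view, f.right)
    if isinstance(f, Implies):
        return (set(view.states) - _sat(view, f.left)) | _sat(view, f.right)
    if isinstance(f, Temporal):
        inner = _sat(view, f.operand)
        if f.op == "EX":
            return _ex(view, inner)
        if f.op == "AX":
            return set(view.states) - _ex(view, set(view.states) - inner)
        if f.op == "EF":
            return _eu(view, set(view.states), inner)
        if f.op == "AF":
            return set(view.states) - _eg(view, set(view.states) - inner)
        if f.op == "EG":
            return _eg(view, inner)
        if f.op == "AG":
            return set(view.states) - _eu(
                view, set(view.states), set(view.states) - inner
            )
    raise TypeError(f"not a CTL formula: {f!r}")


def _ex(view: KripkeView, target: set[State]) -> set[State]:
    return {s for s in view.states if view.succ[s] & target}


def _eu(view: KripkeView, hold: set[State], goal: set[State]) -> set[State]:
    """Least fixpoint of E[hold U goal] by backward chaining."""
    sat = set(goal)
    frontier = list(goal)
    while frontier:
        s = frontier.pop()
        for p in view.pred[s]:
            if p in hold and p not in sat:
                sat.add(p)
                frontier.append(p)
    return sat


def _eg(view: KripkeView, hold: set[State]) -> set[State]:
    """Greatest fixpoint: prune states with no successor still in the set."""
    sat = set(hold)
    changed = True
    while changed:
        changed = False
        for s in list(sat):
            if not (view.succ[s] & sat):
                sat.discard(s)
                changed = True
    return sat


def holds(
    stg: StateTransitionGraph,
    formula: CTLFormula | str,
    mode: Literal["all_states", "initial_states"] = "all_states",
    initial_states: Iterable[State] | None = None,
) -> bool:
    """Model-level satisfaction.

    ``all_states``: the formula holds in every state (the convention used for
    parameter-set verification; guarded implications are vacuously true where
    their antecedent fails).  ``initial_states``: holds in every given initial
    state (falling back to the STG's recorded initial states).
    """
    sat = check(stg, formula)
    if mode == "all_states":
        return sat == set(stg.states)
    if mode == "initial_states":
        init = (
            frozenset(tuple(s) for s in initial_states)
            if initial_states is not None
            else stg.initial_states
        )
        if init is None:
            raise ValueError("initial_states mode requires initial states")
        return set(init) <= sat
    raise ValueError(f"unknown satisfaction mode {mode!r}")


def read_properties_file(text: str) -> dict[str, CTLFormula]:
    """Parse a named-properties file.

    Format: ``[name]`` section headers, each followed by one formula
    (possibly wrapped over several lines); ``#`` lines are comments.
    """
    out: dict[str, CTLFormula] = {}
    name: str | None = None
    buf: list[str] = []

    def flush() -> None:
        nonlocal buf
        if name is not None and any(line.strip() for line in buf):
            out[name] = parse_ctl(" ".join(buf))
        buf = []

    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            continue
        if stripped.startswith("[") and stripped.endswith("]"):
            flush()
            name = stripped[1:-1].strip()
        elif stripped:
            buf.append(stripped)
    flush()
    return out


def write_properties_file(properties: dict[str, CTLFormula | str]) -> str:
    blocks = []
    for name, f in properties.items():
        blocks.append(f"[{name}]\n{f}")
    return "\n\n".join(blocks) + "\n"


def filter_parameterizations(
    net: RegulatoryNetwork,
    formula: CTLFormula | str,
    mode: Literal["all_states", "initial_states"] = "all_states",
    initial_states: Iterable[State] | None = None,
) -> list[Parameterization]:
    """Admissible parameterizations whose STG satisfies ``formula``.

    The reverse-engineering step: enumerate every sign-monotone parameter
    set, build each asynchronous STG, and keep the sets whose dynamics
    exhibit the encoded behaviour.  Deterministic enumeration order.
    """
    from .dynamics import build_stg

    if isinstance(formula, str):
        formula = parse_ctl(formula)
    bind_check(formula, net)
    out = []
    for params in enumerate_admissible_parameterizations(net):
        stg = build_stg(net, params)
        if holds(stg, formula, mode=mode, initial_states=initial_states):
            out.append(params)
    return out
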