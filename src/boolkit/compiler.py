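"""Compile a knowledge base into a bipartite Boolean model (bBM).

The bBM has one Boolean node per elemental reaction, per elemental state
(neutral states included), per component, per input and per gate-defined
output.  Update rules are derived mechanically:

* a reaction fires iff its components are present, its source states hold,
  every required (``!``) modifier holds and no inhibitory (``x``) modifier
  holds (gates inlined);
* a state holds iff its components are present and it is either produced
  this step or held over without being consumed — production dominates
  consumption, so a kinase/phosphatase pair that are both active keep both
  the modified and the neutral state TRUE.  This is *pool* semantics: a
  state node means "some molecules of the component carry this state", not
  a microstate of one molecule;
* a neutral state is additionally produced by every synthesis reaction of
  its component, and degradation consumes the target states named among the
  degradation reaction's required modifiers;
* a component with a synthesis reaction is produced by it and removed by
  degradation; a component without synthesis is constitutively present;
* outputs take their defining contingency expression; inputs hold their
  value unless clamped.

Gates are fully inlined, so compiled rules contain no gate references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .kb import Contingency, GateDef, KnowledgeBase
from .reactions import ElementalReaction
from .states import ElementalState, GateRef, InputRef, StateLike

__all__ = [
    "NodeId",
    "Expr",
    "Const",
    "Lit",
    "NextLit",
    "Not",
    "And",
    "Or",
    "BooleanModel",
    "CompileError",
    "enumerate_nodes",
    "inline_gates",
    "build_update_rules",
]


class CompileError(ValueError):
    pass


@dataclass(frozen=True)
class NodeId:
    kind: str  # "reaction" | "state" | "component" | "input" | "output"
    key: str

    def __str__(self) -> str:  # pragma: no cover
        return self.key


# ---------------------------------------------------------------------------
# Boolean expressions (literals are node keys; evaluation is pure)


class Expr:
    def evaluate(self, assignment: Mapping[str, bool],
                 next_reactions: Optional[Mapping[str, bool]] = None) -> bool:
        raise NotImplementedError

    def literals(self) -> Set[str]:
        raise NotImplementedError


@dataclass(frozen=True)
class Const(Expr):
    value: bool

    def evaluate(self, assignment, next_reactions=None) -> bool:
        return self.value

    def literals(self) -> Set[str]:
        return set()

    def __str__(self) -> str:
        return "TRUE" if self.value else "FALSE"


@dataclass(frozen=True)
class Lit(Expr):
    key: str

    def evaluate(self, assignment, next_reactions=None) -> bool:
        return assignment[self.key]

    def literals(self) -> Set[str]:
        return {self.key}

    def __str__(self) -> str:
        return self.key


@dataclass(frozen=True)
class NextLit(Expr):
    """A reaction literal evaluated at the step being computed.

    State production is instantaneous: the producing reaction's rule is
    evaluated on the current assignment and its product appears in the same
    synchronous update, while consumption acts with a one-step delay through
    the reaction node.  This asymmetry is what makes production dominate
    consumption — an unconstrained kinase/phosphatase pair settles with both
    the modified and the neutral state TRUE instead of chasing each other
    around a cycle.
    """

    key: str

    def evaluate(self, assignment, next_reactions=None) -> bool:
        if next_reactions is None:
            return assignment[self.key]
        return next_reactions[self.key]

    def literals(self) -> Set[str]:
        return {self.key}

    def __str__(self) -> str:
        return f"next({self.key})"


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr

    def evaluate(self, assignment, next_reactions=None) -> bool:
        return not self.operand.evaluate(assignment, next_reactions)

    def literals(self) -> Set[str]:
        return self.operand.literals()

    def __str__(self) -> str:
        return f"NOT({self.operand})"


def _flatten(cls, operands: Iterable[Expr]) -> Tuple[Expr, ...]:
    out: List[Expr] = []
    for op in operands:
        if isinstance(op, cls):
            out.extend(op.operands)
        else:
            out.append(op)
    return tuple(out)


@dataclass(frozen=True)
class And(Expr):
    operands: Tuple[Expr, ...]

    def __init__(self, operands: Iterable[Expr]):
        object.__setattr__(self, "operands", _flatten(And, operands))

    def evaluate(self, assignment, next_reactions=None) -> bool:
        return all(op.evaluate(assignment, next_reactions) for op in self.operands)

    def literals(self) -> Set[str]:
        return set().union(*(op.literals() for op in self.operands)) if self.operands else set()

    def __str__(self) -> str:
        return "AND(" + ", ".join(map(str, self.operands)) + ")"


@dataclass(frozen=True)
class Or(Expr):
    operands: Tuple[Expr, ...]

    def __init__(self, operands: Iterable[Expr]):
        object.__setattr__(self, "operands", _flatten(Or, operands))

    def evaluate(self, assignment, next_reactions=None) -> bool:
        return any(op.evaluate(assignment, next_reactions) for op in self.operands)

    def literals(self) -> Set[str]:
        return set().union(*(op.literals() for op in self.operands)) if self.operands else set()

    def __str__(self) -> str:
        return "OR(" + ", ".join(map(str, self.operands)) + ")"


def _and(operands: Sequence[Expr]) -> Expr:
    operands = [op for op in operands if not (isinstance(op, Const) and op.value)]
    if not operands:
        return Const(True)
    if len(operands) == 1:
        return operands[0]
    return And(operands)


def _or(operands: Sequence[Expr]) -> Expr:
    operands = [op for op in operands if not (isinstance(op, Const) and not op.value)]
    if not operands:
        return Const(False)
    if len(operands) == 1:
        return operands[0]
    return Or(operands)


# ---------------------------------------------------------------------------


@dataclass
class BooleanModel:
    """Bipartite Boolean model: nodes, one update rule per node, and the
    clampable input subset."""

    nodes: List[NodeId]
    rules: Dict[str, Expr]
    clampable: Set[str]

    @property
    def node_keys(self) -> List[str]:
        return [n.key for n in self.nodes]

    @property
    def kinds(self) -> Dict[str, str]:
        return {n.key: n.kind for n in self.nodes}

    def __post_init__(self) -> None:
        keys = set(self.node_keys)
        if len(keys) != len(self.nodes):
            raise CompileError("duplicate node keys")
        for key, rule in self.rules.items():
            missing = rule.literals() - keys
            if missing:
                raise CompileError(
                    f"rule for {key} references undeclared nodes {sorted(missing)}"
                )


def enumerate_nodes(kb: KnowledgeBase) -> List[NodeId]:
    """All bBM nodes: reactions; every state that is a reaction effect or a
    contingency modifier plus its neutral partner(s); components; inputs;
    outputs."""
    nodes: List[NodeId] = [NodeId("reaction", r.text) for r in kb.reactions]

    states: Dict[str, ElementalState] = {}

    def add_state(state: ElementalState) -> None:
        if state.key not in states:
            states[state.key] = state
            for partner in state.neutral_partners():
                add_state(partner)

    for r in kb.reactions:
        for state in sorted(r.consumed | r.produced, key=lambda s: s.key):
            add_state(state)
        if r.synthesises:
            for state in kb.neutral_states_of(r.synthesises):
                add_state(state)
    for state in kb.iter_modifier_states():
        add_state(state)

    nodes.extend(NodeId("state", key) for key in states)
    nodes.extend(NodeId("component", c) for c in kb.components)
    nodes.extend(NodeId("input", i.render()) for i in kb.inputs)
    nodes.extend(NodeId("output", o.render()) for o in kb.outputs)
    return nodes


def inline_gates(kb: KnowledgeBase, modifier: StateLike,
                 negate: bool = False) -> Expr:
    """Inline a contingency modifier into a gate-free expression.

    Gate references are substituted by their definitions, recursively (the
    gate graph is acyclic after validation).  NOT over a neutral-state
    reference is permitted — it reads as "the site is modified/bound"."""
    expr = _inline(kb, modifier)
    return Not(expr) if negate else expr


def _inline(kb: KnowledgeBase, modifier: StateLike) -> Expr:
    if isinstance(modifier, GateRef):
        gate = kb.gates.get(modifier.name)
        if gate is None:
            raise CompileError(f"gate <{modifier.name}> has no definition")
        members = [_inline(kb, m) for m in gate.members]
        if gate.op == "NOT":
            if len(members) != 1:
                raise CompileError(f"NOT gate <{modifier.name}> must have one member")
            return Not(members[0])
        if gate.op == "AND":
            return _and(members)
        return _or(members)
    if isinstance(modifier, InputRef):
        return Lit(modifier.render())
    return Lit(modifier.key)


def _contingency_terms(kb: KnowledgeBase, target_key: str) -> List[Expr]:
    """Required rows inlined as-is, inhibitory rows as negations; no-effect
    rows compile to nothing."""
    terms: List[Expr] = []
    for c in kb.contingencies_for(target_key):
        if c.kind == "!":
            terms.append(inline_gates(kb, c.modifier))
        elif c.kind == "x":
            terms.append(inline_gates(kb, c.modifier, negate=True))
    return terms


def build_update_rules(kb: KnowledgeBase) -> BooleanModel:
    """Construct the bBM for a validated knowledge base."""
    nodes = enumerate_nodes(kb)
    state_keys = {n.key for n in nodes if n.kind == "state"}
    component_keys = {n.key for n in nodes if n.kind == "component"}

    # Rebuild the state objects seen during enumeration (for component and
    # neutral bookkeeping).
    states: Dict[str, ElementalState] = {}

    def register(state: ElementalState) -> None:
        states.setdefault(state.key, state)
        for partner in state.neutral_partners():
            states.setdefault(partner.key, partner)

    for r in kb.reactions:
        for state in r.consumed | r.produced:
            register(state)
        if r.synthesises:
            for state in kb.neutral_states_of(r.synthesises):
                register(state)
    for state in kb.iter_modifier_states():
        register(state)

    # Producer / consumer maps over state keys.
    producers: Dict[str, List[str]] = {key: [] for key in states}
    consumers: Dict[str, List[str]] = {key: [] for key in states}
    synthesis_of: Dict[str, List[str]] = {}
    degradation_of: Dict[str, List[str]] = {}
    for r in kb.reactions:
        for state in r.produced:
            producers[state.key].append(r.text)
        for state in r.consumed:
            consumers[state.key].append(r.text)
        if r.synthesises:
            synthesis_of.setdefault(r.synthesises, []).append(r.text)
            for state in kb.neutral_states_of(r.synthesises):
                producers[state.key].append(r.text)
        target = r.degrades
        if target:
            degradation_of.setdefault(target, []).append(r.text)
            # A degradation consumes the target states named among its
            # required modifiers (e.g. the ubiquitin mark that recruited it).
            for c in kb.contingencies_for(r.text):
                if c.kind == "!" and isinstance(c.modifier, ElementalState):
                    if target in c.modifier.components and c.modifier.key in states:
                        consumers[c.modifier.key].append(r.text)

    rules: Dict[str, Expr] = {}

    for r in kb.reactions:
        terms: List[Expr] = [Lit(c) for c in r.required_components]
        for state in sorted(r.consumed, key=lambda s: s.key):
            terms.append(Lit(state.key))
        terms.extend(_contingency_terms(kb, r.text))
        rules[r.text] = _and(terms)

    for key, state in states.items():
        produced_by = [NextLit(t) for t in dict.fromkeys(producers[key])]
        consumed_by = [Lit(t) for t in dict.fromkeys(consumers[key])]
        if not produced_by and not state.is_neutral and consumers[key]:
            raise CompileError(
                f"state {key} is consumed but has no producer and is not neutral"
            )
        presence = [Lit(c) for c in state.components if c in component_keys]
        # A component with no synthesis reaction is an unlimited constitutive
        # pool, so its neutral sites can never be exhausted: some molecules
        # are always unmodified/unbound.
        constitutive_pool = state.is_neutral and all(
            not synthesis_of.get(c) for c in state.components
        )
        if constitutive_pool:
            rules[key] = _and(presence)
            continue
        hold = _and([Lit(key), Not(_or(consumed_by))]) if consumed_by else Lit(key)
        persistence = _or(produced_by + [hold])
        rules[key] = _and(presence + [persistence])

    for component in kb.components:
        synth = [Lit(t) for t in synthesis_of.get(component, [])]
        deg = [Lit(t) for t in degradation_of.get(component, [])]
        if not synth:
            rules[component] = Const(True)
        elif deg:
            rules[component] = _or(synth + [_and([Lit(component), Not(_or(deg))])])
        else:
            rules[component] = _or(synth + [Lit(component)])

    for i in kb.inputs:
        rules[i.render()] = Lit(i.render())

    for o in kb.outputs:
        terms = _contingency_terms(kb, o.render())
        rules[o.render()] = _and(terms) if terms else Const(False)

    clampable = {i.render() for i in kb.inputs}
    return BooleanModel(nodes, rules, clampable)
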