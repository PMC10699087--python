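"""Knowledge bases: reaction lists, contingency lists, gates, validation.

A knowledge base pairs a *ReactionList* (elemental reactions) with a
*ContingencyList* (regulatory constraints).  A contingency row constrains a
reaction or an output with a required (``!``), inhibitory (``x``) or
no-effect (``0``) modifier; rows whose kind is AND/OR/NOT instead define a
named Boolean gate, member by member.  Bracketed names appearing as
contingency targets are system outputs; bracketed names appearing only as
modifiers (or gate members) are system inputs.

The on-disk dialect is two UTF-8 TSV tables plus a reaction-type registry
table.  Header names may carry a leading ``!`` (as in printed contingency
tables); it is stripped.  Unrecognised columns are preserved as opaque
metadata.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from .reactions import ElementalReaction, Registry, parse_reaction
from .states import (
    BondState,
    ElementalState,
    FreeDomainState,
    GateRef,
    InputRef,
    Locus,
    ModificationState,
    ParseError,
    StateLike,
    parse_state,
)

__all__ = [
    "GateDef",
    "Contingency",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "ValidationIssue",
    "ValidationReport",
    "load_knowledge_base",
    "write_knowledge_base",
    "validate_knowledge_base",
]

STRICT_KINDS = ("!", "x", "0")
GATE_KINDS = ("AND", "OR", "NOT")


class KnowledgeBaseError(ValueError):
    """Structural error while assembling a knowledge base."""


@dataclass
class GateDef:
    """A named AND/OR/NOT combination of states, inputs and other gates."""

    name: str
    op: str
    members: List[StateLike] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.op not in GATE_KINDS:
            raise KnowledgeBaseError(f"invalid gate op {self.op!r} for <{self.name}>")


@dataclass
class Contingency:
    """One contingency row: a constraint on a reaction or output, or one
    member of a gate definition."""

    uid: int
    target: Union[ElementalReaction, InputRef, GateRef]
    kind: str  # "!", "x", "0", "AND", "OR", "NOT"
    modifier: StateLike
    reference: str = ""

    @property
    def is_gate_row(self) -> bool:
        return self.kind in GATE_KINDS

    @property
    def target_key(self) -> str:
        if isinstance(self.target, ElementalReaction):
            return self.target.text
        return self.target.render()


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    ref: str = ""


@dataclass
class ValidationReport:
    issues: List[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> List[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> List[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        """Empty error list <=> the KB is accepted for compilation."""
        return not self.errors

    def add(self, severity: str, code: str, message: str, ref: str = "") -> None:
        self.issues.append(ValidationIssue(severity, code, message, ref))

    def __str__(self) -> str:
        if not self.issues:
            return "knowledge base OK (no issues)"
        lines = [f"{i.severity.upper()} [{i.code}] {i.message}"
                 + (f" ({i.ref})" if i.ref else "") for i in self.issues]
        return "\n".join(lines)


@dataclass
class KnowledgeBase:
    """A reaction-contingency knowledge base."""

    reactions: List[ElementalReaction] = field(default_factory=list)
    contingencies: List[Contingency] = field(default_factory=list)
    gates: Dict[str, GateDef] = field(default_factory=dict)
    registry: Registry = field(default_factory=Registry.default)
    metadata: Dict[str, object] = field(default_factory=dict)

    # -- derived inventories -------------------------------------------------

    @property
    def reaction_index(self) -> Dict[str, ElementalReaction]:
        return {r.text: r for r in self.reactions}

    @property
    def outputs(self) -> List[InputRef]:
        """Bracketed names appearing as contingency targets, in first-seen order."""
        seen: Dict[str, InputRef] = {}
        for c in self.contingencies:
            if isinstance(c.target, InputRef):
                seen.setdefault(c.target.name, c.target)
        return list(seen.values())

    def _referenced_bracket_names(self) -> List[str]:
        seen: Dict[str, None] = {}
        visited_gates: Set[str] = set()

        def visit(modifier: StateLike) -> None:
            if isinstance(modifier, InputRef):
                seen.setdefault(modifier.name)
            elif isinstance(modifier, GateRef):
                if modifier.name in visited_gates:
                    return
                visited_gates.add(modifier.name)
                gate = self.gates.get(modifier.name)
                if gate is not None:
                    for member in gate.members:
                        visit(member)

        for c in self.contingencies:
            visit(c.modifier)
        return list(seen)

    @property
    def inputs(self) -> List[InputRef]:
        """Bracketed names referenced as modifiers/gate members that are not
        outputs: the clampable system boundary."""
        output_names = {o.name for o in self.outputs}
        return [InputRef(n) for n in self._referenced_bracket_names()
                if n not in output_names]

    @property
    def components(self) -> List[str]:
        """Every component touched by a reaction (synthesis products included),
        in first-seen order."""
        seen: Dict[str, None] = {}
        for r in self.reactions:
            for c in r.components:
                seen.setdefault(c)
        return list(seen)

    def loci_of(self, component: str) -> List[Locus]:
        """Locus inventory of a component across reactions and contingency
        states (used to derive the neutral states a synthesis produces)."""
        seen: Dict[Locus, None] = {}

        def visit_state(state: ElementalState) -> None:
            if isinstance(state, ModificationState) and state.component == component:
                seen.setdefault(state.residue)
            elif isinstance(state, FreeDomainState) and state.component == component:
                seen.setdefault(state.domain)
            elif isinstance(state, BondState):
                for comp, locus in (state.endpoint_a, state.endpoint_b):
                    if comp == component:
                        seen.setdefault(locus)

        for r in self.reactions:
            for state in list(r.consumed) + list(r.produced):
                visit_state(state)
        for state in self.iter_modifier_states():
            visit_state(state)
        return list(seen)

    def neutral_states_of(self, component: str) -> List[ElementalState]:
        out: List[ElementalState] = []
        for locus in self.loci_of(component):
            if locus.kind == "residue":
                out.append(ModificationState(component, locus, "0"))
            else:
                out.append(FreeDomainState(component, locus))
        return out

    def iter_modifier_states(self) -> Iterable[ElementalState]:
        """All elemental states referenced by contingencies, gates included."""
        seen: Set[str] = set()
        visited_gates: Set[str] = set()

        def visit(modifier: StateLike):
            if isinstance(modifier, GateRef):
                if modifier.name in visited_gates:
                    return
                visited_gates.add(modifier.name)
                gate = self.gates.get(modifier.name)
                if gate is not None:
                    for member in gate.members:
                        yield from visit(member)
            elif isinstance(modifier, (InputRef,)):
                return
            else:
                if modifier.key not in seen:
                    seen.add(modifier.key)
                    yield modifier

        for c in self.contingencies:
            yield from visit(c.modifier)

    def contingencies_for(self, target_key: str) -> List[Contingency]:
        return [c for c in self.contingencies
                if not c.is_gate_row and c.target_key == target_key]

    def producers_of(self, state: ElementalState) -> List[ElementalReaction]:
        return [r for r in self.reactions if state in r.produced]


def _normalise_columns(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.rename(columns=lambda c: str(c).lstrip("!").strip())


def _as_frame(source, expected_name: str) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return _normalise_columns(source)
    path = os.fspath(source)
    if path.endswith((".xlsx", ".xls")):
        frame = pd.read_excel(path, dtype=str)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    return _normalise_columns(frame)


def _gate_cycle(gates: Dict[str, GateDef]) -> Optional[List[str]]:
    """Return one cycle through the gate-reference graph, or None."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {name: WHITE for name in gates}
    stack: List[str] = []

    def dfs(name: str) -> Optional[List[str]]:
        colour[name] = GREY
        stack.append(name)
        for member in gates[name].members:
            if isinstance(member, GateRef) and member.name in gates:
                if colour[member.name] == GREY:
                    return stack[stack.index(member.name):] + [member.name]
                if colour[member.name] == WHITE:
                    found = dfs(member.name)
                    if found:
                        return found
        colour[name] = BLACK
        stack.pop()
        return None

    for name in gates:
        if colour[name] == WHITE:
            found = dfs(name)
            if found:
                return found
    return None


def load_knowledge_base(
    reaction_table,
    contingency_table,
    registry: Optional[Registry] = None,
) -> KnowledgeBase:
    """Assemble a knowledge base from ReactionList / ContingencyList tables.

    ``reaction_table`` needs a ``Reaction`` column (``UID`` and ``Reference``
    optional); ``contingency_table`` needs ``UID``, ``Target``,
    ``Contingency`` and ``Modifier``.  Either argument may be a TSV/XLSX
    path or a DataFrame.
    """
    registry = registry or Registry.default()
    rframe = _as_frame(reaction_table, "ReactionList")
    cframe = _as_frame(contingency_table, "ContingencyList")
    if "Reaction" not in rframe.columns:
        raise KnowledgeBaseError("ReactionList table lacks a 'Reaction' column")
    for column in ("UID", "Target", "Contingency", "Modifier"):
        if column not in cframe.columns:
            raise KnowledgeBaseError(f"ContingencyList table lacks a {column!r} column")

    reactions: List[ElementalReaction] = []
    for _, row in rframe.iterrows():
        text = row["Reaction"]
        if pd.isna(text) or not str(text).strip():
            continue
        reactions.append(parse_reaction(str(text), registry))
    reaction_index = {r.text: r for r in reactions}

    modifiers = registry.modifiers
    contingencies: List[Contingency] = []
    gates: Dict[str, GateDef] = {}
    seen_uids: Set[int] = set()
    for _, row in cframe.iterrows():
        if pd.isna(row["Target"]) or not str(row["Target"]).strip():
            continue
        uid = int(row["UID"])
        if uid in seen_uids:
            raise KnowledgeBaseError(f"duplicate contingency UID {uid}")
        seen_uids.add(uid)
        target_text = str(row["Target"]).strip()
        kind = str(row["Contingency"]).strip()
        modifier = parse_state(str(row["Modifier"]), modifiers)
        reference = "" if pd.isna(row.get("Reference")) else str(row.get("Reference"))

        target: Union[ElementalReaction, InputRef, GateRef]
        if target_text.startswith("<"):
            target = parse_state(target_text)
            if not isinstance(target, GateRef):
                raise KnowledgeBaseError(f"malformed gate target {target_text!r}")
        elif target_text.startswith("["):
            target = parse_state(target_text)
        else:
            parsed = parse_reaction(target_text, registry)
            target = reaction_index.get(parsed.text, parsed)

        kind_upper = kind.upper()
        if kind_upper in GATE_KINDS:
            if not isinstance(target, GateRef):
                raise KnowledgeBaseError(
                    f"contingency kind {kind!r} requires a gate target (UID {uid})"
                )
            kind = kind_upper
            gate = gates.get(target.name)
            if gate is None:
                gates[target.name] = gate = GateDef(target.name, kind)
            elif gate.op != kind:
                raise KnowledgeBaseError(
                    f"gate <{target.name}> mixes {gate.op} and {kind} rows"
                )
            gate.members.append(modifier)
        elif kind not in STRICT_KINDS:
            raise KnowledgeBaseError(f"unknown contingency kind {kind!r} (UID {uid})")
        contingencies.append(Contingency(uid, target, kind, modifier, reference))

    cycle = _gate_cycle(gates)
    if cycle:
        raise KnowledgeBaseError("gate cycle: " + " -> ".join(cycle))

    extra_r = [c for c in rframe.columns if c not in ("UID", "Reaction", "Reference")]
    extra_c = [c for c in cframe.columns
               if c not in ("UID", "Target", "Contingency", "Modifier", "Reference")]
    metadata: Dict[str, object] = {}
    if extra_r:
        metadata["reaction_extra_columns"] = rframe[["Reaction"] + extra_r]
    if extra_c:
        metadata["contingency_extra_columns"] = cframe[["UID"] + extra_c]
    return KnowledgeBase(reactions, contingencies, gates, registry, metadata)


def write_knowledge_base(kb: KnowledgeBase, directory) -> None:
    """Write the KB as ``reactions.tsv``, ``contingencies.tsv`` and
    ``registry.tsv`` under ``directory``."""
    os.makedirs(directory, exist_ok=True)
    rrows = [(i + 1, r.text, "") for i, r in enumerate(kb.reactions)]
    pd.DataFrame(rrows, columns=["UID", "Reaction", "Reference"]).to_csv(
        os.path.join(directory, "reactions.tsv"), sep="\t", index=False
    )
    crows = []
    for c in kb.contingencies:
        modifier = c.modifier.render() if hasattr(c.modifier, "render") else str(c.modifier)
        crows.append((c.uid, c.target_key, c.kind, modifier, c.reference))
    pd.DataFrame(
        crows, columns=["UID", "Target", "Contingency", "Modifier", "Reference"]
    ).to_csv(os.path.join(directory, "contingencies.tsv"), sep="\t", index=False)
    kb.registry.to_frame().to_csv(
        os.path.join(directory, "registry.tsv"), sep="\t", index=False
    )


def load_knowledge_base_dir(directory, registry: Optional[Registry] = None) -> KnowledgeBase:
    """Load a KB from a directory written by :func:`write_knowledge_base`."""
    registry_path = os.path.join(directory, "registry.tsv")
    if registry is None and os.path.exists(registry_path):
        registry = Registry.from_frame(pd.read_csv(registry_path, sep="\t", dtype=str))
    return load_knowledge_base(
        os.path.join(directory, "reactions.tsv"),
        os.path.join(directory, "contingencies.tsv"),
        registry,
    )


def validate_knowledge_base(kb: KnowledgeBase) -> ValidationReport:
    """Check structural consistency; the report carries all findings.

    Errors: dangling contingency targets, gate cycles, undefined gate
    references, malformed gate arities, duplicate UIDs.  Warnings:
    non-neutral states never produced by any reaction, outputs with no
    defining contingency, components never appearing in any reaction.
    """
    report = ValidationReport()
    reaction_keys = set(kb.reaction_index)

    seen_uids: Set[int] = set()
    for c in kb.contingencies:
        if c.uid in seen_uids:
            report.add("error", "duplicate-uid", f"duplicate UID {c.uid}", str(c.uid))
        seen_uids.add(c.uid)
        if isinstance(c.target, ElementalReaction) and c.target.text not in reaction_keys:
            report.add(
                "error", "dangling-target",
                f"contingency targets unknown reaction {c.target.text}", f"UID {c.uid}",
            )
        if c.is_gate_row and not isinstance(c.target, GateRef):
            report.add(
                "error", "gate-kind-on-non-gate",
                f"kind {c.kind} requires a gate target", f"UID {c.uid}",
            )

    def visit_gate_refs(modifier: StateLike, ref: str) -> None:
        if isinstance(modifier, GateRef) and modifier.name not in kb.gates:
            report.add("error", "undefined-gate",
                       f"gate <{modifier.name}> has no definition", ref)

    for c in kb.contingencies:
        visit_gate_refs(c.modifier, f"UID {c.uid}")
    for gate in kb.gates.values():
        for member in gate.members:
            visit_gate_refs(member, f"<{gate.name}>")
        if gate.op == "NOT" and len(gate.members) != 1:
            report.add("error", "gate-arity",
                       f"NOT gate <{gate.name}> must have exactly one member")
        if gate.op in ("AND", "OR") and len(gate.members) < 2:
            report.add("error", "gate-arity",
                       f"{gate.op} gate <{gate.name}> needs at least two members")

    cycle = _gate_cycle(kb.gates)
    if cycle:
        report.add("error", "gate-cycle", "gate cycle: " + " -> ".join(cycle))

    producible = {s.key for r in kb.reactions for s in r.produced}
    synthesised = {r.synthesises for r in kb.reactions if r.synthesises}
    for state in kb.iter_modifier_states():
        if state.is_neutral:
            continue
        if state.key not in producible:
            report.add("warning", "unproducible-state",
                       f"state {state.key} is never produced by any reaction")
    # Consumed non-neutral states should be producible too (reverse reactions
    # whose forward partner is missing).
    for r in kb.reactions:
        for state in r.consumed:
            if not state.is_neutral and state.key not in producible:
                report.add("warning", "unproducible-state",
                           f"consumed state {state.key} has no producer", r.text)

    reacting = {c for r in kb.reactions for c in r.components}
    for state in kb.iter_modifier_states():
        for comp in state.components:
            if comp not in reacting:
                report.add("warning", "inert-component",
                           f"component {comp} never appears in any reaction",
                           state.key)

    for output in kb.outputs:
        rows = kb.contingencies_for(output.render())
        if not any(r.kind in ("!", "x") for r in rows):
            report.add("warning", "undefined-output",
                       f"output {output.render()} has no defining contingency")
    return report
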