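"""Elemental reactions and the reaction-type registry.

An elemental reaction is a typed, decontextualised event written
``A[locus]_type_B[locus]``: a kinase phosphorylating one residue
(``AKT_P+_NLRP3_[(S5)]``), two domains binding
(``NEK7_[clobe]_ppi+_NLRP3_[HD2LRR]``), synthesis or degradation of a
component, or a nucleotide-cycle step.  The consumed and produced elemental
states are *derived* from the reaction type's effect pattern instantiated at
the subjects' loci; any further context (what else must be bound or
modified) lives in the contingency list, never in the reaction itself.

Reaction types are data, not code: the registry maps a type token to a
class (state-change, synthesis, degradation) and an effect pattern, so new
types (the ATPase-cycle trio ``aBind``/``aHy``/``aEx``, for instance) are
declared in a registry table shipped alongside the reaction list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Optional, Tuple

import pandas as pd

from .states import (
    BondState,
    ElementalState,
    FreeDomainState,
    Locus,
    ModificationState,
    ParseError,
    parse_component_spec,
)

__all__ = [
    "ReactionType",
    "Registry",
    "ElementalReaction",
    "parse_reaction",
    "MRNA_SUFFIX",
]

MRNA_SUFFIX = "mRNA"

_BOND_TOKENS = {"free", "bond"}


@dataclass(frozen=True)
class ReactionType:
    """A reaction type: a token, a class and an effect pattern.

    For state-change types the pattern is either a modifier rewrite
    (``source -> product`` modifier tokens over subjectB's residue) or a
    bond rewrite (``free -> bond`` / ``bond -> free`` over the subjects'
    domains).  Synthesis and degradation types have no effect pairs; their
    effects are derived (all neutral states of the target, or component
    removal).
    """

    name: str
    cls: str  # "state-change" | "synthesis" | "degradation"
    source: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if self.cls not in ("state-change", "synthesis", "degradation"):
            raise ValueError(f"invalid reaction class {self.cls!r}")
        if self.cls == "state-change" and not (self.source and self.product):
            raise ValueError(f"state-change type {self.name!r} needs an effect pair")

    @property
    def mechanism(self) -> str:
        """One of modification, bond, bond-break, synthesis-mrna,
        synthesis-protein, degradation."""
        if self.cls == "degradation":
            return "degradation"
        if self.cls == "synthesis":
            return "synthesis-mrna" if self.product == MRNA_SUFFIX else "synthesis-protein"
        if self.product == "bond":
            return "bond"
        if self.product == "free":
            return "bond-break"
        return "modification"


# The normative registry.  (type, class, source pattern, product pattern)
_DEFAULT_TYPES = [
    ("P+", "state-change", "0", "P"),
    ("P-", "state-change", "P", "0"),
    ("ub48+", "state-change", "0", "ub48"),
    ("ub63+", "state-change", "0", "ub63"),
    ("ub63-", "state-change", "ub63", "0"),
    ("cut", "state-change", "0", "truncated"),
    ("ppi+", "state-change", "free", "bond"),
    ("ppi-", "state-change", "bond", "free"),
    ("i", "state-change", "free", "bond"),  # lipid binding, alias of ppi+
    ("trsc", "synthesis", "", "mRNA"),
    ("trsl", "synthesis", "", "protein"),
    ("deg", "degradation", "", ""),
    ("aBind", "state-change", "0", "ATP"),
    ("aHy", "state-change", "ATP", "ADP"),
    ("aEx", "state-change", "ADP", "ATP"),
]


class Registry:
    """Reaction-type and modifier registries (data, not code)."""

    def __init__(self, types: Iterable[ReactionType]):
        self.types: Dict[str, ReactionType] = {t.name: t for t in types}

    @property
    def modifiers(self) -> set:
        """Modifier alphabet derived from the modification effect patterns."""
        tokens = {"0"}
        for t in self.types.values():
            if t.cls == "state-change" and t.source not in _BOND_TOKENS:
                tokens.update({t.source, t.product})
        return tokens

    @classmethod
    def default(cls) -> "Registry":
        return cls(ReactionType(*row) for row in _DEFAULT_TYPES)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Registry":
        frame = frame.rename(columns=lambda c: c.lstrip("!").strip())
        types = []
        for _, row in frame.iterrows():
            types.append(
                ReactionType(
                    str(row["Type"]).strip(),
                    str(row["Class"]).strip(),
                    "" if pd.isna(row.get("SourcePattern")) else str(row["SourcePattern"]).strip(),
                    "" if pd.isna(row.get("ProductPattern")) else str(row["ProductPattern"]).strip(),
                )
            )
        return cls(types)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.name, t.cls, t.source, t.product) for t in self.types.values()],
            columns=["Type", "Class", "SourcePattern", "ProductPattern"],
        )


@dataclass(frozen=True)
class ElementalReaction:
    """A typed event over one or two subjects, with derived effect sets.

    ``consumed``/``produced`` are the *local* effects (the states rewritten
    by this event).  Synthesis reactions additionally produce every neutral
    state of their product component, and degradation removes the component;
    both are context-dependent (they need the component's locus inventory)
    and are derived at compile time.
    """

    subject_a: Tuple[str, Optional[Locus]]
    rtype: ReactionType
    subject_b: Tuple[str, Optional[Locus]]
    consumed: FrozenSet[ElementalState] = field(default_factory=frozenset)
    produced: FrozenSet[ElementalState] = field(default_factory=frozenset)

    @property
    def text(self) -> str:
        a, locus_a = self.subject_a
        b, locus_b = self.subject_b
        return (
            f"{a}{locus_a.render() if locus_a else ''}"
            f"_{self.rtype.name}_"
            f"{b}{locus_b.render() if locus_b else ''}"
        )

    key = text

    @property
    def synthesises(self) -> Optional[str]:
        """Component produced by a synthesis reaction, else None."""
        mech = self.rtype.mechanism
        if mech == "synthesis-mrna":
            return self.subject_b[0] + MRNA_SUFFIX
        if mech == "synthesis-protein":
            return self.subject_b[0]
        return None

    @property
    def degrades(self) -> Optional[str]:
        if self.rtype.mechanism == "degradation":
            return self.subject_b[0]
        return None

    @property
    def required_components(self) -> Tuple[str, ...]:
        """Components whose presence the reaction needs (synthesis products
        excluded; translation needs the template mRNA)."""
        mech = self.rtype.mechanism
        a, b = self.subject_a[0], self.subject_b[0]
        if mech == "synthesis-mrna":
            out = (a,)
        elif mech == "synthesis-protein":
            out = (a, b + MRNA_SUFFIX)
        else:
            out = (a, b)
        return tuple(dict.fromkeys(out))

    @property
    def components(self) -> Tuple[str, ...]:
        """All components touched, including synthesis products."""
        out = list(self.required_components)
        if self.synthesises:
            out.append(self.synthesises)
        return tuple(dict.fromkeys(out))

    def __str__(self) -> str:  # pragma: no cover
        return self.text


def _split_subjects(text: str, registry: Registry):
    parts = text.strip().split("_")
    if len(parts) < 3:
        raise ParseError("reaction string needs A_type_B", text=text)

    def take_subject(parts, start):
        name = parts[start]
        if not name or name.startswith("["):
            raise ParseError("missing component name", text, name)
        i = start + 1
        spec = name
        if i < len(parts) and parts[i].startswith("["):
            spec = f"{name}_{parts[i]}"
            i += 1
        return parse_component_spec(spec), i

    subject_a, i = take_subject(parts, 0)
    if i >= len(parts):
        raise ParseError("missing reaction type", text=text)
    type_token = parts[i]
    if type_token not in registry.types:
        raise ParseError(f"unknown reaction type {type_token!r}", text, type_token)
    rtype = registry.types[type_token]
    i += 1
    if i >= len(parts):
        raise ParseError("missing second subject", text=text)
    subject_b, i = take_subject(parts, i)
    if i != len(parts):
        raise ParseError("trailing tokens after second subject", text, parts[i])
    return subject_a, rtype, subject_b


def parse_reaction(text: str, registry: Optional[Registry] = None) -> ElementalReaction:
    """Parse a reaction string and derive its local effect sets."""
    registry = registry or Registry.default()
    (subject_a, rtype, subject_b) = _split_subjects(text, registry)
    comp_a, locus_a = subject_a
    comp_b, locus_b = subject_b
    mech = rtype.mechanism

    consumed: set = set()
    produced: set = set()
    if mech == "modification":
        if locus_b is None or locus_b.kind != "residue":
            raise ParseError(
                f"{rtype.name} requires subjectB at residue resolution", text,
                f"{comp_b}{locus_b.render() if locus_b else ''}",
            )
        consumed.add(ModificationState(comp_b, locus_b, rtype.source))
        produced.add(ModificationState(comp_b, locus_b, rtype.product))
    elif mech in ("bond", "bond-break"):
        for comp, locus in ((comp_a, locus_a), (comp_b, locus_b)):
            if locus is None or locus.kind != "domain":
                raise ParseError(
                    f"{rtype.name} requires both subjects at domain resolution",
                    text,
                    f"{comp}{locus.render() if locus else ''}",
                )
        frees = {FreeDomainState(comp_a, locus_a), FreeDomainState(comp_b, locus_b)}
        bond = BondState((comp_a, locus_a), (comp_b, locus_b))
        if mech == "bond":
            consumed.update(frees)
            produced.add(bond)
        else:
            consumed.add(bond)
            produced.update(frees)
    elif mech in ("synthesis-mrna", "synthesis-protein", "degradation"):
        if locus_b is not None:
            raise ParseError(
                f"{rtype.name} targets a whole component, not a locus", text,
                f"{comp_b}{locus_b.render()}",
            )
    if consumed & produced:
        raise ParseError("reaction consumes and produces the same state", text=text)
    return ElementalReaction(
        (comp_a, locus_a), rtype, (comp_b, locus_b),
        frozenset(consumed), frozenset(produced),
    )
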