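"""Site-specific elemental states and their surface syntax.

An *elemental state* is a fact about a single site: a modification at a
residue (``NLRP3_[(S5)]-{P}``), a bond between two domains
(``NEK7_[clobe]--NLRP3_[HD2LRR]``), a free (unbound) domain
(``NEK7_[clobe]--0``), or a nucleotide occupancy (``NLRP3_[(NBD)]-{ATP}``).
It says nothing about any other site of the component.  Bracketed names
(``[LPS]``) reference the system boundary (inputs/outputs) and angle-bracket
names (``<Signal1>``) reference Boolean gates defined in the contingency
list.

The surface syntax round-trips: ``parse_state(s).render()`` is the canonical
form of ``s`` (bond endpoints are sorted, so bond equality is
order-insensitive).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

__all__ = [
    "ParseError",
    "Locus",
    "ModificationState",
    "BondState",
    "FreeDomainState",
    "InputRef",
    "GateRef",
    "ElementalState",
    "StateLike",
    "NEUTRAL_MODIFIER",
    "parse_state",
    "parse_component_spec",
]

NEUTRAL_MODIFIER = "0"


class ParseError(ValueError):
    """A state or reaction string could not be parsed.

    Carries the offending text and, where known, the sub-span that failed.
    """

    def __init__(self, message: str, text: str = "", span: str = ""):
        self.text = text
        self.span = span
        detail = message
        if span:
            detail += f" (offending span: {span!r})"
        if text and text != span:
            detail += f" in {text!r}"
        super().__init__(detail)


@dataclass(frozen=True, order=True)
class Locus:
    """A named site on a component: an interaction domain or a residue.

    Residues render with nested brackets (``_[(S5)]``), domains with plain
    brackets (``_[clobe]``).
    """

    kind: str  # "domain" | "residue"
    name: str

    def __post_init__(self) -> None:
        if self.kind not in ("domain", "residue"):
            raise ValueError(f"invalid locus kind {self.kind!r}")
        if not self.name or re.search(r"[\[\]()\s]", self.name):
            raise ValueError(f"invalid locus name {self.name!r}")

    def render(self) -> str:
        if self.kind == "residue":
            return f"_[({self.name})]"
        return f"_[{self.name}]"


# Component name: no underscore (the reaction-string field separator), no
# brackets, no whitespace.
_COMPONENT = r"[A-Za-z0-9][A-Za-z0-9.\-]*"
_SPEC_RE = re.compile(
    rf"^({_COMPONENT})"
    r"(?:_\[\(([^\[\]()\s]+)\)\]|_\[([^\[\]()\s]+)\])?$"
)


def parse_component_spec(text: str) -> Tuple[str, Optional[Locus]]:
    """Parse ``Component``, ``Component_[domain]`` or ``Component_[(res)]``."""
    m = _SPEC_RE.match(text)
    if m is None:
        raise ParseError("malformed component/locus specification", span=text)
    name, residue, domain = m.groups()
    if residue is not None:
        return name, Locus("residue", residue)
    if domain is not None:
        return name, Locus("domain", domain)
    return name, None


class ElementalState:
    """Base class for concrete elemental states (marker/interface)."""

    @property
    def components(self) -> Tuple[str, ...]:
        raise NotImplementedError

    @property
    def is_neutral(self) -> bool:
        raise NotImplementedError

    def render(self) -> str:
        raise NotImplementedError

    def neutral_partners(self) -> Tuple["ElementalState", ...]:
        """The neutral state(s) mutually exclusive with this one per molecule."""
        raise NotImplementedError

    @property
    def key(self) -> str:
        return self.render()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class ModificationState(ElementalState):
    """A modification (or nucleotide occupancy) at a single residue.

    ``modifier == "0"`` marks the neutral, unmodified residue.
    """

    component: str
    residue: Locus
    modifier: str

    def __post_init__(self) -> None:
        if self.residue.kind != "residue":
            raise ValueError("modification states live on residue loci")

    @property
    def components(self) -> Tuple[str, ...]:
        return (self.component,)

    @property
    def is_neutral(self) -> bool:
        return self.modifier == NEUTRAL_MODIFIER

    def render(self) -> str:
        return f"{self.component}{self.residue.render()}-{{{self.modifier}}}"

    def neutral_partners(self) -> Tuple[ElementalState, ...]:
        if self.is_neutral:
            return ()
        return (ModificationState(self.component, self.residue, NEUTRAL_MODIFIER),)


def _endpoint_key(endpoint: Tuple[str, Locus]) -> str:
    component, locus = endpoint
    return f"{component}{locus.render()}"


@dataclass(frozen=True)
class BondState(ElementalState):
    """A bond between two domains.  Equality is order-insensitive: the
    endpoint pair is stored in canonical (lexicographic) order."""

    endpoint_a: Tuple[str, Locus]
    endpoint_b: Tuple[str, Locus]

    def __post_init__(self) -> None:
        for endpoint in (self.endpoint_a, self.endpoint_b):
            if endpoint[1].kind != "domain":
                raise ValueError("bond endpoints must be domain loci")
        if _endpoint_key(self.endpoint_a) > _endpoint_key(self.endpoint_b):
            a, b = self.endpoint_a, self.endpoint_b
            object.__setattr__(self, "endpoint_a", b)
            object.__setattr__(self, "endpoint_b", a)

    @property
    def components(self) -> Tuple[str, ...]:
        a, b = self.endpoint_a[0], self.endpoint_b[0]
        return (a,) if a == b else (a, b)

    @property
    def is_neutral(self) -> bool:
        return False

    def render(self) -> str:
        return f"{_endpoint_key(self.endpoint_a)}--{_endpoint_key(self.endpoint_b)}"

    def neutral_partners(self) -> Tuple[ElementalState, ...]:
        frees = {
            FreeDomainState(component, locus)
            for component, locus in (self.endpoint_a, self.endpoint_b)
        }
        return tuple(sorted(frees, key=lambda s: s.key))


@dataclass(frozen=True)
class FreeDomainState(ElementalState):
    """The neutral (unbound) partner of every bond sharing this endpoint."""

    component: str
    domain: Locus

    def __post_init__(self) -> None:
        if self.domain.kind != "domain":
            raise ValueError("free-domain states live on domain loci")

    @property
    def components(self) -> Tuple[str, ...]:
        return (self.component,)

    @property
    def is_neutral(self) -> bool:
        return True

    def render(self) -> str:
        return f"{self.component}{self.domain.render()}--0"

    def neutral_partners(self) -> Tuple[ElementalState, ...]:
        return ()


@dataclass(frozen=True)
class InputRef:
    """A bracketed boundary name (system input or output), e.g. ``[LPS]``."""

    name: str

    def render(self) -> str:
        return f"[{self.name}]"

    @property
    def key(self) -> str:
        return self.render()

    def __str__(self) -> str:  # pragma: no cover
        return self.render()


@dataclass(frozen=True)
class GateRef:
    """An angle-bracketed reference to a named Boolean gate, e.g. ``<Signal1>``."""

    name: str

    def render(self) -> str:
        return f"<{self.name}>"

    @property
    def key(self) -> str:
        return self.render()

    def __str__(self) -> str:  # pragma: no cover
        return self.render()


StateLike = Union[ElementalState, InputRef, GateRef]

_BRACKET_RE = re.compile(r"^\[([^\[\]\s]+)\]$")
_GATE_RE = re.compile(r"^<([^<>\s]+)>$")
_MOD_RE = re.compile(r"^(.*)-\{([^{}\s]*)\}$")


def parse_state(text: str, modifiers: Optional[set] = None) -> StateLike:
    """Parse an elemental-state, input or gate reference string.

    Parameters
    ----------
    text:
        The surface form (whitespace is trimmed).
    modifiers:
        Known modifier tokens; if given, an unknown ``-{...}`` token is a
        :class:`ParseError`.  The neutral token ``"0"`` is always accepted.
    """
    original = text
    text = text.strip()
    if not text:
        raise ParseError("empty state string", text=original)
    m = _BRACKET_RE.match(text)
    if m:
        return InputRef(m.group(1))
    m = _GATE_RE.match(text)
    if m:
        return GateRef(m.group(1))
    if "--" in text:
        left, sep, right = text.partition("--")
        if right == NEUTRAL_MODIFIER:
            component, locus = parse_component_spec(left)
            if locus is None or locus.kind != "domain":
                raise ParseError(
                    "free-domain state requires a domain locus", text, left
                )
            return FreeDomainState(component, locus)
        comp_a, locus_a = parse_component_spec(left)
        comp_b, locus_b = parse_component_spec(right)
        if locus_a is None or locus_a.kind != "domain":
            raise ParseError("bond endpoint requires a domain locus", text, left)
        if locus_b is None or locus_b.kind != "domain":
            raise ParseError("bond endpoint requires a domain locus", text, right)
        return BondState((comp_a, locus_a), (comp_b, locus_b))
    m = _MOD_RE.match(text)
    if m:
        spec, modifier = m.groups()
        component, locus = parse_component_spec(spec)
        if locus is None or locus.kind != "residue":
            raise ParseError(
                "modification state requires a residue locus", text, spec
            )
        if not modifier:
            raise ParseError("empty modifier token", text, f"-{{{modifier}}}")
        if (
            modifiers is not None
            and modifier != NEUTRAL_MODIFIER
            and modifier not in modifiers
        ):
            raise ParseError(f"unknown modifier token {modifier!r}", text, modifier)
        return ModificationState(component, locus, modifier)
    raise ParseError("unrecognised state syntax", text=original, span=text)
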