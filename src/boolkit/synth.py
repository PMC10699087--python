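"""Random reaction-contingency networks and a reference interpreter.

The generator emits small knowledge bases with the structural motifs the
analysis relies on — kinase/phosphatase cycles, bond formation (with and
without reverse reactions), ubiquitylation/deubiquitylation, proteolytic
cleavage, nucleotide cycles, and input-gated synthesis/degradation — plus
strict contingencies and (nested) Boolean gates.  Generation is a pure
function of the configuration, so the same seed always yields a
structurally identical network.

The reference interpreter executes the bipartite-Boolean-model semantics
*directly from the knowledge base*, re-deriving producers, consumers and
contingency expressions at every step without building rule expressions.
It is intentionally naive and serves as the independent oracle for the
compiler and simulator: compiled-model and interpreter trajectories must
agree bitwise on every node at every step.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .kb import Contingency, GateDef, KnowledgeBase, validate_knowledge_base
from .reactions import ElementalReaction, Registry, parse_reaction
from .states import ElementalState, GateRef, InputRef, StateLike, parse_state
from .sim import Assignment, Trajectory

__all__ = ["SynthConfig", "random_network", "reference_interpret"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; all probabilities in [0, 1], counts >= 1."""

    n_components: int = 4
    n_reactions: int = 6
    p_contingency: float = 0.6
    p_gate: float = 0.3
    max_gate_depth: int = 2
    p_synthesis: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1 or self.n_reactions < 1:
            raise ValueError("counts must be >= 1")
        for p in (self.p_contingency, self.p_gate, self.p_synthesis):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


def random_network(config: SynthConfig) -> KnowledgeBase:
    """Generate a validator-clean knowledge base from the configuration."""
    rng = random.Random(config.seed)
    registry = Registry.default()
    components = [f"C{i + 1}" for i in range(config.n_components)]
    fresh = iter(range(1, 10_000))

    texts: List[str] = []

    def motif_phospho():
        sub, kin, ph = (rng.choice(components) for _ in range(3))
        k = next(fresh)
        return [f"{kin}_P+_{sub}_[(r{k})]", f"{ph}_P-_{sub}_[(r{k})]"]

    def motif_bond():
        a, b = rng.sample(components, 2) if len(components) > 1 else (components[0],) * 2
        k = next(fresh)
        out = [f"{a}_[d{k}a]_ppi+_{b}_[d{k}b]"]
        if rng.random() < 0.4:
            out.append(f"{a}_[d{k}a]_ppi-_{b}_[d{k}b]")
        return out

    def motif_ub():
        sub, e3, dub = (rng.choice(components) for _ in range(3))
        k = next(fresh)
        return [f"{e3}_ub63+_{sub}_[(u{k})]", f"{dub}_ub63-_{sub}_[(u{k})]"]

    def motif_cut():
        a, b = (rng.choice(components) for _ in range(2))
        return [f"{a}_cut_{b}_[(pro{next(fresh)})]"]

    def motif_atpase():
        c = rng.choice(components)
        k = next(fresh)
        return [f"{c}_aBind_{c}_[(n{k})]", f"{c}_aHy_{c}_[(n{k})]",
                f"{c}_aEx_{c}_[(n{k})]"]

    def motif_turnover():
        target = rng.choice(components)
        cat = rng.choice(components)
        return [f"{cat}_trsc_{target}", f"{cat}_trsl_{target}",
                f"{cat}_deg_{target}", f"{cat}_deg_{target}mRNA"]

    motifs = [motif_phospho, motif_bond, motif_ub, motif_cut, motif_atpase]
    for component in components:
        if rng.random() < config.p_synthesis and len(texts) < config.n_reactions:
            texts.extend(motif_turnover())
    while len(texts) < config.n_reactions:
        texts.extend(rng.choice(motifs)())
    # Trim to the requested count.  Motifs put forward reactions before their
    # reverses, so a prefix never keeps a reverse without its producer.
    texts = list(dict.fromkeys(texts))[: config.n_reactions]

    reactions = [parse_reaction(t, registry) for t in texts]
    producible = sorted(
        {s.key for r in reactions for s in r.produced},
    )
    input_pool = [InputRef("in1"), InputRef("in2")]

    gates: Dict[str, GateDef] = {}

    def pick_atom() -> StateLike:
        if producible and rng.random() < 0.75:
            return parse_state(rng.choice(producible), registry.modifiers)
        return rng.choice(input_pool)

    def make_gate(depth: int) -> GateRef:
        name = f"g{len(gates) + 1}"
        op = rng.choice(["AND", "OR", "NOT"])
        if op == "NOT":
            members: List[StateLike] = [pick_member(depth + 1)]
        else:
            members = [pick_member(depth + 1) for _ in range(rng.randint(2, 3))]
        gates[name] = GateDef(name, op, members)
        return GateRef(name)

    def pick_member(depth: int) -> StateLike:
        if depth < config.max_gate_depth and rng.random() < 0.3:
            return make_gate(depth)
        return pick_atom()

    contingencies: List[Contingency] = []
    uid = 0
    for r in reactions:
        if rng.random() >= config.p_contingency:
            continue
        uid += 1
        kind = rng.choice(["!", "!", "x", "0"])
        if rng.random() < config.p_gate:
            modifier: StateLike = make_gate(1)
        else:
            modifier = pick_atom()
        contingencies.append(Contingency(uid, r, kind, modifier))

    # Guarantee at least one input and one output.
    uid += 1
    anchor = (parse_state(rng.choice(producible), registry.modifiers)
              if producible else input_pool[0])
    gates["gout"] = GateDef("gout", "OR", [input_pool[0], anchor])
    contingencies.append(Contingency(uid, InputRef("out1"), "!", GateRef("gout")))

    # Gate-definition rows mirror the gate table (dialect round-trip).
    for gate in gates.values():
        for member in gate.members:
            uid += 1
            contingencies.append(
                Contingency(uid, GateRef(gate.name), gate.op, member)
            )

    kb = KnowledgeBase(reactions, contingencies, gates, registry)
    report = validate_knowledge_base(kb)
    if not report.ok:  # pragma: no cover - generator guarantee
        raise AssertionError(f"generated KB failed validation:\n{report}")
    return kb


# ---------------------------------------------------------------------------
# Reference interpreter


def _gate_value(kb: KnowledgeBase, modifier: StateLike, a: Mapping[str, bool]) -> bool:
    if isinstance(modifier, GateRef):
        gate = kb.gates[modifier.name]
        values = [_gate_value(kb, m, a) for m in gate.members]
        if gate.op == "NOT":
            return not values[0]
        if gate.op == "AND":
            return all(values)
        return any(values)
    if isinstance(modifier, InputRef):
        return a[modifier.render()]
    return a[modifier.key]


def _reaction_active(kb: KnowledgeBase, r: ElementalReaction,
                     a: Mapping[str, bool]) -> bool:
    if not all(a[c] for c in r.required_components):
        return False
    if not all(a[s.key] for s in r.consumed):
        return False
    for c in kb.contingencies_for(r.text):
        if c.kind == "!" and not _gate_value(kb, c.modifier, a):
            return False
        if c.kind == "x" and _gate_value(kb, c.modifier, a):
            return False
    return True


def reference_interpret(
    kb: KnowledgeBase,
    initial: Assignment,
    clamps: Optional[Mapping[str, bool]] = None,
    n_steps: int = 50,
) -> Trajectory:
    """Simulate ``n_steps`` synchronous updates straight from the KB.

    Every step re-derives, from scratch: each reaction's activity (required
    components, source states, contingencies); each state's producers
    (including synthesis for neutral states) and consumers (including
    degradation of required-modifier states); component synthesis and
    degradation; output expressions.  Neutral states of synthesis-less
    components are treated as inexhaustible pools.
    """
    clamps = dict(clamps or {})

    # Independent node bookkeeping (no use of the compiler).
    states: Dict[str, ElementalState] = {}

    def register(state: ElementalState) -> None:
        states.setdefault(state.key, state)
        for partner in state.neutral_partners():
            states.setdefault(partner.key, partner)

    for r in kb.reactions:
        for s in r.consumed | r.produced:
            register(s)
        if r.synthesises:
            for s in kb.neutral_states_of(r.synthesises):
                register(s)
    for s in kb.iter_modifier_states():
        register(s)

    components = kb.components
    synthesis: Dict[str, List[ElementalReaction]] = {}
    degradation: Dict[str, List[ElementalReaction]] = {}
    for r in kb.reactions:
        if r.synthesises:
            synthesis.setdefault(r.synthesises, []).append(r)
        if r.degrades:
            degradation.setdefault(r.degrades, []).append(r)

    def producers_of(key: str) -> List[ElementalReaction]:
        state = states[key]
        out = [r for r in kb.reactions if any(s.key == key for s in r.produced)]
        if state.is_neutral:
            for comp in state.components:
                out.extend(synthesis.get(comp, []))
        return out

    def consumers_of(key: str) -> List[ElementalReaction]:
        state = states[key]
        out = [r for r in kb.reactions if any(s.key == key for s in r.consumed)]
        for comp in state.components:
            for r in degradation.get(comp, []):
                for c in kb.contingencies_for(r.text):
                    if (c.kind == "!" and isinstance(c.modifier, ElementalState)
                            and c.modifier.key == key):
                        out.append(r)
        return out

    current = dict(initial)
    current.update(clamps)
    steps = [current]
    for _ in range(n_steps):
        prev = steps[-1]
        active_next = {r.text: _reaction_active(kb, r, prev) for r in kb.reactions}
        nxt: Assignment = {}
        for r in kb.reactions:
            nxt[r.text] = active_next[r.text]
        for key, state in states.items():
            present = all(prev[c] for c in state.components if c in components)
            if not present:
                nxt[key] = False
                continue
            if state.is_neutral and all(
                not synthesis.get(c) for c in state.components
            ):
                nxt[key] = True  # constitutive pool, never exhausted
                continue
            produced = any(active_next[r.text] for r in producers_of(key))
            consumed = any(prev[r.text] for r in consumers_of(key))
            nxt[key] = produced or (prev[key] and not consumed)
        for comp in components:
            if not synthesis.get(comp):
                nxt[comp] = True
            else:
                made = any(prev[r.text] for r in synthesis[comp])
                lost = any(prev[r.text] for r in degradation.get(comp, []))
                nxt[comp] = made or (prev[comp] and not lost)
        for i in kb.inputs:
            nxt[i.render()] = prev[i.render()]
        for o in kb.outputs:
            rows = [c for c in kb.contingencies_for(o.render())
                    if c.kind in ("!", "x")]
            if not rows:
                nxt[o.render()] = False
            else:
                nxt[o.render()] = all(
                    _gate_value(kb, c.modifier, prev) == (c.kind == "!")
                    for c in rows
                )
        nxt.update(clamps)
        steps.append(nxt)
    return Trajectory(steps, clamps)
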