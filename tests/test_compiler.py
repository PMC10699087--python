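"""Compilation to the bipartite Boolean model."""

import itertools

import pandas as pd
import pytest

from boolkit.compiler import (
    And,
    Const,
    Lit,
    Not,
    Or,
    build_update_rules,
    enumerate_nodes,
    inline_gates,
)
from boolkit.kb import load_knowledge_base
from boolkit.reactions import Registry
from boolkit.states import GateRef
from boolkit.synth import SynthConfig, random_network


REGISTRY = Registry.default()


def minimal_kb(reactions, contingencies=()):
    rframe = pd.DataFrame({"Reaction": reactions})
    cframe = pd.DataFrame(
        list(contingencies) or None,
        columns=["UID", "Target", "Contingency", "Modifier"],
    )
    return load_knowledge_base(rframe, cframe, REGISTRY)


def test_minimal_kb_node_set():
    kb = minimal_kb(["AKT_P+_NLRP3_[(S5)]"])
    nodes = enumerate_nodes(kb)
    by_kind = {}
    for n in nodes:
        by_kind.setdefault(n.kind, set()).add(n.key)
    assert by_kind["reaction"] == {"AKT_P+_NLRP3_[(S5)]"}
    assert by_kind["state"] == {"NLRP3_[(S5)]-{P}", "NLRP3_[(S5)]-{0}"}
    assert by_kind["component"] == {"AKT", "NLRP3"}
    assert "input" not in by_kind and "output" not in by_kind


def test_fixture_node_set_contains_boundary(nlrp3_model):
    keys = set(nlrp3_model.node_keys)
    assert "[IL1Brelease]" in keys
    assert "[extK]" in keys
    assert nlrp3_model.kinds["[IL1Brelease]"] == "output"
    assert nlrp3_model.kinds["[extK]"] == "input"


@pytest.mark.parametrize("seed", [0, 5, 11, 42])
def test_node_count_identity_on_random_kb(seed):
    kb = random_network(SynthConfig(seed=seed))
    nodes = enumerate_nodes(kb)
    states = {s.key for r in kb.reactions
              for s in (r.consumed | r.produced)}
    for r in kb.reactions:
        if r.synthesises:
            states |= {s.key for s in kb.neutral_states_of(r.synthesises)}
    for s in kb.iter_modifier_states():
        states.add(s.key)
        states |= {p.key for p in s.neutral_partners()}
    expected = (len(kb.reactions) + len(states) + len(kb.components)
                + len(kb.inputs) + len(kb.outputs))
    assert len(nodes) == expected


def test_gate_inlining_fixture_examples(nlrp3_kb):
    inhib = inline_gates(nlrp3_kb, GateRef("AKTinhib"))
    assert inhib == Or([Lit("[MK2206]"), Lit("[AKTK179M]")])
    active = inline_gates(nlrp3_kb, GateRef("AKTactive"))
    assert active == And([
        Lit("AKT_[PH]--PI_[head]"),
        Or([Lit("[SC79]"),
            And([Lit("AKT_[(T308)]-{P}"), Lit("AKT_[(S473)]-{P}")])]),
    ])


def test_gate_inlining_is_semantics_preserving(nlrp3_kb):
    """Evaluating the gated and the inlined forms agrees on every member
    assignment (exhaustive over the gate's literals)."""
    for name, gate in nlrp3_kb.gates.items():
        expr = inline_gates(nlrp3_kb, GateRef(name))
        literals = sorted(expr.literals())
        assert len(literals) <= 10

        def reference(assignment, modifier):
            from boolkit.states import GateRef as G, InputRef as I
            if isinstance(modifier, G):
                inner = nlrp3_kb.gates[modifier.name]
                vals = [reference(assignment, m) for m in inner.members]
                return (not vals[0] if inner.op == "NOT"
                        else all(vals) if inner.op == "AND" else any(vals))
            key = modifier.render() if isinstance(modifier, I) else modifier.key
            return assignment[key]

        for bits in itertools.product([False, True], repeat=len(literals)):
            assignment = dict(zip(literals, bits))
            assert expr.evaluate(assignment) == reference(assignment, GateRef(name))


def test_unconstrained_reaction_rule_is_presences_and_sources():
    kb = minimal_kb(["AKT_P+_NLRP3_[(S5)]"])
    model = build_update_rules(kb)
    rule = model.rules["AKT_P+_NLRP3_[(S5)]"]
    assert rule == And([Lit("AKT"), Lit("NLRP3"), Lit("NLRP3_[(S5)]-{0}")])


def test_fixture_reaction_rule_includes_priming_gate(nlrp3_model):
    rule = nlrp3_model.rules["JNK1_P+_NLRP3_[(S198)]"]
    literals = rule.literals()
    assert {"JNK1", "NLRP3", "NLRP3_[(S198)]-{0}"} <= literals
    # the inlined Signal-1 gate: any of the five priming stimuli
    assert {"[LPS]", "[Pam3csk4]", "[IL1]", "[TNF]", "[ABagg]"} <= literals


def test_fixture_neutral_state_produced_by_translation(nlrp3_model):
    rule = nlrp3_model.rules["NLRP3_[(S5)]-{0}"]
    assert "Ribo_trsl_NLRP3" in rule.literals()


def test_component_rules(nlrp3_model):
    # synthesised component: produced by translation, removed by degradation
    nlrp3 = nlrp3_model.rules["NLRP3"]
    assert "Ribo_trsl_NLRP3" in nlrp3.literals()
    assert "Proteasome_deg_NLRP3" in nlrp3.literals()
    # component without synthesis is constitutive
    assert nlrp3_model.rules["NEK7"] == Const(True)


def test_bipartiteness(nlrp3_model):
    """Reaction rules never reference reaction nodes; state rules reference
    only reactions, components and themselves."""
    kinds = nlrp3_model.kinds
    for key, rule in nlrp3_model.rules.items():
        referenced = {kinds[k] for k in rule.literals()}
        if kinds[key] == "reaction":
            assert "reaction" not in referenced
        elif kinds[key] == "state":
            for lit in rule.literals():
                assert kinds[lit] in ("reaction", "component") or lit == key


def test_output_rule_conjoins_required_rows(nlrp3_model):
    rule = nlrp3_model.rules["[IL1Brelease]"]
    assert rule == And([Lit("[gDpmPoreFormation]"), Lit("IL1b_[(pro)]-{truncated}")])


def test_input_rule_is_identity(nlrp3_model):
    assert nlrp3_model.rules["[LPS]"] == Lit("[LPS]")
    assert "[LPS]" in nlrp3_model.clampable
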