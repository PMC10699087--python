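"""Knowledge-base loading, writing and validation."""

import pandas as pd
import pytest

from boolkit.kb import (
    Contingency,
    GateDef,
    KnowledgeBase,
    KnowledgeBaseError,
    load_knowledge_base,
    load_knowledge_base_dir,
    validate_knowledge_base,
    write_knowledge_base,
)
from boolkit.reactions import Registry, parse_reaction
from boolkit.states import GateRef, InputRef, parse_state
from boolkit.synth import SynthConfig, random_network


REGISTRY = Registry.default()


def frames(reactions, contingencies):
    rframe = pd.DataFrame(
        [(i + 1, t, "") for i, t in enumerate(reactions)],
        columns=["!UID", "!Reaction", "!Reference"],
    )
    cframe = pd.DataFrame(
        contingencies, columns=["!UID", "!Target", "!Contingency", "!Modifier"]
    )
    return rframe, cframe


def test_load_strips_bang_headers_and_parses_rows():
    rframe, cframe = frames(
        ["AKT_P+_NLRP3_[(S5)]"],
        [(1, "AKT_P+_NLRP3_[(S5)]", "x", "[OKA]")],
    )
    kb = load_knowledge_base(rframe, cframe, REGISTRY)
    assert len(kb.reactions) == 1
    assert len(kb.contingencies) == 1
    assert kb.contingencies[0].kind == "x"
    assert [i.name for i in kb.inputs] == ["OKA"]


def test_empty_contingency_table_gives_unconstrained_reaction():
    rframe, cframe = frames(["AKT_P+_NLRP3_[(S5)]"], [])
    kb = load_knowledge_base(rframe, cframe, REGISTRY)
    assert len(kb.reactions) == 1
    assert kb.contingencies == []
    assert validate_knowledge_base(kb).ok


def test_duplicate_uid_rejected():
    rframe, cframe = frames(
        ["AKT_P+_NLRP3_[(S5)]"],
        [(1, "AKT_P+_NLRP3_[(S5)]", "x", "[OKA]"),
         (1, "AKT_P+_NLRP3_[(S5)]", "!", "[LPS]")],
    )
    with pytest.raises(KnowledgeBaseError, match="duplicate"):
        load_knowledge_base(rframe, cframe, REGISTRY)


def test_gate_kind_requires_gate_target():
    rframe, cframe = frames(
        ["AKT_P+_NLRP3_[(S5)]"],
        [(1, "AKT_P+_NLRP3_[(S5)]", "AND", "[OKA]")],
    )
    with pytest.raises(KnowledgeBaseError, match="gate target"):
        load_knowledge_base(rframe, cframe, REGISTRY)


def test_gate_cycle_rejected_at_load():
    rframe, cframe = frames(
        ["AKT_P+_NLRP3_[(S5)]"],
        [(1, "<A>", "OR", "<B>"), (2, "<A>", "OR", "[x1]"),
         (3, "<B>", "OR", "<A>"), (4, "<B>", "OR", "[x2]")],
    )
    with pytest.raises(KnowledgeBaseError, match="cycle"):
        load_knowledge_base(rframe, cframe, REGISTRY)


def test_validator_flags_dangling_target():
    r = parse_reaction("AKT_P+_NLRP3_[(S5)]", REGISTRY)
    ghost = parse_reaction("PKA_P+_NLRP3_[(S295)]", REGISTRY)
    kb = KnowledgeBase(
        [r],
        [Contingency(1, ghost, "!", parse_state("[LPS]"))],
        {}, REGISTRY,
    )
    report = validate_knowledge_base(kb)
    assert not report.ok
    assert [i.code for i in report.errors] == ["dangling-target"]


def test_validator_flags_gate_cycle():
    r = parse_reaction("AKT_P+_NLRP3_[(S5)]", REGISTRY)
    gates = {
        "A": GateDef("A", "OR", [GateRef("B"), parse_state("[x1]")]),
        "B": GateDef("B", "OR", [GateRef("A"), parse_state("[x2]")]),
    }
    kb = KnowledgeBase([r], [Contingency(1, r, "!", GateRef("A"))], gates, REGISTRY)
    report = validate_knowledge_base(kb)
    assert "gate-cycle" in [i.code for i in report.errors]


def test_validator_warns_on_unproducible_modifier_state():
    r = parse_reaction("AKT_P+_NLRP3_[(S5)]", REGISTRY)
    kb = KnowledgeBase(
        [r],
        [Contingency(1, r, "!", parse_state("NLRP3_[(S198)]-{P}", REGISTRY.modifiers))],
        {}, REGISTRY,
    )
    report = validate_knowledge_base(kb)
    assert report.ok  # warning, not error
    assert "unproducible-state" in [i.code for i in report.warnings]


@pytest.mark.parametrize("seed", [1, 7, 23])
def test_random_kb_round_trips_through_tsv(tmp_path, seed):
    kb = random_network(SynthConfig(seed=seed))
    write_knowledge_base(kb, tmp_path)
    again = load_knowledge_base_dir(tmp_path)

    def shape(k):
        return (
            [r.text for r in k.reactions],
            [(c.uid, c.target_key, c.kind, c.modifier.render())
             for c in k.contingencies],
            {name: (g.op, [m.render() for m in g.members])
             for name, g in k.gates.items()},
        )

    assert shape(kb) == shape(again)


def test_fixture_validates_clean(nlrp3_kb):
    report = validate_knowledge_base(nlrp3_kb)
    assert report.ok
    assert report.warnings == []


def test_fixture_consumed_states_all_producible_or_neutral(nlrp3_kb):
    producible = {s.key for r in nlrp3_kb.reactions for s in r.produced}
    for r in nlrp3_kb.reactions:
        for state in r.consumed:
            assert state.is_neutral or state.key in producible, state.key
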