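"""The NLRP3 fixture, scenario catalogue and outcome classification."""

import pytest

from boolkit.compiler import build_update_rules
from boolkit.kb import validate_knowledge_base
from boolkit.nlrp3 import (
    T346M_BYPASSES_CENTROSOME,
    apply_variants,
    classify_outcome,
    load_nlrp3_network,
    run_catalogue,
    scenario_catalogue,
)
from boolkit.sim import Scenario, natural_off_state, run_scenario, simulate_to_attractor


def test_fixture_validates_with_zero_errors(nlrp3_kb):
    assert validate_knowledge_base(nlrp3_kb).ok


def test_signal1_gate_has_five_members(nlrp3_kb):
    gate = nlrp3_kb.gates["Signal1"]
    assert gate.op == "OR"
    assert len(gate.members) == 5
    assert {m.name for m in gate.members} == {"LPS", "Pam3csk4", "IL1", "TNF", "ABagg"}


def test_mini_nlrp3_rows(nlrp3_kb):
    rows = [c for c in nlrp3_kb.contingencies
            if getattr(c.modifier, "name", None) == "miniNLRP3"]
    assert len(rows) == 8
    assert all(c.kind == "x" for c in rows)
    assert sorted(c.uid for c in rows) == list(range(175, 183))
    targets = {c.target_key for c in rows}
    assert "RNF125_ub63+_NLRP3_[(lrr)]" in targets
    assert "NLRP3_[cl]_i_CL_[lrrCL]" in targets


def test_catalogue_contains_required_scenarios():
    names = {s.name for s in scenario_catalogue()}
    assert {"S-none", "S-LPS", "S-Nig", "S-LPS+Nig", "S-Pam+Imq", "S-intLPS",
            "S-dualLPS", "S-MMPT", "S-LPS+MMPT", "S-MCC-A", "S-MCC-B", "S-G5",
            "S-OKA", "S-D305G", "S-T346M-A", "S-T346M-B", "S-mini-Nig",
            "S-mini-MMPT", "S-extK-Nig", "S-extK-Imq"} <= names


def test_truth_table_matches_expectations(catalogue):
    for name, (scenario, _, call) in catalogue.items():
        assert call.activated == scenario.expected_activated, (
            f"{name}: got {call.summary}, expected "
            f"activated={scenario.expected_activated}"
        )


def test_full_activation_call_invariant(catalogue):
    for name, (_, _, call) in catalogue.items():
        assert (call.summary == "FULL_ACTIVATION") == (
            call.speck and call.casp1_active and call.il1b_release
        )


def test_off_state_classifies_as_no_activation(nlrp3_model, nlrp3_off):
    result = run_scenario(nlrp3_model, Scenario("none"), off_state=nlrp3_off)
    call = classify_outcome(result)
    assert call.summary == "NO_ACTIVATION"
    assert not call.oscillating


def test_intlps_gives_pyroptosis_without_speck(catalogue):
    _, _, call = catalogue["S-intLPS"]
    assert call.pyroptosis and not call.speck
    assert call.summary == "PORE_ONLY"


def test_t346m_variant_changes_only_t346m_scenario(nlrp3_kb):
    """Relaxing the centrosome requirement for the constitutively open
    mutant flips the T346M scenario and nothing else."""
    baseline = {sc.name: call.summary
                for sc, _, call in run_catalogue(nlrp3_kb)}
    patched_kb = apply_variants(nlrp3_kb, {T346M_BYPASSES_CENTROSOME})
    scenarios = [s for s in scenario_catalogue() if not s.variant_flags]
    patched = {sc.name: call.summary
               for sc, _, call in run_catalogue(patched_kb, scenarios)}
    changed = {n for n in patched if patched[n] != baseline[n]}
    assert changed == {"S-T346M-A"}
    assert patched["S-T346M-A"] == "FULL_ACTIVATION"


def test_g5_bypass_depends_on_synthesis(nlrp3_kb, nlrp3_model, nlrp3_off):
    """Under G5 the deubiquitylated LRR pool is sustained only while
    priming-driven synthesis runs."""
    _, with_lps = simulate_to_attractor(
        nlrp3_model, nlrp3_off,
        {"[LPS]": True, "[Nigericin]": True, "[G5]": True}, 500)
    assert all(s["NLRP3_[(lrr)]-{0}"] for s in with_lps.states)
    _, without_lps = simulate_to_attractor(
        nlrp3_model, nlrp3_off, {"[Nigericin]": True, "[G5]": True}, 500)
    assert not any(s["NLRP3_[(lrr)]-{0}"] for s in without_lps.states)


def test_monotone_stimulus_property(nlrp3_model, nlrp3_off):
    lps, _ = simulate_to_attractor(nlrp3_model, nlrp3_off, {"[LPS]": True}, 500)
    both, _ = simulate_to_attractor(
        nlrp3_model, nlrp3_off, {"[LPS]": True, "[Nigericin]": True}, 500)
    assert lps.ever_true() <= both.ever_true()


def test_k_efflux_follows_gasdermin_pore(nlrp3_model, nlrp3_off):
    """With a type III trigger, potassium efflux is a consequence of
    gasdermin D insertion, not a trigger."""
    trajectory, _ = simulate_to_attractor(
        nlrp3_model, nlrp3_off,
        {"[Pam3csk4]": True, "[Imiquimod]": True}, 500)
    pore = trajectory.first_true_step("[gDpmPoreFormation]")
    kefflux = trajectory.first_true_step("[Kefflux]")
    assert pore is not None and kefflux is not None
    assert kefflux > pore


def test_neutral_modified_duality(catalogue, nlrp3_model):
    """Wherever a component is present now and was present a step ago, every
    one of its residues carries at least one state (the pool is never
    stateless)."""
    import re

    by_site = {}
    for key in nlrp3_model.node_keys:
        if nlrp3_model.kinds[key] != "state":
            continue
        m = re.match(r"^([A-Za-z0-9]+)_\[\(([^)]+)\)\]-\{", key)
        if m:
            by_site.setdefault((m.group(1), m.group(2)), []).append(key)

    for name in ("S-LPS+Nig", "S-LPS", "S-intLPS"):
        trajectory = catalogue[name][1].trajectory
        for t in range(1, len(trajectory.steps)):
            now, before = trajectory.steps[t], trajectory.steps[t - 1]
            for (comp, _), keys in by_site.items():
                if now[comp] and before[comp]:
                    assert any(now[k] for k in keys), (name, t, comp, keys)


def test_unknown_variant_flag_rejected(nlrp3_kb):
    with pytest.raises(ValueError, match="unknown variant"):
        apply_variants(nlrp3_kb, {"no-such-variant"})
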