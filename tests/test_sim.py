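"""Synchronous simulation: stepping, attractors, off states, export."""

import pandas as pd
import pytest

from boolkit.compiler import BooleanModel, Lit, Not, NodeId, build_update_rules
from boolkit.kb import load_knowledge_base
from boolkit.reactions import Registry
from boolkit.sim import (
    ClampError,
    CyclicOffStateError,
    NonConvergenceError,
    Scenario,
    export_trajectory,
    export_trajectories,
    initial_assignment,
    natural_off_state,
    run_scenario,
    simulate_to_attractor,
    step,
)

REGISTRY = Registry.default()


def oscillator():
    node = NodeId("state", "x")
    return BooleanModel([node], {"x": Not(Lit("x"))}, set())


def constitutive_kb():
    rframe = pd.DataFrame({"Reaction": ["PI4K_P+_PI_[(4)]"]})
    cframe = pd.DataFrame(None, columns=["UID", "Target", "Contingency", "Modifier"])
    return load_knowledge_base(rframe, cframe, REGISTRY)


def test_step_is_deterministic_and_pure(nlrp3_model, nlrp3_off):
    once = step(nlrp3_model, nlrp3_off, {"[LPS]": True})
    again = step(nlrp3_model, nlrp3_off, {"[LPS]": True})
    assert once == again


def test_clamp_on_non_input_rejected(nlrp3_model, nlrp3_off):
    with pytest.raises(ClampError):
        step(nlrp3_model, nlrp3_off, {"NLRP3": True})


def test_lps_clamp_turns_signal1_on_next_step(nlrp3_model, nlrp3_off):
    after = step(nlrp3_model, nlrp3_off, {"[LPS]": True})
    # the off state has the gate off; one step after clamping LPS it is on
    assert not nlrp3_off["[Signal1]"]
    first = step(nlrp3_model, dict(nlrp3_off, **{"[LPS]": True}), {"[LPS]": True})
    assert first["[Signal1]"]


def test_two_node_negation_is_a_two_cycle():
    model = oscillator()
    _, attractor = simulate_to_attractor(model, {"x": False}, {}, 10)
    assert attractor.kind == "cycle"
    assert attractor.period == 2
    with pytest.raises(CyclicOffStateError):
        natural_off_state(model)


def test_non_convergence_carries_trajectory():
    model = oscillator()
    with pytest.raises(NonConvergenceError) as err:
        simulate_to_attractor(model, {"x": False}, {}, 1)
    assert len(err.value.trajectory) >= 1


def test_constitutive_fixed_point():
    kb = constitutive_kb()
    model = build_update_rules(kb)
    off = natural_off_state(model)
    assert off["PI_[(4)]-{P}"]
    assert off["PI4K_P+_PI_[(4)]"]


def test_off_state_is_idempotent(nlrp3_model, nlrp3_off):
    assert step(nlrp3_model, nlrp3_off, {}) == nlrp3_off


def test_off_state_all_outputs_false(nlrp3_model, nlrp3_off):
    for node in nlrp3_model.nodes:
        if node.kind == "output":
            assert not nlrp3_off[node.key], node.key


def test_empty_scenario_result_equals_off_state(nlrp3_model, nlrp3_off):
    result = run_scenario(nlrp3_model, Scenario("none"), off_state=nlrp3_off)
    assert result.attractor.kind == "point"
    assert result.attractor.states[0] == nlrp3_off


def test_clamp_containment(nlrp3_model, nlrp3_off):
    result = run_scenario(nlrp3_model, Scenario("lps", {"LPS"}),
                          off_state=nlrp3_off)
    assert all(s["[LPS]"] for s in result.trajectory.steps)


def test_export_activation_order(nlrp3_model, nlrp3_off, tmp_path):
    result = run_scenario(nlrp3_model, Scenario("lps", {"LPS"}),
                          off_state=nlrp3_off)
    frame = export_trajectory(result.trajectory, tmp_path / "t.csv",
                              model=nlrp3_model)
    rows = list(frame.index)
    # clamped input rows first (true from step 0), the priming gate at step 1
    assert frame.loc["[LPS]"].iloc[0] == 1
    assert frame.loc["[Signal1]"].tolist()[:2] == [0, 1]
    first_true = {k: result.trajectory.first_true_step(k) for k in rows}
    order = [first_true[k] if first_true[k] is not None else len(frame.columns)
             for k in rows]
    assert order == sorted(order)
    on_disk = pd.read_csv(tmp_path / "t.csv", index_col=0)
    assert on_disk.shape == frame.shape


def test_export_degenerate_single_column(nlrp3_model, nlrp3_off):
    from boolkit.sim import Trajectory

    frame = export_trajectory(Trajectory([nlrp3_off]), model=nlrp3_model)
    assert frame.shape[1] == 1


def test_export_concatenates_with_separator(nlrp3_model, nlrp3_off):
    result = run_scenario(nlrp3_model, Scenario("lps", {"LPS"}),
                          off_state=nlrp3_off)
    frame = export_trajectories([result.trajectory, result.trajectory],
                                model=nlrp3_model)
    sep_cols = [c for c in frame.columns if str(c).startswith("sep")]
    assert len(sep_cols) == 1
    assert (frame[sep_cols[0]] == -1).all()


def test_determinism_identical_trajectories(nlrp3_model, nlrp3_off):
    a = run_scenario(nlrp3_model, Scenario("x", {"LPS", "Nigericin"}),
                     off_state=nlrp3_off)
    b = run_scenario(nlrp3_model, Scenario("x", {"LPS", "Nigericin"}),
                     off_state=nlrp3_off)
    assert a.trajectory.steps == b.trajectory.steps


def test_initial_assignment_modes(nlrp3_model):
    neutral = initial_assignment(nlrp3_model, "neutral")
    alltrue = initial_assignment(nlrp3_model, "all-true")
    kinds = nlrp3_model.kinds
    for key, kind in kinds.items():
        if kind == "input":
            assert not neutral[key] and not alltrue[key]
        else:
            assert alltrue[key]
    assert neutral["NLRP3"]                       # components present
    assert neutral["NLRP3_[(S5)]-{0}"]            # neutral states true
    assert not neutral["NLRP3_[(S5)]-{P}"]        # modified states false
    with pytest.raises(ValueError):
        initial_assignment(nlrp3_model, "bogus")
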