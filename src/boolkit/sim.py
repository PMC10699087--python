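"""Synchronous simulation of bipartite Boolean models.

All nodes update simultaneously; clamped inputs are pinned to their clamp
value at every step.  Trajectories are followed until an assignment repeats,
which yields either a point attractor (a fixed point) or a cycle.

The *natural off state* is the point attractor reached, with every input
FALSE, from an artificial initial assignment.  Two artificial starts are
supported: ``"neutral"`` (components present, all neutral states TRUE,
everything else FALSE) and ``"all-true"`` (everything TRUE except inputs).
The neutral start is the default: it corresponds to freshly produced,
unmodified and unbound protein pools relaxing to rest.  The all-true start
additionally asserts irreversibly produced states (cleaved caspases,
gasdermin pores) whose only removal route would be degradation of a
constitutive component, so networks containing such latches need not relax
to the same rest state from it; see the methods note.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
import yaml

from .compiler import BooleanModel

__all__ = [
    "Assignment",
    "Trajectory",
    "Attractor",
    "Scenario",
    "ScenarioResult",
    "NonConvergenceError",
    "CyclicOffStateError",
    "ClampError",
    "step",
    "simulate_to_attractor",
    "initial_assignment",
    "natural_off_state",
    "run_scenario",
    "export_trajectory",
    "load_scenario",
]

Assignment = Dict[str, bool]


class ClampError(ValueError):
    """A clamp was requested on a non-input node."""


class NonConvergenceError(RuntimeError):
    """No attractor within max_steps; carries the trajectory so far."""

    def __init__(self, message: str, trajectory: "Trajectory"):
        super().__init__(message)
        self.trajectory = trajectory


class CyclicOffStateError(RuntimeError):
    """The artificial start relaxed to a cycle, not a point."""


@dataclass
class Trajectory:
    """An ordered list of assignments related by one synchronous step each,
    under fixed clamps."""

    steps: List[Assignment]
    clamps: Dict[str, bool] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.steps)

    def first_true_step(self, key: str) -> Optional[int]:
        for i, assignment in enumerate(self.steps):
            if assignment[key]:
                return i
        return None

    def ever_true(self) -> Set[str]:
        out: Set[str] = set()
        for assignment in self.steps:
            out.update(k for k, v in assignment.items() if v)
        return out


@dataclass
class Attractor:
    kind: str  # "point" | "cycle"
    states: List[Assignment]
    entry_step: int

    @property
    def period(self) -> int:
        return len(self.states)


@dataclass
class Scenario:
    """A clamped-input experiment started from the natural off state."""

    name: str
    clamped_true: Set[str] = field(default_factory=set)
    variant_flags: Set[str] = field(default_factory=set)
    max_steps: int = 500
    expected_activated: Optional[bool] = None
    note: str = ""

    @property
    def clamps(self) -> Dict[str, bool]:
        return {f"[{name}]": True for name in sorted(self.clamped_true)}


@dataclass
class ScenarioResult:
    scenario: Scenario
    off_state: Assignment
    trajectory: Trajectory
    attractor: Attractor
    readouts: Dict[str, str]  # node key -> "ON" | "OFF" | "OSCILLATING"

    def readout(self, key: str) -> str:
        return self.readouts[key]

    def is_on(self, key: str) -> bool:
        return self.readouts.get(key) == "ON"

    def to_json_dict(self) -> Dict[str, object]:
        off_digest = hashlib.sha256(
            json.dumps(sorted(self.off_state.items())).encode()
        ).hexdigest()[:16]
        return {
            "scenario": self.scenario.name,
            "clamped_true": sorted(self.scenario.clamped_true),
            "variant_flags": sorted(self.scenario.variant_flags),
            "off_state_hash": off_digest,
            "attractor": self.attractor.kind,
            "attractor_entry_step": self.attractor.entry_step,
            "readouts": dict(sorted(self.readouts.items())),
        }


def _check_clamps(model: BooleanModel, clamps: Mapping[str, bool]) -> None:
    bad = set(clamps) - model.clampable
    if bad:
        raise ClampError(f"clamps on non-input nodes: {sorted(bad)}")


def step(model: BooleanModel, assignment: Assignment,
         clamps: Optional[Mapping[str, bool]] = None) -> Assignment:
    """One synchronous update; clamped inputs take their clamp value.

    Reaction rules are evaluated first; state rules then see the *new*
    reaction values in their production terms (instantaneous production)
    but the old values in their consumption terms.
    """
    clamps = clamps or {}
    _check_clamps(model, clamps)
    kinds = model.kinds
    next_reactions = {
        key: model.rules[key].evaluate(assignment)
        for key in model.rules if kinds[key] == "reaction"
    }
    nxt = {}
    for key, rule in model.rules.items():
        if kinds[key] == "reaction":
            nxt[key] = next_reactions[key]
        else:
            nxt[key] = rule.evaluate(assignment, next_reactions)
    nxt.update(clamps)
    return nxt


def _apply_clamps(assignment: Assignment, clamps: Mapping[str, bool]) -> Assignment:
    out = dict(assignment)
    out.update(clamps)
    return out


def simulate_to_attractor(
    model: BooleanModel,
    initial: Assignment,
    clamps: Optional[Mapping[str, bool]] = None,
    max_steps: int = 500,
) -> Tuple[Trajectory, Attractor]:
    """Iterate synchronously until an assignment repeats.

    The returned trajectory starts at ``initial`` (with clamps applied) and
    ends at the first revisited assignment; the attractor is the segment
    between the two visits.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    clamps = dict(clamps or {})
    _check_clamps(model, clamps)
    order = model.node_keys
    current = _apply_clamps(initial, clamps)
    steps = [current]
    seen: Dict[Tuple[bool, ...], int] = {tuple(current[k] for k in order): 0}
    for _ in range(max_steps):
        current = step(model, current, clamps)
        steps.append(current)
        frozen = tuple(current[k] for k in order)
        if frozen in seen:
            entry = seen[frozen]
            trajectory = Trajectory(steps, clamps)
            cycle_states = steps[entry:-1]
            kind = "point" if len(cycle_states) == 1 else "cycle"
            return trajectory, Attractor(kind, cycle_states, entry)
        seen[frozen] = len(steps) - 1
    raise NonConvergenceError(
        f"no attractor within {max_steps} steps",
        Trajectory(steps, clamps),
    )


def initial_assignment(model: BooleanModel, start: str = "neutral") -> Assignment:
    """Build an artificial initial assignment (inputs always FALSE)."""
    kinds = model.kinds
    out: Assignment = {}
    for key in model.node_keys:
        kind = kinds[key]
        if kind == "input":
            out[key] = False
        elif start == "all-true":
            out[key] = True
        elif start == "neutral":
            if kind == "component":
                out[key] = True
            elif kind == "state":
                out[key] = key.endswith("--0") or key.endswith("-{0}")
            else:
                out[key] = False
        else:
            raise ValueError(f"unknown start mode {start!r}")
    return out


def natural_off_state(model: BooleanModel, start: str = "neutral",
                      max_steps: int = 500) -> Assignment:
    """Relax the model, with all inputs FALSE, to its resting point attractor."""
    initial = initial_assignment(model, start)
    _, attractor = simulate_to_attractor(model, initial, {}, max_steps)
    if attractor.kind != "point":
        raise CyclicOffStateError(
            f"artificial start {start!r} relaxed to a {attractor.period}-cycle"
        )
    return attractor.states[0]


def classify_readout(attractor: Attractor, key: str) -> str:
    values = {state[key] for state in attractor.states}
    if values == {True}:
        return "ON"
    if values == {False}:
        return "OFF"
    return "OSCILLATING"


def run_scenario(
    model: BooleanModel,
    scenario: Scenario,
    off_state: Optional[Assignment] = None,
    readout_keys: Optional[Sequence[str]] = None,
) -> ScenarioResult:
    """Clamp the scenario's inputs in the natural off state and simulate to
    the treated attractor.

    ``model`` must already be compiled with the scenario's variant flags
    applied (variants patch the knowledge base before compilation).
    ``off_state`` may be passed to reuse a precomputed resting state.
    """
    if off_state is None:
        off_state = natural_off_state(model, max_steps=scenario.max_steps)
    clamps = scenario.clamps
    _check_clamps(model, clamps)
    trajectory, attractor = simulate_to_attractor(
        model, off_state, clamps, scenario.max_steps
    )
    keys = list(readout_keys) if readout_keys is not None else [
        n.key for n in model.nodes if n.kind == "output"
    ]
    readouts = {key: classify_readout(attractor, key) for key in keys}
    return ScenarioResult(scenario, off_state, trajectory, attractor, readouts)


def _trajectory_frame(trajectory: Trajectory, model: Optional[BooleanModel],
                      sort: str) -> pd.DataFrame:
    if not trajectory.steps:
        raise ValueError("empty trajectory")
    if model is not None:
        keys = model.node_keys
    else:
        keys = list(trajectory.steps[0])
    matrix = {key: [int(s[key]) for s in trajectory.steps] for key in keys}
    frame = pd.DataFrame.from_dict(matrix, orient="index",
                                   columns=range(len(trajectory.steps)))
    if sort == "activation-order":
        declaration = {key: i for i, key in enumerate(keys)}

        def sort_key(key: str):
            first = trajectory.first_true_step(key)
            return (first if first is not None else len(trajectory.steps),
                    declaration[key])

        frame = frame.loc[sorted(keys, key=sort_key)]
    elif sort != "declaration-order":
        raise ValueError(f"unknown sort mode {sort!r}")
    frame.index.name = "node"
    return frame


def export_trajectory(
    trajectory: Trajectory,
    path=None,
    sort: str = "activation-order",
    model: Optional[BooleanModel] = None,
) -> pd.DataFrame:
    """Render a node x time 0/1 matrix (rows sorted by step of first
    activation by default; never-active rows last, ties by declaration
    order).  Writes CSV if ``path`` is given."""
    frame = _trajectory_frame(trajectory, model, sort)
    if path is not None:
        frame.to_csv(path)
    return frame


def export_trajectories(
    trajectories: Sequence[Trajectory],
    path=None,
    sort: str = "activation-order",
    model: Optional[BooleanModel] = None,
) -> pd.DataFrame:
    """Concatenate several trajectories column-wise with a separator column
    (all -1) between runs; rows are sorted on the first trajectory."""
    if not trajectories:
        raise ValueError("no trajectories")
    frames = [_trajectory_frame(t, model, sort="declaration-order")
              for t in trajectories]
    lead = _trajectory_frame(trajectories[0], model, sort)
    blocks = []
    for i, frame in enumerate(frames):
        frame = frame.loc[lead.index]
        frame.columns = [f"t{i}.{c}" for c in frame.columns]
        blocks.append(frame)
        if i < len(frames) - 1:
            blocks.append(pd.DataFrame({f"sep{i}": [-1] * len(frame)},
                                       index=frame.index))
    out = pd.concat(blocks, axis=1)
    out.index.name = "node"
    if path is not None:
        out.to_csv(path)
    return out


def load_scenario(path) -> Scenario:
    """Read a scenario definition from YAML (keys: name, inputs, variants,
    max_steps)."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    return Scenario(
        name=str(raw.get("name", "scenario")),
        clamped_true=set(raw.get("inputs", []) or []),
        variant_flags=set(raw.get("variants", []) or []),
        max_steps=int(raw.get("max_steps", 500)),
    )
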