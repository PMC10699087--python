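"""The curated NLRP3 inflammasome network, scenario catalogue and outcome
classification.

The network covers the PI(4)P/NEK7-dependent activation axis of the NLRP3
inflammasome: NF-kB-dependent transcriptional priming of NLRP3 and
pro-IL-1b; post-translational licensing through the Ser5, Ser198, Ser295,
Ser806 and Tyr861 phosphorylation sites and the K48-/K63-linked
ubiquitylation of the LRR domain; the nucleotide (ATPase) cycle of the
NACHT domain; the trigger chain connecting ionophores, lysosome
destabilisers and electron-transport-chain inhibitors to centrosomal
PI(4)P or exposed cardiolipin; assembly via NEK7 binding, NACHT
dimerisation, PYD polymerisation and ASC/caspase-1 filaments; the caspase-1
outputs IL-1b, IL-18 and gasdermin D; the non-canonical caspase-4/5 route
for cytoplasmic LPS; and turnover through the proteasome and autophagy.
Drugs and mutations (MCC950, G5, okadaic acid, the CAPS mutations D305G and
T346M, the LRR-less miniNLRP3 truncation) are modelled as inputs, two of
them with explicit alternative-mechanism variants.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .compiler import BooleanModel, build_update_rules
from .kb import Contingency, KnowledgeBase, load_knowledge_base, validate_knowledge_base
from .reactions import Registry
from .sim import Assignment, Scenario, ScenarioResult, classify_readout, natural_off_state, run_scenario
from .states import BondState, InputRef, Locus, ModificationState, parse_state

__all__ = [
    "ActivationCall",
    "VARIANTS",
    "WATCH_NODES",
    "load_nlrp3_network",
    "apply_variants",
    "compile_variant",
    "scenario_catalogue",
    "classify_outcome",
    "run_catalogue",
]

# Node keys used for outcome classification.
WATCH_NODES = {
    "speck": "ASC_[pydA]--NLRP3_[pydB]",
    "casp1_active": "Caspase1_[(pro)]-{truncated}",
    "il1b_release": "[IL1Brelease]",
    "il18_release": "[IL18release]",
    "pyroptosis": "[Pyroptosis]",
    "bacterial_killing": "[BacterialKilling]",
    "nlrp3_present": "NLRP3",
    "nek7_bond": "NEK7_[clobe]--NLRP3_[HD2LRR]",
    "nacht_dimer": "NLRP3_[NACHT]--NLRP3_[NACHT]",
    "cl_bond": "CL_[lrrCL]--NLRP3_[cl]",
}

# Model variants: named rule patches applied to the knowledge base before
# compilation, capturing alternative mechanistic hypotheses.
MCC950_BLOCKS_ABIND = "mcc950-blocks-abind"
T346M_BYPASSES_CENTROSOME = "t346m-bypasses-centrosome"
VARIANTS = {
    MCC950_BLOCKS_ABIND:
        "MCC950 binding also blocks ATP binding to the empty NBD, not only "
        "ADP-to-ATP exchange",
    T346M_BYPASSES_CENTROSOME:
        "the open-conformation mutation T346M makes NLRP3 activation "
        "independent of centrosomal PI(4)P/cardiolipin localisation",
}


def load_nlrp3_network() -> KnowledgeBase:
    """Load the built-in NLRP3 fixture (two TSV tables plus the registry)."""
    base = resources.files("boolkit").joinpath("data/nlrp3")
    with resources.as_file(base) as path:
        from .kb import load_knowledge_base_dir

        return load_knowledge_base_dir(path)


def apply_variants(kb: KnowledgeBase, flags: Iterable[str]) -> KnowledgeBase:
    """Return a copy of the KB with the given variant patches applied."""
    flags = set(flags)
    unknown = flags - set(VARIANTS)
    if unknown:
        raise ValueError(f"unknown variant flags {sorted(unknown)}")
    if not flags:
        return kb
    kb = copy.deepcopy(kb)
    next_uid = max((c.uid for c in kb.contingencies), default=0) + 1
    if MCC950_BLOCKS_ABIND in flags:
        target = kb.reaction_index["NLRP3_aBind_NLRP3_[(NBD)]"]
        modifier = parse_state("MCC950_[bd]--NLRP3_[NOD]")
        kb.contingencies.append(
            Contingency(next_uid, target, "x", modifier, "variant patch")
        )
        next_uid += 1
    if T346M_BYPASSES_CENTROSOME in flags:
        kb.gates["CentrosomalNLRP3OR"].members.append(InputRef("nlrp3T346M"))
    return kb


def compile_variant(kb: KnowledgeBase, flags: Iterable[str]) -> BooleanModel:
    return build_update_rules(apply_variants(kb, flags))


def scenario_catalogue() -> List[Scenario]:
    """The in-silico experiment catalogue: stimuli, inhibitors, mutations.

    ``expected_activated`` records the experimentally established outcome
    (inflammasome assembly with IL-1b release, or not) that the simulation
    is expected to reproduce.
    """

    def s(name, inputs, variants=(), expected=None, note=""):
        return Scenario(name, set(inputs), set(variants),
                        expected_activated=expected, note=note)

    return [
        s("S-none", [], expected=False, note="untreated control"),
        s("S-LPS", ["LPS"], expected=False, note="priming only"),
        s("S-Nig", ["Nigericin"], expected=False, note="trigger only"),
        s("S-LPS+Nig", ["LPS", "Nigericin"], expected=True,
          note="canonical two-signal activation"),
        s("S-Pam+Imq", ["Pam3csk4", "Imiquimod"], expected=True,
          note="KCl-insensitive type III trigger; K+ efflux only via the "
               "gasdermin pore feedback"),
        s("S-extLPS", ["LPS"], expected=False, note="extracellular LPS only"),
        s("S-intLPS", ["intLPS"], expected=False,
          note="cytoplasmic LPS without priming; the caspase-4/5 route may "
               "still drive gasdermin pores"),
        s("S-dualLPS", ["LPS", "intLPS"], expected=True,
          note="non-canonical feedback plus priming"),
        s("S-MMPT", ["MMPT"], expected=False, note="cardiolipin exposure only"),
        s("S-LPS+MMPT", ["LPS", "MMPT"], expected=True,
          note="cardiolipin-axis activation"),
        s("S-MCC-A", ["LPS", "Nigericin", "MCC950"], expected=True,
          note="MCC950 blocking exchange only is bypassed by ATP binding to "
               "newly synthesised NLRP3"),
        s("S-MCC-B", ["LPS", "Nigericin", "MCC950"],
          [MCC950_BLOCKS_ABIND], expected=False,
          note="MCC950 blocking exchange and binding interrupts activation "
               "after NEK7 binding"),
        s("S-G5", ["LPS", "Nigericin", "G5"], expected=True,
          note="deubiquitinase inhibition bypassed by synthesis of "
               "unubiquitylated NLRP3"),
        s("S-OKA", ["LPS", "Nigericin", "OKA"], expected=True,
          note="phosphatase inhibition bypassed by synthesis of "
               "unphosphorylated NLRP3"),
        s("S-D305G", ["nlrp3D305G"], expected=False),
        s("S-LPS+D305G", ["LPS", "nlrp3D305G"], expected=False,
          note="loss of PKA-site control alone does not activate"),
        s("S-T346M-A", ["LPS", "nlrp3T346M"], expected=False,
          note="open conformation alone, centrosome requirement intact"),
        s("S-T346M-B", ["LPS", "nlrp3T346M"],
          [T346M_BYPASSES_CENTROSOME], expected=True,
          note="constitutively open NLRP3 activated by priming alone"),
        s("S-mini-Nig", ["LPS", "Nigericin", "miniNLRP3"], expected=True,
          note="LRR-less NLRP3 phenocopies full length on the PI(4)P axis"),
        s("S-mini-MMPT", ["LPS", "MMPT", "miniNLRP3"], expected=False,
          note="LRR-less NLRP3 cannot bind cardiolipin"),
        s("S-extK-Nig", ["LPS", "Nigericin", "extK"], expected=False,
          note="type I trigger suppressed by external KCl"),
        s("S-extK-Imq", ["LPS", "Imiquimod", "extK"], expected=True,
          note="type III trigger insensitive to external KCl"),
    ]


@dataclass
class ActivationCall:
    """Qualitative outcome of one in-silico experiment."""

    speck: bool
    casp1_active: bool
    il1b_release: bool
    il18_release: bool
    pyroptosis: bool
    bacterial_killing: bool
    nlrp3_present: bool
    oscillating: bool
    summary: str

    @property
    def activated(self) -> bool:
        """NLRP3 inflammasome activation: speck, active caspase-1 and IL-1b
        release all present."""
        return self.speck and self.casp1_active and self.il1b_release


def classify_outcome(result: ScenarioResult) -> ActivationCall:
    """Derive the activation call from a scenario's attractor readouts.

    ``FULL_ACTIVATION`` requires the ASC speck, active caspase-1 and IL-1b
    release.  ``PORE_ONLY`` flags gasdermin-pore-driven pyroptosis without a
    speck (the non-canonical caspase-4/5 route without priming).
    ``TRIGGERED_ONLY`` marks a speck without the full output,
    ``PRIMED_ONLY`` an NLRP3 pool with no assembly at all.  Oscillating
    readouts are surfaced via ``oscillating``; they never silently count as
    ON.
    """
    attractor = result.attractor
    flags: Dict[str, bool] = {}
    oscillating = False
    for name, key in WATCH_NODES.items():
        value = classify_readout(attractor, key)
        flags[name] = value == "ON"
        if value == "OSCILLATING" and name != "nlrp3_present":
            oscillating = True

    if flags["speck"] and flags["casp1_active"] and flags["il1b_release"]:
        summary = "FULL_ACTIVATION"
    elif flags["pyroptosis"] and not flags["speck"]:
        summary = "PORE_ONLY"
    elif flags["speck"]:
        summary = "TRIGGERED_ONLY"
    elif flags["nlrp3_present"]:
        summary = "PRIMED_ONLY"
    else:
        summary = "NO_ACTIVATION"
    if oscillating:
        summary += "(OSCILLATING)"
    return ActivationCall(
        speck=flags["speck"],
        casp1_active=flags["casp1_active"],
        il1b_release=flags["il1b_release"],
        il18_release=flags["il18_release"],
        pyroptosis=flags["pyroptosis"],
        bacterial_killing=flags["bacterial_killing"],
        nlrp3_present=flags["nlrp3_present"],
        oscillating=oscillating,
        summary=summary,
    )


def run_catalogue(
    kb: Optional[KnowledgeBase] = None,
    scenarios: Optional[Sequence[Scenario]] = None,
) -> List[Tuple[Scenario, ScenarioResult, ActivationCall]]:
    """Compile (per variant set), simulate and classify every scenario."""
    kb = kb or load_nlrp3_network()
    report = validate_knowledge_base(kb)
    if not report.ok:
        raise ValueError(f"fixture failed validation:\n{report}")
    scenarios = list(scenarios) if scenarios is not None else scenario_catalogue()

    models: Dict[frozenset, Tuple[BooleanModel, Assignment]] = {}
    out = []
    for scenario in scenarios:
        flag_key = frozenset(scenario.variant_flags)
        if flag_key not in models:
            model = compile_variant(kb, flag_key)
            models[flag_key] = (model, natural_off_state(model))
        model, off_state = models[flag_key]
        watch = list(dict.fromkeys(
            [n.key for n in model.nodes if n.kind == "output"]
            + list(WATCH_NODES.values())
        ))
        result = run_scenario(model, scenario, off_state=off_state,
                              readout_keys=watch)
        out.append((scenario, result, classify_outcome(result)))
    return out
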