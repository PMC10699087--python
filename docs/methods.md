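# Methods

## Scope and intent

`boolkit` turns a reaction–contingency knowledge base — a list of
site-specific elemental reactions plus a list of regulatory constraints —
into an executable, parameter-free Boolean model. The model is strictly
qualitative: it answers whether a signal can propagate, never how fast or
how much. The built-in network describes the PI(4)P/NEK7-dependent
activation axis of the NLRP3 inflammasome; the caspase-8-dependent,
NEK7-independent axis, TXNIP and cathepsin B are deliberately outside its
scope, so in this model NEK7 binding is absolutely required for assembly.

## The state and reaction formalism

An elemental state is a fact about one site: a residue modification
(`NLRP3_[(S5)]-{P}`), a bond between two domains
(`NEK7_[clobe]--NLRP3_[HD2LRR]`), a free domain (`NEK7_[clobe]--0`), or a
nucleotide occupancy (`NLRP3_[(NBD)]-{ATP}`). Each state says nothing about
other sites of the same molecule; this keeps the representation congruent
with how site-directed experiments are reported and avoids microstate
enumeration. Bond equality is order-insensitive; the canonical form sorts
endpoints lexicographically, and that form is the node identity everywhere.

Reaction types are data: a registry table maps each type token to a class
(state-change, synthesis, degradation) and an effect pattern (for
modifications a modifier rewrite such as `0 → P`, for bonds
`free → bond` or the reverse). The normative registry covers
`P+ P- ub48+ ub63+ ub63- cut ppi+ ppi- i trsc trsl deg aBind aHy aEx`.
New types are added by adding registry rows, not code. Transcription
synthesises `<target>mRNA`; translation requires that mRNA as a component
and synthesises the protein.

Contingencies constrain a reaction or define an output: `!` required, `x`
inhibitory, `0` recorded but compiled to nothing. Modifiers may be states,
inputs, or named AND/OR/NOT gates; gates may nest but must be acyclic, and
they are fully inlined at compile time (inlining is semantics-preserving;
the test suite checks this exhaustively per gate).

## Update semantics of the bipartite Boolean model

Nodes: one per reaction, per elemental state (neutral states included),
per component, per input, per output. Rules:

* **Reaction**: AND of component presence, source states, required
  modifiers, and negated inhibitory modifiers.
* **State** (pool semantics — "some molecules carry this state"):
  `presence AND (produced_now OR (self AND NOT consumed))`.
  The production term evaluates the producing reactions' rules on the
  *current* assignment (instantaneous production), while the consumption
  term uses the reaction nodes' values from the previous step. This
  asymmetry is deliberate: with both terms delayed, an unconstrained
  kinase/phosphatase pair chases its own tail around a 4-cycle instead of
  settling with both site states TRUE, and the network has no resting
  point. Production therefore dominates consumption by construction.
* **Neutral states** are additionally produced by every synthesis reaction
  of their component (fresh protein is unmodified and unbound). Neutral
  states of components that have *no* synthesis reaction are modelled as
  inexhaustible pools (`rule = presence`): a constitutive component stands
  for an unlimited supply, so one partner binding a shared site (AKT on
  the PI head group) must not exhaust it for another (NLRP3). Without this
  choice no ionophore scenario can activate.
* **Components** with synthesis: `synthesised OR (self AND NOT degraded)`;
  without synthesis: constitutively TRUE. A degradation reaction also
  consumes those states of its target that appear among its own required
  modifiers (the ubiquitin mark that recruited it disappears with the
  protein).
* **Outputs** take their defining contingency expression (`!` rows
  conjoined, `x` rows conjoined as negations); **inputs** hold their value
  unless clamped.

Simulation is synchronous and deterministic. Trajectories are followed
until an assignment repeats; the attractor is a fixed point or a cycle, and
readouts are ON/OFF only if constant across all attractor states,
OSCILLATING otherwise (never silently coerced).

## The natural off state

The resting state is found by relaxing the model, all inputs FALSE, from an
artificial start. The default start is *all-neutral*: components present,
neutral states TRUE, everything else FALSE — freshly made, unmodified,
unbound pools. An *all-true* start is also implemented, but it asserts
irreversibly produced states (cleaved caspases, gasdermin–lipid bonds,
ASC/CARD filament bonds) whose only removal route would be degradation of a
constitutive component; those states latch, and the model then relaxes to a
different fixed point with outputs ON. The two starts are therefore **not**
equivalent on the built-in network, and the off state is defined from the
all-neutral start. For the fixture it is a point attractor with every
output node FALSE and no NLRP3 present (no priming, no synthesis).

## Scenarios, variants and classification

A scenario clamps a set of inputs TRUE in the off state and simulates to
the treated attractor (`max_steps` defaults to 500; the fixture settles in
well under 30, and exhaustion raises loudly). Mechanistic alternatives are
*variants*: named knowledge-base patches applied before compilation —
`mcc950-blocks-abind` adds an inhibitory MCC950-bond contingency to ATP
binding, `t346m-bypasses-centrosome` adds the T346M input as a disjunct of
the centrosomal-localisation gate.

The activation call reads the attractor: `speck` is the ASC–NLRP3 PYD bond,
`casp1_active` the truncated caspase-1 state, the release/pyroptosis/
bactericidal flags are the corresponding outputs. Full activation means
speck AND active caspase-1 AND IL-1β release. `PORE_ONLY` marks gasdermin
pores (and hence pyroptosis) without a speck — the non-canonical
caspase-4/5 route without priming; `PRIMED_ONLY` marks a synthesised but
unassembled NLRP3 pool. Whether cytoplasmic LPS alone "counts" as
activation is a modelling question; both readouts are reported and neither
is coerced.

## Curation choices in the built-in network

* Transcription/translation need a catalytic subject; placeholder
  components `Pol` and `Ribo` serve, and `X` stands for unknown catalysts
  (mRNA turnover, unassigned phosphatases), following the network's own
  placeholder convention.
* AKT's Ser473 kinase is mTORC2.
* The AKT activator input is named `[SC79]`.
* Lysosomal membrane permeabilisation is gated as
  `AND([HighLysoK], NOT [extK])`: lysosome-destabilising (type II)
  triggers permeabilise by default and high external KCl rescues, without
  requiring a prior ionophore event.
* MCC950's baseline mechanism blocks only ADP→ATP exchange; the stronger
  hypothesis (also blocking ATP binding) ships as a variant, since only the
  stronger form fully inhibits in silico.
* A generic phosphatase `X_P-_NLRP3_[(S295)]` keeps Ser295 reversible.
* IL-18 is constitutive (no synthesis reactions); only NLRP3 and pro-IL-1β
  are under transcriptional priming.
* `extATP`, `PoreToxin` and `Type2Trigger` are representative inputs for
  their trigger classes; the full trigger catalogue is out of scope.
* The miniNLRP3 truncation is an input that inhibits the eight
  LRR-directed reactions (contingency UIDs 175–182).

## The synthetic generator and the reference interpreter

The generator emits small knowledge bases biased toward the motifs the
semantics must handle — kinase/phosphatase cycles, bonds with and without
reverse reactions, ubiquitylation cycles, cleavage, nucleotide cycles, and
input-gated synthesis/degradation — plus strict contingencies and nested
gates, always with at least one input and one output, and always
validator-clean. Generation is a pure function of `(config, seed)`.
Defaults (4 components, 6 reactions, contingency probability 0.6, gate
probability 0.3, depth ≤ 2, synthesis probability 0.25) keep networks at or
below 30 nodes so equivalence sweeps stay exhaustive and fast.

The reference interpreter executes the same semantics directly from the
knowledge base, re-deriving producers, consumers and contingency
expressions every step without building rule expressions. It is the
independent oracle: compiled model and interpreter must agree bitwise on
every node at every step, from both artificial starts, under random
clamps. What these synthetic networks do *not* emulate: realistic degree
distributions, feedback density, or component counts of real signalling
networks — passing the sweep certifies the compiler/simulator semantics,
not biological realism.

## Numerical and procedural choices

* Everything is Boolean; there are no tolerances. Determinism is exact:
  identical model and scenario give bitwise-identical trajectories.
* Attractor detection hashes full assignments; the first revisit defines
  the attractor and entry step.
* Node ordering (and hence trajectory export) follows declaration order;
  activation-order export sorts rows by first-TRUE step with never-TRUE
  rows last and declaration order as tie-break.
* Graph serialisation sorts nodes and edges, so repeated writes are
  byte-identical. Neutral states never appear in the regulatory graph; a
  neutral modifier is rendered as a NOT operator over the non-neutral
  states of the same site.
* Trajectory lengths and step counts are properties of this
  implementation's update order and are not meaningful quantities beyond
  their ordering; only attractor content and first-activation order are
  asserted.

## Known limitations

* Qualitative only: no rates, concentrations, or dose responses. The D305G
  scenario illustrates the limit — a mutation whose effect is quantitative
  modulation of the nucleotide cycle cannot flip a Boolean outcome.
* Synchronous update only; asynchronous or stochastic schedules are out of
  scope.
* Pool semantics cannot express stoichiometric competition or sequestration.
* The all-true artificial start is not a usable resting-state seed for
  networks with irreversible proteolysis (see above).
* Outputs chained through other outputs introduce one step of delay per
  link; ordering claims are robust to this, absolute step numbers are not.
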