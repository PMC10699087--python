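# boolkit

Reaction–contingency knowledge bases, compiled to bipartite Boolean models
and simulated synchronously — with a curated network of NLRP3 inflammasome
signalling as the built-in application.

`boolkit` is for systems biologists and immunologists who want to encode
mechanistic signalling knowledge as *elemental reactions* (decontextualised,
site-specific events such as `AKT_P+_NLRP3_[(S5)]`) and *contingencies*
(regulatory constraints: required `!`, inhibitory `x`, or neutral `0`,
optionally combined through nested AND/OR/NOT gates), and then execute that
knowledge qualitatively: does the assembled mechanism explain which stimuli
activate the pathway, and how inhibitors and mutations change the answer?

## The model

A knowledge base is a pair of tables. The ReactionList holds typed events
over site-resolved subjects:

* modifications at residues — `P+`/`P-`, `ub48+`, `ub63+`/`ub63-`, `cut`,
  and the nucleotide cycle `aBind`/`aHy`/`aEx` (empty → ATP → ADP → ATP);
* bonds between domains — `ppi+`/`ppi-` and the lipid-binding alias `i`;
* synthesis and degradation — `trsc` (makes `<target>mRNA`), `trsl`, `deg`.

The ContingencyList constrains reactions and defines named Boolean gates
and system inputs/outputs (bracketed names such as `[LPS]` or
`[IL1Brelease]`).

Compilation produces a **bipartite Boolean model**: one node per reaction,
per elemental state (neutral states included), per component, per input and
per output, with mechanically derived update rules. A reaction node is the
conjunction of its components' presence, its source states, its required
modifiers and the negation of its inhibitory modifiers. A state node holds
*pool* semantics — "some molecules carry this state" — so it is TRUE if
produced this step, or held over without being consumed; production
dominates consumption, and neutral states of components that are never
synthesised form inexhaustible pools. Synchronous simulation from an
artificial all-neutral start relaxes the network, with every input FALSE,
to its **natural off state**; an experiment then clamps inputs TRUE and
follows the trajectory to its attractor, where readouts are classified ON,
OFF or OSCILLATING.

The shipped NLRP3 network covers transcriptional priming (Signal 1),
post-translational licensing (Ser5, Ser198, Ser295, Ser806, Tyr861
phosphorylation; K48/K63 ubiquitylation), the NACHT nucleotide cycle, the
Signal-2 trigger chain (ionophores, lysosome destabilisers and
electron-transport-chain inhibitors converging on centrosomal PI(4)P or
exposed cardiolipin), NEK7-dependent assembly, the caspase-1 outputs
(IL-1β, IL-18, gasdermin D), the non-canonical caspase-4/5 route, and
NLRP3 turnover. Drugs and mutations (MCC950, G5, okadaic acid, D305G,
T346M, the LRR-less miniNLRP3) are modelled as inputs, two of them with
explicit alternative-mechanism variants.

## Worked example

```sh
boolkit scenarios --fixture nlrp3 --all
```

prints the activation truth table of the scenario catalogue (1 = the node
is ON in the treated attractor):

```
scenario        speck  casp1  IL1B  IL18  pyroptosis  summary
S-none          0      0      0     0     0           NO_ACTIVATION
S-LPS           0      0      0     0     0           PRIMED_ONLY
S-Nig           0      0      0     0     0           NO_ACTIVATION
S-LPS+Nig       1      1      1     1     1           FULL_ACTIVATION
S-Pam+Imq       1      1      1     1     1           FULL_ACTIVATION
S-intLPS        0      0      0     0     1           PORE_ONLY
S-dualLPS       1      1      1     1     1           FULL_ACTIVATION
S-MMPT          0      0      0     0     0           NO_ACTIVATION
S-LPS+MMPT      1      1      1     1     1           FULL_ACTIVATION
S-MCC-A         1      1      1     1     1           FULL_ACTIVATION
S-MCC-B         0      0      0     0     0           PRIMED_ONLY
S-G5            1      1      1     1     1           FULL_ACTIVATION
S-OKA           1      1      1     1     1           FULL_ACTIVATION
S-T346M-A       0      0      0     0     0           PRIMED_ONLY
S-T346M-B       1      1      1     1     1           FULL_ACTIVATION
S-mini-Nig      1      1      1     1     1           FULL_ACTIVATION
S-mini-MMPT     0      0      0     0     0           PRIMED_ONLY
S-extK-Nig      0      0      0     0     0           PRIMED_ONLY
S-extK-Imq      1      1      1     1     1           FULL_ACTIVATION
```

Reading it: LPS alone only primes (NLRP3 is synthesised and licensed, no
assembly); nigericin alone runs the trigger chain but there is nothing to
assemble; together they give full activation — ASC speck, caspase-1
processing, IL-1β/IL-18 release and pyroptosis. MCC950 blocking only
ADP→ATP exchange is bypassed by ATP binding to newly synthesised NLRP3
(`S-MCC-A`); blocking ATP binding as well halts the cascade right after
NEK7 binding (`S-MCC-B`). The deubiquitinase inhibitor G5 and the
phosphatase inhibitor okadaic acid are both bypassed by priming-driven
synthesis of unmodified NLRP3. The LRR-less miniNLRP3 phenocopies the
full-length protein on the PI(4)P axis but cannot respond to cardiolipin
exposure (`S-mini-MMPT`). External KCl suppresses the ionophore route but
not the electron-transport-chain route (`S-extK-*`).

The same pipeline is available as a library:

```python
from boolkit import load_nlrp3_network, build_update_rules, natural_off_state
model = build_update_rules(load_nlrp3_network())
off = natural_off_state(model)          # point attractor, all outputs OFF
```

Other entry points: `boolkit validate <kb-dir>`,
`boolkit simulate <kb-dir> --scenario <yaml>`,
`boolkit graph <kb-dir> --format graphml -o out.graphml`,
`boolkit synth --seed N --out <dir>`.

## Layout

| module               | contents                                             |
| -------------------- | ---------------------------------------------------- |
| `boolkit.states`     | elemental-state grammar and canonical rendering      |
| `boolkit.reactions`  | reaction types (registry-driven) and effect derivation |
| `boolkit.kb`         | knowledge bases: TSV dialect, gates, validation      |
| `boolkit.compiler`   | bipartite Boolean model construction                 |
| `boolkit.sim`        | synchronous simulation, attractors, scenarios        |
| `boolkit.nlrp3`      | the curated NLRP3 network, variants, classification  |
| `boolkit.reggraph`   | regulatory-graph export (GraphML/DOT)                |
| `boolkit.synth`      | random network generator + reference interpreter     |

See `docs/methods.md` for the precise update semantics, the design choices
behind them, and known limitations.
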