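"""Regulatory-graph export: the causal view of a knowledge base.

Nodes are elemental reactions, non-neutral elemental states, components,
Boolean operators and inputs/outputs; edges carry the causal role
(production, consumption, synthesis-degradation, required, inhibitory,
membership).  Neutral states are excluded — the graph shows what reactions
do and what regulates them, not the bookkeeping of empty sites.  Categories
are emitted as plain node/edge attributes; colours and layout are a viewer
concern.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Tuple

import networkx as nx

from .kb import KnowledgeBase
from .states import (
    BondState,
    ElementalState,
    FreeDomainState,
    GateRef,
    InputRef,
    ModificationState,
    StateLike,
)

__all__ = ["build_regulatory_graph", "write_graph"]

_GATE_CATEGORY = {"AND": "boolean-AND", "OR": "boolean-OR", "NOT": "boolean-NOT"}


def _counterparts(kb: KnowledgeBase, neutral: ElementalState) -> List[ElementalState]:
    """Non-neutral states of the same site as a neutral state."""
    pool: dict = {}
    for r in kb.reactions:
        for state in list(r.consumed) + list(r.produced):
            pool.setdefault(state.key, state)
    for state in kb.iter_modifier_states():
        pool.setdefault(state.key, state)
    out = []
    for state in pool.values():
        if state.is_neutral:
            continue
        if isinstance(neutral, ModificationState) and isinstance(state, ModificationState):
            if (state.component, state.residue) == (neutral.component, neutral.residue):
                out.append(state)
        elif isinstance(neutral, FreeDomainState) and isinstance(state, BondState):
            endpoint = (neutral.component, neutral.domain)
            if endpoint in (state.endpoint_a, state.endpoint_b):
                out.append(state)
    return sorted(out, key=lambda s: s.key)


def _modifier_node(graph: nx.DiGraph, kb: KnowledgeBase, modifier: StateLike) -> str:
    """Ensure the node for a contingency modifier exists; return its key."""
    if isinstance(modifier, GateRef):
        key = modifier.render()
        gate = kb.gates.get(modifier.name)
        category = _GATE_CATEGORY.get(gate.op if gate else "AND")
        if key not in graph:
            graph.add_node(key, category=category)
            if gate is not None:
                for member in gate.members:
                    member_key = _modifier_node(graph, kb, member)
                    graph.add_edge(member_key, key, category="membership")
        return key
    if isinstance(modifier, InputRef):
        key = modifier.render()
        if key not in graph:
            graph.add_node(key, category="input-output")
        return key
    if modifier.is_neutral:
        # Neutral states are excluded from the graph; a neutral modifier
        # ("the site is unmodified/unbound") is rendered as a NOT operator
        # fed by the non-neutral state(s) of the same site.
        key = f"<NOT {modifier.key}>"
        if key not in graph:
            graph.add_node(key, category="boolean-NOT")
            for counterpart in _counterparts(kb, modifier):
                graph.add_node(counterpart.key, category="state")
                graph.add_edge(counterpart.key, key, category="membership")
        return key
    key = modifier.key
    if key not in graph:
        graph.add_node(key, category="state")
    return key


def build_regulatory_graph(kb: KnowledgeBase) -> nx.DiGraph:
    """Build the regulatory graph of a validated knowledge base."""
    graph = nx.DiGraph()

    for component in kb.components:
        graph.add_node(component, category="component")
    for r in kb.reactions:
        graph.add_node(r.text, category="reaction")
    for r in kb.reactions:
        for state in sorted(r.produced, key=lambda s: s.key):
            if state.is_neutral:
                continue
            graph.add_node(state.key, category="state")
            graph.add_edge(r.text, state.key, category="production")
        for state in sorted(r.consumed, key=lambda s: s.key):
            if state.is_neutral:
                continue
            graph.add_node(state.key, category="state")
            graph.add_edge(r.text, state.key, category="consumption")
        if r.synthesises:
            graph.add_edge(r.text, r.synthesises, category="synthesis-degradation")
        if r.degrades:
            graph.add_edge(r.text, r.degrades, category="synthesis-degradation")

    for io in list(kb.inputs) + list(kb.outputs):
        graph.add_node(io.render(), category="input-output")

    for c in kb.contingencies:
        if c.is_gate_row:
            # membership edges are added when the gate node is materialised
            _modifier_node(graph, kb, GateRef(c.target.name))
            continue
        if c.kind == "0":
            continue
        source = _modifier_node(graph, kb, c.modifier)
        target = c.target_key
        if target not in graph:
            graph.add_node(target, category="input-output")
        category = "required" if c.kind == "!" else "inhibitory"
        graph.add_edge(source, target, category=category)

    return graph


def write_graph(graph: nx.DiGraph, path, fmt: str = "graphml") -> None:
    """Serialise with deterministic node/edge ordering (diff-stable)."""
    ordered = nx.DiGraph()
    for key in sorted(graph.nodes):
        ordered.add_node(key, **graph.nodes[key])
    for u, v in sorted(graph.edges):
        ordered.add_edge(u, v, **graph.edges[u, v])
    if fmt == "graphml":
        nx.write_graphml(ordered, path)
    elif fmt == "dot":
        lines = ["digraph regulatory {"]
        for key in ordered.nodes:
            category = ordered.nodes[key].get("category", "")
            lines.append(f'  "{key}" [category="{category}"];')
        for u, v in ordered.edges:
            category = ordered.edges[u, v].get("category", "")
            lines.append(f'  "{u}" -> "{v}" [category="{category}"];')
        lines.append("}")
        with open(path, "w") as handle:
            handle.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
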