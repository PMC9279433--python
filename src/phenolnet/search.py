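"""Guided search over the extended metabolic space ("biosensor" mode).

Starting from a source compound (a dietary phenolic), reaction rules are
applied iteratively to grow a scope of predicted transformations until the
products land in the sink set — the metabolites already connected to the
known metabolic network.  The search is a deterministic best-first expansion:
the frontier is ordered by the combined chemical×biological score of the
transformation that discovered each node (ties broken by insertion order),
which replaces the stochastic tree search of general-purpose retrosynthesis
tools while keeping the same inputs and outputs.

Pathways are then read out of the scope as linear chains; a pathway is
*connected* when every terminal metabolite is a sink, and only connected
pathways are returned (dangling ones are counted).
"""

from __future__ import annotations

import heapq
import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .chem import (BalanceError, CompoundStructure, PredictedTransformation,
                   ReactionRule, SearchParams, apply_rule, complete_and_balance,
                   score_match)
from .network import Reaction

__all__ = [
    "SearchParams", "Scope", "ScopeEdge", "PredictedPathway",
    "expand_node", "search_biosensor", "extract_connected_pathways",
]


@dataclass(frozen=True)
class ScopeEdge:
    """One accepted transformation in the scope, with its completed reaction."""

    transformation: PredictedTransformation
    depth: int
    reaction: Reaction | None = None

    @property
    def substrate_inchi(self) -> str:
        return self.transformation.substrate_structure.inchi


@dataclass
class Scope:
    """Full search output for one source compound."""

    source: str
    source_structure: CompoundStructure
    nodes: dict[str, CompoundStructure] = field(default_factory=dict)
    edges: list[ScopeEdge] = field(default_factory=list)
    trivially_connected: bool = False
    iterations: int = 0
    balance_failures: list[str] = field(default_factory=list)

    def edges_from(self, inchi: str) -> list[ScopeEdge]:
        return [e for e in self.edges if e.substrate_inchi == inchi]


@dataclass(frozen=True)
class PredictedPathway:
    """Ordered chain of predicted reactions from a source toward terminals."""

    transformations: tuple[PredictedTransformation, ...]
    reactions: tuple[Reaction | None, ...]
    terminal_set: frozenset[str]  # InChIs of chain products not consumed later

    def __len__(self) -> int:
        return len(self.transformations)


def _combined_score(rule: ReactionRule, t: PredictedTransformation) -> float:
    return rule.biological_score * t.chemical_score


def expand_node(
    node: CompoundStructure,
    rules: Sequence[ReactionRule],
    params: SearchParams,
) -> list[tuple[ReactionRule, PredictedTransformation]]:
    """All accepted rule applications at a node, deduplicated and ordered.

    Rules outside the admitted diameter window are skipped.  Duplicate
    product sets are collapsed: for the same template the highest-diameter
    (most specific) rule wins, otherwise the highest combined score, ties by
    rule_id.  Output is sorted by descending combined score, then rule_id.
    """
    by_products: dict[frozenset[str], tuple[ReactionRule, PredictedTransformation]] = {}
    for rule in sorted(rules, key=lambda r: r.rule_id):
        if rule.diameter not in params.diameters:
            continue
        for t in apply_rule(rule, node):
            if not score_match(rule, t, params):
                continue
            key = t.product_inchis
            if key in by_products:
                old_rule, old_t = by_products[key]
                if rule.template_reaction_id == old_rule.template_reaction_id:
                    better = rule.diameter > old_rule.diameter
                else:
                    better = _combined_score(rule, t) > _combined_score(
                        old_rule, old_t)
                if not better:
                    continue
            by_products[key] = (rule, t)
    return sorted(
        by_products.values(),
        key=lambda rt: (-_combined_score(*rt), rt[0].rule_id))


def search_biosensor(
    source: str,
    source_structure: CompoundStructure,
    sinks: Mapping[str, str] | set[str],
    rules: Sequence[ReactionRule],
    params: SearchParams,
    templates: Mapping[str, Reaction] | None = None,
    template_structures: Mapping[str, CompoundStructure] | None = None,
) -> Scope:
    """Best-first expansion connecting a source compound to sink metabolites.

    ``sinks`` maps sink InChIs to metabolite ids (a plain set of InChIs also
    works).  Nodes already in the sink set are never expanded, and a node is
    expanded at most once.  The search halts at ``params.itermax``
    iterations, the time budget, or frontier exhaustion, and is fully
    deterministic (the seed is reserved for the optional stochastic mode).

    When ``templates`` (template reactions, by id) and
    ``template_structures`` are supplied, each accepted transformation is
    completed with template co-substrates and atomically balanced into a
    :class:`~phenolnet.network.Reaction`; transformations that cannot be
    balanced are dropped and recorded in ``scope.balance_failures``.
    """
    if source_structure is None:
        raise ValueError(f"source {source!r} lacks a structure")
    sink_inchis = set(sinks.keys()) if isinstance(sinks, Mapping) else set(sinks)
    if not sink_inchis:
        raise ValueError("sink set must be non-empty")
    sink_ids = dict(sinks) if isinstance(sinks, Mapping) else {}

    scope = Scope(source=source, source_structure=source_structure)
    scope.nodes[source_structure.inchi] = source_structure
    if source_structure.inchi in sink_inchis:
        scope.trivially_connected = True
        return scope

    t0 = time.monotonic()
    counter = 0
    # (negative priority, insertion order, inchi, depth)
    frontier: list[tuple[float, int, str, int]] = [
        (-1.0, counter, source_structure.inchi, 0)]
    expanded: set[str] = set()
    n_pred = 0
    while frontier and scope.iterations < params.itermax:
        if time.monotonic() - t0 > params.time_budget:
            break
        _, _, inchi, depth = heapq.heappop(frontier)
        if inchi in expanded or inchi in sink_inchis or depth >= params.max_depth:
            continue
        expanded.add(inchi)
        scope.iterations += 1
        node = scope.nodes[inchi]
        for rule, t in expand_node(node, rules, params):
            reaction = None
            if templates is not None and rule.template_reaction_id in templates:
                substrate_id = (sink_ids.get(inchi)
                                or (source if inchi == source_structure.inchi
                                    else f"pred_{node.inchikey[:14]}"))
                t = PredictedTransformation(
                    rule_id=t.rule_id, substrate=substrate_id,
                    substrate_structure=t.substrate_structure,
                    products=t.products, chemical_score=t.chemical_score)
                product_ids = {
                    p.inchi: sink_ids[p.inchi]
                    for p in t.products if p.inchi in sink_ids}
                try:
                    n_pred += 1
                    reaction = complete_and_balance(
                        t, templates[rule.template_reaction_id],
                        template_structures or {},
                        reaction_id=f"pred_{source}_{n_pred:03d}",
                        product_ids=product_ids, taxa=rule.taxa)
                except BalanceError as exc:
                    scope.balance_failures.append(str(exc))
                    continue
            scope.edges.append(ScopeEdge(t, depth + 1, reaction))
            score = _combined_score(rule, t)
            for p in t.products:
                if p.inchi not in scope.nodes:
                    scope.nodes[p.inchi] = p
                if p.inchi not in expanded and p.inchi not in sink_inchis:
                    counter += 1
                    heapq.heappush(frontier, (-score, counter, p.inchi, depth + 1))
    return scope


def extract_connected_pathways(
    scope: Scope, sinks: Mapping[str, str] | set[str]
) -> tuple[list[PredictedPathway], int]:
    """Linear pathways from the source whose every terminal is a sink.

    Returns ``(connected, n_disconnected)``: maximal chains are enumerated by
    depth-first traversal (one product extended per step, no compound
    revisited on a path); chains with any terminal outside the sink set are
    counted as disconnected, not returned.
    """
    sink_inchis = set(sinks.keys()) if isinstance(sinks, Mapping) else set(sinks)
    connected: list[PredictedPathway] = []
    n_disconnected = 0
    if not scope.edges:
        return connected, n_disconnected

    def emit(chain: list[ScopeEdge]) -> None:
        nonlocal n_disconnected
        consumed = {e.substrate_inchi for e in chain}
        terminals = frozenset(
            p.inchi for e in chain for p in e.transformation.products
        ) - consumed
        pathway = PredictedPathway(
            transformations=tuple(e.transformation for e in chain),
            reactions=tuple(e.reaction for e in chain),
            terminal_set=terminals)
        if terminals <= sink_inchis:
            connected.append(pathway)
        else:
            n_disconnected += 1

    def extend(chain: list[ScopeEdge], backbone: set[str]) -> None:
        # a compound already expanded on this path is not re-expanded
        last_products = {p.inchi for p in chain[-1].transformation.products}
        extensions = [
            e for e in scope.edges
            if e.substrate_inchi in last_products
            and e.substrate_inchi not in sink_inchis
            and e.substrate_inchi not in backbone]
        if not extensions:
            emit(chain)
            return
        for edge in extensions:
            extend(chain + [edge], backbone | {edge.substrate_inchi})

    src = scope.source_structure.inchi
    for edge in scope.edges_from(src):
        extend([edge], {src})
    return connected, n_disconnected
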