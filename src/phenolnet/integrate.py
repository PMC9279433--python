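"""End-to-end network-update pipeline.

Predicted degradation reactions are folded into the base reconstruction by
sequential weighted-FASTCORE gap-filling (one pass per phenolic compound,
core = base reactions plus that compound's predictions), followed by
annotation pruning (non-exchange reactions without taxonomic evidence are
dropped), blocked-reaction elimination to a fixpoint, and a single-species
repair step that resolves per-organism dead ends — adding transport/exchange
machinery only where an evidence table permits it.  A coverage/diff report
compares two network versions per compound sub-class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

from .fluxlp import (CoreInfeasibleError, FluxProblem, GapfillSpec,
                     blocked_reactions, fastcore_weighted)
from .network import MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "GapfillReport", "sequential_gapfill", "prune_and_consistency",
    "single_species_repair", "coverage_and_diff_report",
    "UNANNOTATED_WEIGHT",
]

#: penalty for gap-filling through a reaction without taxonomic annotation
UNANNOTATED_WEIGHT = 100.0
ANNOTATED_WEIGHT = 1.0


def _gapfill_weights(net: MetabolicNetwork) -> dict[str, float]:
    return {
        rid: (ANNOTATED_WEIGHT
              if (r.taxa or r.provenance == "exchange") else UNANNOTATED_WEIGHT)
        for rid, r in net.reactions.items()}


@dataclass
class GapfillReport:
    integrated: list[str] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)  # compound -> reason
    added_reactions: set[str] = field(default_factory=set)


def sequential_gapfill(
    universal: MetabolicNetwork,
    base: MetabolicNetwork,
    predictions: Mapping[str, Iterable[str]],
    weights: Mapping[str, float] | None = None,
) -> tuple[MetabolicNetwork, GapfillReport]:
    """Gap-fill each compound's predicted reactions into the base network.

    ``predictions`` maps compound id to the ids of its predicted reactions,
    which must already be merged into ``universal``; ``base`` must be a
    reaction-subset of ``universal``.  Compounds are processed in sorted
    order; for each, the core is base ∪ that compound's predictions and the
    selected support is accumulated.  Core-infeasible compounds are skipped
    and reported, not fatal.
    """
    missing = set(base.reactions) - set(universal.reactions)
    if missing:
        raise ValueError(
            f"base is not a subset of the universal network: missing "
            f"{sorted(missing)[:5]}")
    for compound, rids in predictions.items():
        unknown = set(rids) - set(universal.reactions)
        if unknown:
            raise ValueError(
                f"predicted reactions for {compound!r} not in universal: "
                f"{sorted(unknown)}")
    problem = FluxProblem.from_network(universal)
    w = dict(weights) if weights is not None else _gapfill_weights(universal)
    report = GapfillReport()
    selected: set[str] = set(base.reactions)
    for compound in sorted(predictions):
        core = set(base.reactions) | set(predictions[compound])
        try:
            chosen = fastcore_weighted(problem, GapfillSpec(core=core, weights=w))
        except CoreInfeasibleError as exc:
            report.skipped[compound] = f"core infeasible: {exc.reaction_id}"
            continue
        report.integrated.append(compound)
        report.added_reactions |= chosen - set(base.reactions)
        selected |= chosen
    return universal.subset(selected), report


def prune_and_consistency(net: MetabolicNetwork) -> MetabolicNetwork:
    """Drop unannotated non-exchange reactions, then blocked reactions, to fixpoint."""
    keep = {
        rid for rid, r in net.reactions.items()
        if r.taxa or r.provenance == "exchange" or len(r.stoichiometry) == 1}
    out = net.subset(keep)
    while True:
        if not out.reactions:
            return out
        blocked = blocked_reactions(FluxProblem.from_network(out))
        if not blocked:
            return out
        out = out.subset(set(out.reactions) - blocked)


# ---------------------------------------------------------------------------
# single-species analysis


def _split_compartment(mid: str) -> tuple[str, str]:
    if mid.endswith("]") and "[" in mid:
        base, _, comp = mid.rpartition("[")
        return base, comp[:-1]
    return mid, ""


def _species_subnetwork(net: MetabolicNetwork, species: str) -> MetabolicNetwork:
    """Reactions annotated to one organism, plus exchanges of its metabolites."""
    rids = {rid for rid, r in net.reactions.items() if species in r.taxa}
    used = {m for rid in rids for m in net.reactions[rid].stoichiometry}
    rids |= {
        rid for rid in net.exchange_reaction_ids()
        if set(net.reactions[rid].stoichiometry) <= used}
    return net.subset(rids) if rids else MetabolicNetwork()


def _dead_end_metabolites(sub: MetabolicNetwork) -> set[str]:
    """Metabolites only producible or only consumable under the bounds."""
    producers: dict[str, int] = {}
    consumers: dict[str, int] = {}
    for r in sub.reactions.values():
        for m, c in r.stoichiometry.items():
            c = Fraction(c)
            can_produce = (c > 0 and r.upper_bound > 0) or (
                c < 0 and r.lower_bound < 0)
            can_consume = (c < 0 and r.upper_bound > 0) or (
                c > 0 and r.lower_bound < 0)
            if can_produce:
                producers[m] = producers.get(m, 0) + 1
            if can_consume:
                consumers[m] = consumers.get(m, 0) + 1
    return {m for m in sub.metabolites
            if bool(producers.get(m)) != bool(consumers.get(m))}


def single_species_repair(
    net: MetabolicNetwork,
    evidence: set[tuple[str, str]],
) -> MetabolicNetwork:
    """Resolve per-organism dead ends; add transports only with evidence.

    For each species' induced sub-network, a dead-end metabolite with
    ``(species, metabolite-base-id)`` in the evidence table gains a
    transport + exchange pair; otherwise the species is removed from the
    annotation of the reactions stranded by that dead end (reactions left
    without any taxa are dropped).  Remaining per-species blocked reactions
    lose that species' annotation, and whole-network consistency is
    re-verified at the end.
    """
    out = net.copy()
    for species in sorted(net.species_catalog):
        sub = _species_subnetwork(out, species)
        if not sub.reactions:
            continue
        for mid in sorted(_dead_end_metabolites(sub)):
            base, comp = _split_compartment(mid)
            if (species, base) in evidence:
                eid = f"{base}[e]"
                if eid not in out.metabolites:
                    src = out.metabolites[mid]
                    out.add_metabolite(Metabolite(
                        id=eid, name=src.name, inchi=src.inchi,
                        smiles=src.smiles, formula=src.formula,
                        compartment="e"))
                tid = f"T_{base}_{species}"
                if tid not in out.reactions:
                    out.add_reaction(Reaction(
                        id=tid, stoichiometry={mid: -1, eid: 1},
                        reversible=True, taxa={species},
                        provenance="transport"))
                ex = f"EX_{base}"
                if ex not in out.reactions:
                    out.add_reaction(Reaction(
                        id=ex, stoichiometry={eid: -1}, reversible=True,
                        provenance="exchange"))
            else:
                # strip this species from the reactions touching the dead end
                for rid in sorted(sub.reactions):
                    r = out.reactions.get(rid)
                    if r is None or species not in r.taxa:
                        continue
                    if mid in r.stoichiometry:
                        _remove_species_annotation(out, rid, species)
        # blocked reactions within the (possibly repaired) species model
        sub = _species_subnetwork(out, species)
        if sub.reactions:
            blocked = blocked_reactions(FluxProblem.from_network(sub))
            for rid in sorted(blocked):
                if species in out.reactions[rid].taxa:
                    _remove_species_annotation(out, rid, species)
    return prune_and_consistency(out)


def _remove_species_annotation(net: MetabolicNetwork, rid: str,
                               species: str) -> None:
    from dataclasses import replace

    r = net.reactions[rid]
    taxa = r.taxa - {species}
    if taxa or r.provenance in ("exchange",):
        net.reactions[rid] = replace(r, taxa=taxa)
    else:
        del net.reactions[rid]


# ---------------------------------------------------------------------------
# version comparison


def coverage_and_diff_report(
    net_old: MetabolicNetwork,
    net_new: MetabolicNetwork,
    compound_classes: Mapping[str, tuple[str, int]],
    species_to_phylum: Mapping[str, str] | None = None,
) -> dict:
    """Added content and per-sub-class catalogue coverage of two versions.

    ``compound_classes`` maps compound id → (sub-class, catalogue size of
    that sub-class).  A compound is covered by a network when a metabolite
    with that base id (compartment suffix stripped) is present.  The
    percentage-point coverage difference per sub-class is
    ``round((covered_new − covered_old) / catalogue_size × 100)``.
    Compounds whose sub-class is unknown count under ``"unclassified"``.
    """
    def base_ids(net: MetabolicNetwork) -> set[str]:
        return {_split_compartment(m)[0] for m in net.metabolites}

    old_ids, new_ids = base_ids(net_old), base_ids(net_new)
    classes: dict[str, dict] = {}
    for compound, entry in compound_classes.items():
        if isinstance(entry, tuple):
            subclass, total = entry
        else:
            subclass, total = "unclassified", 0
        rec = classes.setdefault(
            subclass, {"catalogue_size": 0, "covered_old": 0, "covered_new": 0})
        rec["catalogue_size"] = max(rec["catalogue_size"], int(total))
        if compound in old_ids:
            rec["covered_old"] += 1
        if compound in new_ids:
            rec["covered_new"] += 1
    for rec in classes.values():
        total = rec["catalogue_size"] or max(
            rec["covered_new"], rec["covered_old"], 1)
        rec["coverage_diff_pct"] = round(
            (rec["covered_new"] - rec["covered_old"]) / total * 100)

    added_rxns = set(net_new.reactions) - set(net_old.reactions)
    phylum_counts: dict[str, int] = {}
    lookup = species_to_phylum or {}
    for rid in added_rxns:
        for ph in {lookup.get(s, "unclassified")
                   for s in net_new.reactions[rid].taxa}:
            phylum_counts[ph] = phylum_counts.get(ph, 0) + 1
    return {
        "added_metabolites": sorted(set(net_new.metabolites)
                                    - set(net_old.metabolites)),
        "added_reactions": sorted(added_rxns),
        "n_added_metabolites": len(set(net_new.metabolites)
                                   - set(net_old.metabolites)),
        "n_added_reactions": len(added_rxns),
        "by_subclass": classes,
        "added_reactions_by_phylum": phylum_counts,
    }
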