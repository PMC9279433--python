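"""Core metabolic-network data model.

A :class:`MetabolicNetwork` holds metabolites, stoichiometric reactions and a
species catalogue.  The universal reaction database, the base gut-microbiota
reconstruction and every extended network produced by the pipeline are all
instances of this one class; the stoichiometric matrix ``S`` (metabolites ×
reactions) is derivable from it without loss.

Metabolite identity across databases is keyed on the standard InChI string
when present (structure beats name or id), falling back to the raw id.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "ValidationError",
    "PROVENANCES",
    "filter_universal",
    "merge_with_dedup",
    "summarize",
]

PROVENANCES = ("annotated", "predicted", "gapfilled", "exchange", "transport")

#: conventional large finite flux cap (mmol/gDW/h scale) keeping LPs bounded
DEFAULT_FLUX_CAP = 1000.0


class ValidationError(ValueError):
    """A network or one of its components violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    inchi: str | None = None
    smiles: str | None = None
    formula: Mapping[str, int] | None = None
    compartment: str = "c"

    def __post_init__(self) -> None:
        if self.formula is not None:
            bad = {e: n for e, n in self.formula.items()
                   if not (isinstance(n, int) and n >= 0)}
            if bad:
                raise ValidationError(
                    f"metabolite {self.id!r}: formula counts must be "
                    f"nonnegative integers, got {bad}")

    @property
    def identity_key(self) -> str:
        """InChI when available (structural identity), else the id."""
        return self.inchi if self.inchi else self.id


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, Fraction | int | float]
    reversible: bool = False
    lower_bound: float | None = None
    upper_bound: float | None = None
    taxa: frozenset[str] = frozenset()
    ec_numbers: frozenset[str] = frozenset()
    provenance: str = "annotated"

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.provenance not in PROVENANCES:
            raise ValidationError(
                f"reaction {self.id!r}: unknown provenance {self.provenance!r}")
        object.__setattr__(self, "taxa", frozenset(self.taxa))
        object.__setattr__(self, "ec_numbers", frozenset(self.ec_numbers))
        lb = self.lower_bound if self.lower_bound is not None else (
            -DEFAULT_FLUX_CAP if self.reversible else 0.0)
        ub = self.upper_bound if self.upper_bound is not None else DEFAULT_FLUX_CAP
        object.__setattr__(self, "lower_bound", float(lb))
        object.__setattr__(self, "upper_bound", float(ub))
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}")
        if self.reversible != (self.lower_bound < 0):
            raise ValidationError(
                f"reaction {self.id!r}: reversible flag ({self.reversible}) "
                f"inconsistent with lower bound {self.lower_bound}")

    @property
    def substrates(self) -> dict[str, Fraction]:
        return {m: -Fraction(c) for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {m: Fraction(c) for m, c in self.stoichiometry.items() if c > 0}

    def canonical_stoichiometry(
        self, identity: Mapping[str, str] | None = None
    ) -> tuple[tuple[str, Fraction], ...]:
        """Sorted (metabolite-key, coefficient) pairs; the duplicate-reaction key.

        ``identity`` optionally remaps metabolite ids (e.g. to InChI keys) so
        that the same chemistry written over different id vocabularies
        compares equal.
        """
        items = {}
        for m, c in self.stoichiometry.items():
            key = identity.get(m, m) if identity else m
            items[key] = items.get(key, Fraction(0)) + Fraction(c)
        return tuple(sorted((k, v) for k, v in items.items() if v != 0))


class MetabolicNetwork:
    """Metabolites + reactions + species catalogue, with validation."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        species_catalog: Iterable[str] = (),
    ) -> None:
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.species_catalog: set[str] = set(species_catalog)
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, m: Metabolite) -> None:
        if m.id in self.metabolites:
            raise ValidationError(f"duplicate metabolite id {m.id!r}")
        self.metabolites[m.id] = m

    def add_reaction(self, r: Reaction) -> None:
        if r.id in self.reactions:
            raise ValidationError(f"duplicate reaction id {r.id!r}")
        missing = set(r.stoichiometry) - set(self.metabolites)
        if missing:
            raise ValidationError(
                f"reaction {r.id!r} references undeclared metabolites: "
                f"{sorted(missing)}")
        self.reactions[r.id] = r
        self.species_catalog |= r.taxa

    def copy(self) -> "MetabolicNetwork":
        net = MetabolicNetwork()
        net.metabolites = dict(self.metabolites)
        net.reactions = dict(self.reactions)
        net.species_catalog = set(self.species_catalog)
        return net

    def subset(self, reaction_ids: Iterable[str]) -> "MetabolicNetwork":
        """Sub-network induced by ``reaction_ids`` (metabolites restricted)."""
        rids = set(reaction_ids)
        unknown = rids - set(self.reactions)
        if unknown:
            raise ValidationError(f"unknown reaction ids: {sorted(unknown)}")
        used = {m for rid in rids for m in self.reactions[rid].stoichiometry}
        net = MetabolicNetwork()
        net.metabolites = {m: self.metabolites[m] for m in used}
        net.reactions = {rid: self.reactions[rid] for rid in sorted(rids)}
        net.species_catalog = set(self.species_catalog)
        return net

    # -- views ------------------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return sorted(self.metabolites)

    def reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S (metabolites × reactions) plus row and column labels."""
        mets = self.metabolite_ids()
        rxns = self.reaction_ids()
        mindex = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rxns)))
        for j, rid in enumerate(rxns):
            for m, c in self.reactions[rid].stoichiometry.items():
                S[mindex[m], j] = float(c)
        return S, mets, rxns

    def exchange_reaction_ids(self) -> list[str]:
        """Single-metabolite boundary reactions (uptake/secretion)."""
        return sorted(
            rid for rid, r in self.reactions.items()
            if len(r.stoichiometry) == 1)

    def validate(self) -> None:
        for r in self.reactions.values():
            missing = set(r.stoichiometry) - set(self.metabolites)
            if missing:
                raise ValidationError(
                    f"reaction {r.id!r} references undeclared metabolites: "
                    f"{sorted(missing)}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (self.metabolites == other.metabolites
                and self.reactions == other.reactions
                and self.species_catalog == other.species_catalog)

    def __repr__(self) -> str:
        return (f"MetabolicNetwork({len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions, "
                f"{len(self.species_catalog)} species)")


# ---------------------------------------------------------------------------
# universal-database construction


def filter_universal(
    net: MetabolicNetwork, allowed_taxa: set[str]
) -> MetabolicNetwork:
    """Restrict a universal database to structurally usable, taxon-backed reactions.

    Keeps exactly the reactions with at least one taxon in ``allowed_taxa``
    whose participating metabolites all carry an InChI; metabolites are
    restricted to those still used.  Idempotent.
    """
    if not allowed_taxa:
        raise ValueError("allowed_taxa must be non-empty")
    keep = [
        r for r in net.reactions.values()
        if (r.taxa & allowed_taxa)
        and all(net.metabolites[m].inchi for m in r.stoichiometry)
    ]
    out = MetabolicNetwork()
    used = {m for r in keep for m in r.stoichiometry}
    out.metabolites = {m: net.metabolites[m] for m in used}
    out.reactions = {r.id: r for r in keep}
    out.species_catalog = set(net.species_catalog)
    return out


@dataclass
class MergeConflict:
    identity_key: str
    ids: tuple[str, str]
    detail: str


def merge_with_dedup(
    a: MetabolicNetwork, b: MetabolicNetwork
) -> tuple[MetabolicNetwork, list[MergeConflict]]:
    """Merge two networks, identifying metabolites by InChI and deduplicating reactions.

    Metabolites sharing a canonical InChI collapse to one record (first-seen id
    wins; structure wins over formula on conflict, which is reported).
    Reactions with identical canonical stoichiometry over merged identities and
    the same directionality collapse, unioning taxa and EC sets.
    """
    conflicts: list[MergeConflict] = []
    merged = MetabolicNetwork()
    # identity key -> surviving metabolite id
    key_to_id: dict[str, str] = {}
    id_map: dict[tuple[int, str], str] = {}  # (which net, original id) -> merged id

    for tag, net in ((0, a), (1, b)):
        for mid in sorted(net.metabolites):
            m = net.metabolites[mid]
            key = m.identity_key
            if key in key_to_id:
                kept = merged.metabolites[key_to_id[key]]
                if (m.formula and kept.formula
                        and dict(m.formula) != dict(kept.formula)):
                    conflicts.append(MergeConflict(
                        key, (kept.id, m.id),
                        f"conflicting formulas {dict(kept.formula)} vs "
                        f"{dict(m.formula)}; structure wins"))
                id_map[(tag, mid)] = key_to_id[key]
            else:
                if m.id in merged.metabolites:
                    # same id, different structure: keep both, disambiguate
                    new_id = f"{m.id}__{tag}"
                    m = replace(m, id=new_id)
                merged.add_metabolite(m)
                key_to_id[key] = m.id
                id_map[(tag, mid)] = m.id

    # reaction dedup key: canonical stoichiometry over merged ids + direction
    seen: dict[tuple, str] = {}
    for tag, net in ((0, a), (1, b)):
        for rid in sorted(net.reactions):
            r = net.reactions[rid]
            remap = {m: id_map[(tag, m)] for m in r.stoichiometry}
            stoich = {}
            for m, c in r.stoichiometry.items():
                mm = remap[m]
                stoich[mm] = stoich.get(mm, Fraction(0)) + Fraction(c)
            stoich = {m: c for m, c in stoich.items() if c != 0}
            if not stoich:
                continue
            key = (tuple(sorted(stoich.items())), r.reversible)
            if key in seen:
                old = merged.reactions[seen[key]]
                merged.reactions[seen[key]] = replace(
                    old, taxa=old.taxa | r.taxa,
                    ec_numbers=old.ec_numbers | r.ec_numbers)
            else:
                new_id = rid if rid not in merged.reactions else f"{rid}__{tag}"
                merged.add_reaction(replace(r, id=new_id, stoichiometry=stoich))
                seen[key] = new_id
    merged.species_catalog |= a.species_catalog | b.species_catalog
    return merged, conflicts


def summarize(
    net: MetabolicNetwork,
    species_to_phylum: Mapping[str, str] | None = None,
) -> dict:
    """Counts of metabolites and reactions, by provenance and by phylum.

    Species missing from the lookup are counted under ``"unclassified"``.
    Phylum counts are reaction counts: a reaction annotated to species of two
    phyla contributes to both.
    """
    by_provenance = Counter(r.provenance for r in net.reactions.values())
    by_phylum: Counter[str] = Counter()
    lookup = species_to_phylum or {}
    for r in net.reactions.values():
        phyla = {lookup.get(s, "unclassified") for s in r.taxa}
        by_phylum.update(phyla)
    return {
        "n_metabolites": len(net.metabolites),
        "n_reactions": len(net.reactions),
        "n_species": len(net.species_catalog),
        "by_provenance": dict(by_provenance),
        "by_phylum": dict(by_phylum),
    }
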