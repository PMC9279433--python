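"""Synthetic inputs with planted ground truth.

The generator emulates every input the pipeline consumes: a universal
reaction database with taxonomy and real chemical structures, hidden
degradation pathways for novel source compounds together with a rule table
derived from structurally analogous annotated reactions, food/sample
contexts, and presence/absence metabolomics calls with stated sensitivity
and specificity.

Chemistry is drawn from a small curated library of phenolic-like scaffolds
(benzoic and cinnamic acid derivatives, simple phenols) decorated
systematically with the conjugations gut bacteria actually remove —
O-glycosides, O-glucuronides and O-methyl ethers — so that the hydrolysis /
demethylation rules have realistic match semantics.  Every metabolite
carries a valid structure; every annotated degradation reaction is
elementally balanced by construction.

A single global seed fans out to per-component seeds through
``numpy.random.default_rng(seed).spawn``-style splitting (documented in the
methods note), so each artifact is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import (CompoundStructure, ReactionRule, chemical_similarity,
                   standardize_structure)
from .network import Metabolite, MetabolicNetwork, Reaction

__all__ = [
    "PlantedTruth", "GenerationError", "CommunityContext",
    "generate_universe", "plant_pathways", "extended_universal",
    "simulate_metabolomics",
    "generate_contexts", "structures_of", "species_phylum_map",
    "SCAFFOLDS", "DECORATIONS",
]


class GenerationError(ValueError):
    """Generator parameters too small to build a consistent network."""


# curated phenolic-like scaffold library (id -> SMILES); all neutral acids
SCAFFOLDS: dict[str, str] = {
    "phenol": "Oc1ccccc1",
    "catechol": "Oc1ccccc1O",
    "resorcinol": "Oc1cccc(O)c1",
    "hydroquinone": "Oc1ccc(O)cc1",
    "phloroglucinol": "Oc1cc(O)cc(O)c1",
    "4_hydroxybenzoate": "O=C(O)c1ccc(O)cc1",
    "protocatechuate": "O=C(O)c1ccc(O)c(O)c1",
    "gallate": "O=C(O)c1cc(O)c(O)c(O)c1",
    "p_coumarate": "O=C(O)C=Cc1ccc(O)cc1",
    "caffeate": "O=C(O)C=Cc1ccc(O)c(O)c1",
}

#: decoration type -> (decoration SMARTS, degradation rule SMARTS,
#:                     released small molecule id, its SMILES, EC class)
DECORATIONS: dict[str, tuple[str, str, str, str, str]] = {
    "glucoside": (
        "[c:1][OH:2]>>[c:1][O:2]C1OC(CO)C(O)C(O)C1O",
        "[c:1][O:2][CH:3]1[O:4][CH:5]([CH2:6][OH:7])[CH:8]([OH:9])"
        "[CH:10]([OH:11])[CH:12]1[OH:13]"
        ">>[c:1][OH:2].[OH][CH:3]1[O:4][CH:5]([CH2:6][OH:7])[CH:8]([OH:9])"
        "[CH:10]([OH:11])[CH:12]1[OH:13]",
        "glucose", "OCC1OC(O)C(O)C(O)C1O", "3.2.1.21"),
    "glucuronide": (
        "[c:1][OH:2]>>[c:1][O:2]C1OC(C(=O)O)C(O)C(O)C1O",
        "[c:1][O:2][CH:3]1[O:4][CH:5]([C:6](=[O:7])[OH:8])[CH:9]([OH:10])"
        "[CH:11]([OH:12])[CH:13]1[OH:14]"
        ">>[c:1][OH:2].[OH][CH:3]1[O:4][CH:5]([C:6](=[O:7])[OH:8])"
        "[CH:9]([OH:10])[CH:11]([OH:12])[CH:13]1[OH:14]",
        "glucuronate", "OC(=O)C1OC(O)C(O)C(O)C1O", "3.2.1.31"),
    "methyl": (
        "[c:1][OH:2]>>[c:1][O:2]C",
        "[c:1][O:2][CH3:3]>>[c:1][OH:2].[OH][CH3:3]",
        "methanol", "CO", "2.1.1.-"),
}

_WATER_SMILES = "O"

#: minimum query-to-template fingerprint similarity a planted chain step may
#: have; matches the permissive chemical cutoff under which the planted rules
#: are guaranteed rediscoverable
ADMISSIBLE_SIMILARITY = 0.2


def species_phylum_map(species: Iterable[str]) -> dict[str, str]:
    """Round-robin assignment of species to the four major gut phyla."""
    phyla = ["Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria"]
    return {s: phyla[i % 4] for i, s in enumerate(sorted(species))}


def _decorate(smiles: str, decoration: str, site: int = 0) -> str | None:
    """Attach a decoration at the ``site``-th free aromatic OH; None if no site."""
    rxn = AllChem.ReactionFromSmarts(DECORATIONS[decoration][0])
    mol = Chem.MolFromSmiles(smiles)
    products = rxn.RunReactants((mol,))
    uniq: list[str] = []
    for (p,) in products:
        try:
            Chem.SanitizeMol(p)
        except Exception:
            continue
        smi = Chem.MolToSmiles(p)
        if smi not in uniq:
            uniq.append(smi)
    if site < len(uniq):
        return uniq[site]
    return None


def structures_of(net: MetabolicNetwork) -> dict[str, CompoundStructure]:
    """CompoundStructure lookup for every structured metabolite of a network."""
    out: dict[str, CompoundStructure] = {}
    for mid, m in net.metabolites.items():
        if m.smiles:
            out[mid] = standardize_structure(mid, smiles=m.smiles)
        elif m.inchi:
            out[mid] = standardize_structure(mid, inchi=m.inchi)
    return out


def _met(mid: str, smiles: str, compartment: str) -> Metabolite:
    s = standardize_structure(mid, smiles=smiles)
    return Metabolite(id=f"{mid}[{compartment}]", name=mid, inchi=s.inchi,
                      smiles=s.smiles, formula=dict(s.formula),
                      compartment=compartment)


@dataclass
class _ChainStep:
    """Bookkeeping for one annotated degradation reaction in the universe."""

    reaction_id: str
    decoration: str
    substrate_smiles: str
    product_smiles: str
    taxa: frozenset[str]


def generate_universe(
    n_species: int,
    n_metabolites: int,
    connectivity: float = 0.3,
    seed: int = 0,
) -> MetabolicNetwork:
    """Flux-consistent toy universal database with taxonomy and structures.

    Phenolic scaffolds are conjugated (glucosides, glucuronides, methyl
    ethers) and each conjugate gets an annotated, balanced hydrolysis /
    demethylation reaction back to its scaffold, plus uptake/secretion
    machinery (transport + exchange).  ``connectivity`` is the probability
    that a conjugate is decorated a second time, yielding depth-2 annotated
    chains.  Reaction taxa are drawn over ``s1..s<n_species>``.
    """
    if n_species < 1 or n_metabolites < 4:
        raise GenerationError("need n_species >= 1 and n_metabolites >= 4")
    rng = np.random.default_rng(seed)
    species = [f"s{i + 1}" for i in range(n_species)]
    net = MetabolicNetwork(species_catalog=species)
    chain_steps: list[_ChainStep] = []

    def add_compound(mid: str, smiles: str,
                     exchange: bool = True) -> None:
        """[c] + [e] metabolites, a transport open to every species, an exchange.

        Uptake/export is modelled as generic (all species can transport);
        catalysis below is species-specific.  This keeps every organism's
        sub-model free of trivial dead ends by construction.
        """
        if f"{mid}[c]" in net.metabolites:
            return
        net.add_metabolite(_met(mid, smiles, "c"))
        net.add_metabolite(_met(mid, smiles, "e"))
        net.add_reaction(Reaction(
            id=f"T_{mid}", stoichiometry={f"{mid}[e]": -1, f"{mid}[c]": 1},
            reversible=True, taxa=all_taxa, provenance="transport"))
        if exchange:
            net.add_reaction(Reaction(
                id=f"EX_{mid}", stoichiometry={f"{mid}[e]": -1},
                reversible=True, provenance="exchange"))

    all_taxa = frozenset(species)
    add_compound("water", _WATER_SMILES)
    for _, (_, _, small_id, small_smiles, _) in sorted(DECORATIONS.items()):
        add_compound(small_id, small_smiles)

    def pick_taxa() -> frozenset[str]:
        k = int(rng.integers(1, n_species + 1))
        return frozenset(rng.choice(species, size=k, replace=False).tolist())

    scaffold_ids = sorted(SCAFFOLDS)
    deco_ids = sorted(DECORATIONS)
    i = 0
    while len(net.metabolites) < n_metabolites:
        scaffold = scaffold_ids[i % len(scaffold_ids)]
        if i >= 3 * len(scaffold_ids):  # library exhausted
            break
        add_compound(scaffold, SCAFFOLDS[scaffold])
        deco = deco_ids[int(rng.integers(len(deco_ids)))]
        dec_smiles = _decorate(SCAFFOLDS[scaffold], deco, site=(i // len(scaffold_ids)))
        i += 1
        if dec_smiles is None:
            continue
        dec_id = f"{scaffold}_{deco}{(i - 1) // len(scaffold_ids) or ''}"
        if f"{dec_id}[c]" in net.metabolites:
            continue
        taxa = pick_taxa()
        add_compound(dec_id, dec_smiles)
        _, _, small_id, _, ec = DECORATIONS[deco]
        rid = f"R_{dec_id}_hydrolysis"
        net.add_reaction(Reaction(
            id=rid,
            stoichiometry={f"{dec_id}[c]": -1, "water[c]": -1,
                           f"{scaffold}[c]": 1, f"{small_id}[c]": 1},
            reversible=False, taxa=taxa, ec_numbers={ec},
            provenance="annotated"))
        chain_steps.append(_ChainStep(rid, deco, dec_smiles,
                                      SCAFFOLDS[scaffold], taxa))
        # occasional second conjugation -> depth-2 annotated chain
        if rng.random() < connectivity:
            deco2 = deco_ids[int(rng.integers(len(deco_ids)))]
            dec2_smiles = _decorate(dec_smiles, deco2)
            if dec2_smiles is not None:
                dec2_id = f"{dec_id}_{deco2}"
                if f"{dec2_id}[c]" not in net.metabolites:
                    taxa2 = pick_taxa()
                    add_compound(dec2_id, dec2_smiles)
                    _, _, small2, _, ec2 = DECORATIONS[deco2]
                    rid2 = f"R_{dec2_id}_hydrolysis"
                    net.add_reaction(Reaction(
                        id=rid2,
                        stoichiometry={f"{dec2_id}[c]": -1, "water[c]": -1,
                                       f"{dec_id}[c]": 1, f"{small2}[c]": 1},
                        reversible=False, taxa=taxa2, ec_numbers={ec2},
                        provenance="annotated"))
                    chain_steps.append(_ChainStep(
                        rid2, deco2, dec2_smiles, dec_smiles, taxa2))
    if not chain_steps:
        raise GenerationError(
            "parameters too small to plant any annotated degradation chain")
    net._chain_steps = chain_steps  # consumed by plant_pathways
    net.validate()
    return net


@dataclass
class PlantedTruth:
    """Ground truth for hidden degradation pathways planted next to a universe."""

    sources: dict[str, CompoundStructure]
    hidden_reactions: dict[str, tuple[Reaction, ...]]
    hidden_metabolites: dict[str, Metabolite]
    support_reactions: dict[str, tuple[Reaction, ...]]  # exchange/transport per source
    rules: list[ReactionRule]
    templates: dict[str, Reaction]
    template_structures: dict[str, CompoundStructure]
    #: per source, the ordered (substrate InChI, product InChI set) steps
    steps: dict[str, tuple[tuple[str, frozenset[str]], ...]]


def plant_pathways(
    universe: MetabolicNetwork,
    n_sources: int,
    depth: int,
    seed: int = 0,
) -> PlantedTruth:
    """Plant hidden degradation chains and derive rules from analog reactions.

    Each source is an existing universe compound conjugated ``depth`` more
    times; the hidden chain of hydrolysis/demethylation reactions leading
    back into the universe is recorded but NOT added to the universe.  The
    rule table holds SMARTS rules generalized from annotated universe
    reactions of the same transformation type (different scaffold), at
    diameters 6–16, so the biosensor search can rediscover the chains.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    chain_steps: list[_ChainStep] = getattr(universe, "_chain_steps", [])
    if not chain_steps:
        raise GenerationError("universe carries no annotated chain templates")

    # rule table: one rule per (decoration type, diameter), template = an
    # annotated universe reaction of that type
    rules: list[ReactionRule] = []
    templates: dict[str, Reaction] = {}
    by_deco: dict[str, _ChainStep] = {}
    for step in chain_steps:
        by_deco.setdefault(step.decoration, step)
    for deco in sorted(by_deco):
        step = by_deco[deco]
        templates[step.reaction_id] = universe.reactions[step.reaction_id]
        for diameter in (6, 8, 10, 12, 14, 16):
            rules.append(ReactionRule(
                rule_id=f"rule_{deco}_d{diameter}",
                smarts=DECORATIONS[deco][1],
                diameter=diameter,
                biological_score=float(np.round(rng.uniform(0.5, 0.95), 3)),
                template_reaction_id=step.reaction_id,
                taxa=step.taxa,
                template_substrate=step.substrate_smiles))

    structures = structures_of(universe)
    universe_inchis = {s.inchi for s in structures.values()}
    # anchors: [c] compounds with a free aromatic OH (so decoration can apply)
    anchors = sorted(
        mid for mid, m in universe.metabolites.items()
        if m.compartment == "c" and m.smiles
        and Chem.MolFromSmiles(m.smiles).HasSubstructMatch(
            Chem.MolFromSmarts("[c][OH]")))
    if not anchors:
        raise GenerationError("universe has no decoratable anchor compounds")

    truth = PlantedTruth({}, {}, {}, {}, rules, templates,
                         dict(structures), {})
    deco_ids = sorted(by_deco)  # only types with an analog rule available
    made = 0
    attempts = 0
    while made < n_sources and attempts < 200 * n_sources:
        attempts += 1
        anchor = anchors[int(rng.integers(len(anchors)))]
        smiles = universe.metabolites[anchor].smiles
        chain_smiles = [smiles]
        decos: list[str] = []
        for _ in range(depth):
            deco = deco_ids[int(rng.integers(len(deco_ids)))]
            nxt = _decorate(chain_smiles[-1], deco)
            if nxt is None:
                break
            chain_smiles.append(nxt)
            decos.append(deco)
        if len(decos) < depth:
            continue
        # at least one species must be competent for the entire hidden chain,
        # otherwise the single-species repair would legitimately disconnect it
        common_taxa = frozenset.intersection(
            *(by_deco[d].taxa for d in decos))
        if not common_taxa:
            continue
        # every chain substrate must resemble its analog rule's template
        # closely enough for the search to rediscover the step (the rule
        # table is contractually rediscoverable at the permissive cutoff)
        admissible = True
        for j in range(depth):
            deco = decos[depth - 1 - j]
            template = standardize_structure(
                "tmpl", smiles=by_deco[deco].substrate_smiles)
            query = standardize_structure(
                "qry", smiles=chain_smiles[depth - j])
            if chemical_similarity(query, template) < ADMISSIBLE_SIMILARITY:
                admissible = False
                break
        if not admissible:
            continue
        # the source and every intermediate must be genuinely novel compounds
        level_structs = [standardize_structure(f"cand_{made}_{j}", smiles=s)
                         for j, s in enumerate(chain_smiles[1:])]
        if any(s.inchi in universe_inchis for s in level_structs):
            continue
        if len({s.inchi for s in level_structs}) < len(level_structs):
            continue
        src_struct = level_structs[-1]
        sid = f"psrc_{made + 1}"
        mets: dict[str, Metabolite] = {}
        hidden: list[Reaction] = []
        steps: list[tuple[str, frozenset[str]]] = []
        # intermediate ids: psrc_k itself, then psrc_k_i1.., anchor at the end
        level_ids = [f"{sid}_i{j}" for j in range(depth - 1, 0, -1)]
        ids = [sid] + level_ids + [anchor.rsplit("[", 1)[0]]
        for j, mid in enumerate(ids[:-1]):
            s = standardize_structure(mid, smiles=chain_smiles[depth - j])
            mets[f"{mid}[c]"] = Metabolite(
                id=f"{mid}[c]", name=mid, inchi=s.inchi, smiles=s.smiles,
                formula=dict(s.formula), compartment="c")
        for j in range(depth):
            deco = decos[depth - 1 - j]  # outermost conjugation removed first
            sub_id, prod_id = ids[j], ids[j + 1]
            small = DECORATIONS[deco][2]
            analog = by_deco[deco]
            prod_cid = (f"{prod_id}[c]")
            hidden.append(Reaction(
                id=f"hid_{sid}_{j + 1}",
                stoichiometry={f"{sub_id}[c]": -1, "water[c]": -1,
                               prod_cid: 1, f"{small}[c]": 1},
                reversible=False, taxa=analog.taxa, provenance="predicted"))
            sub_struct = standardize_structure(
                sub_id, smiles=chain_smiles[depth - j])
            prod_struct = standardize_structure(
                prod_id, smiles=chain_smiles[depth - j - 1])
            small_struct = structures[f"{small}[c]"]
            steps.append((sub_struct.inchi,
                          frozenset({prod_struct.inchi, small_struct.inchi})))
        # uptake machinery for the new source so gap-filling can feed it
        s_e = standardize_structure(sid, smiles=chain_smiles[-1])
        mets[f"{sid}[e]"] = Metabolite(
            id=f"{sid}[e]", name=sid, inchi=s_e.inchi, smiles=s_e.smiles,
            formula=dict(s_e.formula), compartment="e")
        support = (
            Reaction(id=f"EX_{sid}", stoichiometry={f"{sid}[e]": -1},
                     reversible=True, provenance="exchange"),
            Reaction(id=f"T_{sid}",
                     stoichiometry={f"{sid}[e]": -1, f"{sid}[c]": 1},
                     reversible=True,
                     taxa=frozenset(universe.species_catalog),
                     provenance="transport"),
        )
        truth.sources[sid] = src_struct
        truth.hidden_reactions[sid] = tuple(hidden)
        truth.hidden_metabolites.update(mets)
        truth.support_reactions[sid] = support
        truth.steps[sid] = tuple(steps)
        made += 1
    if made < n_sources:
        raise GenerationError(
            f"could only plant {made} of {n_sources} requested pathways")
    return truth


def extended_universal(universe: MetabolicNetwork,
                       truth: PlantedTruth) -> MetabolicNetwork:
    """Universe plus planted predictions — the gap-filling universal database."""
    ext = universe.copy()
    for mid in sorted(truth.hidden_metabolites):
        if mid not in ext.metabolites:
            ext.add_metabolite(truth.hidden_metabolites[mid])
    for sid in sorted(truth.hidden_reactions):
        for r in truth.hidden_reactions[sid] + truth.support_reactions[sid]:
            if r.id not in ext.reactions:
                ext.add_reaction(r)
    return ext


@dataclass(frozen=True)
class CommunityContext:
    """A food's input compounds plus a sample's species-presence vector."""

    context_id: str
    input_compounds: frozenset[str]
    present_species: frozenset[str]


def generate_contexts(
    universe: MetabolicNetwork,
    n_contexts: int,
    seed: int = 0,
    extra_inputs: Iterable[str] = (),
    ensure_one_of: Iterable[str] = (),
    species_presence: float = 0.8,
    food_size: int = 3,
) -> list[CommunityContext]:
    """Random dietary/microbial contexts over a universe's uptake-able compounds.

    Input compounds are drawn from the universe's exchanged metabolites
    (plus ``extra_inputs``, e.g. planted sources); each species is present
    independently with probability ``species_presence``, mirroring 16S
    presence/absence profiles.  When ``ensure_one_of`` is given, every food
    contains at least one compound from that set — the selection rule used
    when restricting a food table to foods touched by newly added compounds.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    # candidate dietary inputs: exchanged conjugates (not water / small byproducts)
    basics = {"water", "glucose", "glucuronate", "methanol"}
    candidates = sorted(
        {rid[3:] for rid in universe.exchange_reaction_ids()
         if rid.startswith("EX_")} - basics) + sorted(extra_inputs)
    required = sorted(set(ensure_one_of))
    species = sorted(universe.species_catalog)
    out: list[CommunityContext] = []
    for k in range(n_contexts):
        size = min(food_size, len(candidates))
        foods = rng.choice(candidates, size=size, replace=False).tolist()
        if required and not set(foods) & set(required):
            foods[0] = required[int(rng.integers(len(required)))]
        present = [s for s in species if rng.random() < species_presence]
        if not present:
            present = [species[int(rng.integers(len(species)))]]
        out.append(CommunityContext(
            context_id=f"ctx_{k + 1}",
            input_compounds=frozenset(foods) | {"water"},
            present_species=frozenset(present)))
    return out


def simulate_metabolomics(
    true_outputs: Mapping[str, set[str]],
    sensitivity: float,
    specificity: float,
    universe: Sequence[str],
    seed: int = 0,
) -> dict[str, set[str]]:
    """Presence/absence calls per sample with stated sensitivity/specificity.

    Each true output is called present with probability ``sensitivity``;
    each non-output with probability ``1 - specificity``.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("rates must be in [0,1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    mets = sorted(universe)
    calls: dict[str, set[str]] = {}
    for sample in sorted(true_outputs):
        truth = true_outputs[sample]
        present: set[str] = set()
        for m in mets:
            p = sensitivity if m in truth else 1.0 - specificity
            if rng.random() < p:
                present.add(m)
        calls[sample] = present
    return calls
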