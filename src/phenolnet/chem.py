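"""Structure handling and reaction-rule machinery.

Enzyme promiscuity is exercised here: a :class:`ReactionRule` is a generic
SMARTS transformation distilled from an annotated reaction, applicable to
substrates the enzyme was never annotated with.  Applying a rule yields
mono-substrate :class:`PredictedTransformation` records; these are then
completed with the co-substrates of the rule's template reaction and balanced
at the atomic level (integer stoichiometry, zero residual for every element
and for net charge) to become proper :class:`~phenolnet.network.Reaction`
objects.

Chemical plausibility of a rule application is scored by the Tanimoto
similarity of radius-2 circular (Morgan) fingerprints, 2048 bits, between the
query substrate and the rule's template substrate — self-similarity is 1, so
a rule always accepts its own template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, DataStructs, rdFingerprintGenerator
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds as _Bounds

from .network import Reaction

RDLogger.DisableLog("rdApp.warning")
RDLogger.DisableLog("rdApp.info")

__all__ = [
    "CompoundStructure", "ReactionRule", "PredictedTransformation",
    "StructureError", "RuleError", "BalanceError",
    "standardize_structure", "apply_rule", "chemical_similarity",
    "score_match", "complete_and_balance",
]


class StructureError(ValueError):
    """A compound record could not be parsed into a structure."""


class RuleError(ValueError):
    """A rule's SMARTS failed to compile."""


class BalanceError(ValueError):
    """No nonnegative integer stoichiometry closes the elemental balance."""


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass(frozen=True)
class CompoundStructure:
    """A standardized compound: canonical InChI plus derived descriptors."""

    inchi: str
    smiles: str | None = None
    formula: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    @property
    def inchikey(self) -> str:
        return Chem.InchiToInchiKey(self.inchi)

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromInchi(self.inchi)
        if m is None:  # pragma: no cover - inchi was produced by RDKit
            raise StructureError(f"cannot rebuild molecule from {self.inchi!r}")
        return m


@dataclass(frozen=True)
class ReactionRule:
    """Generic SMARTS transformation with provenance back to a template reaction.

    ``diameter`` is the atom-environment radius around the reaction centre
    used when the rule was generalized: larger diameter means a more specific
    rule.  ``biological_score`` in [0,1] comes from the rule table as given.
    """

    rule_id: str
    smarts: str
    diameter: int
    biological_score: float
    template_reaction_id: str
    taxa: frozenset[str] = frozenset()
    template_substrate: str | None = None  # SMILES or InChI of template substrate

    def __post_init__(self) -> None:
        if not 0.0 <= self.biological_score <= 1.0:
            raise ValueError(
                f"rule {self.rule_id!r}: biological_score must be in [0,1]")
        object.__setattr__(self, "taxa", frozenset(self.taxa))

    def rdkit_reaction(self) -> AllChem.ChemicalReaction:
        try:
            rxn = AllChem.ReactionFromSmarts(self.smarts)
        except ValueError as exc:
            raise RuleError(
                f"rule {self.rule_id!r}: SMARTS failed to compile: "
                f"{self.smarts!r}") from exc
        if rxn is None or rxn.GetNumReactantTemplates() != 1:
            raise RuleError(
                f"rule {self.rule_id!r}: SMARTS must compile to a "
                f"mono-substrate transformation: {self.smarts!r}")
        return rxn


@dataclass(frozen=True)
class PredictedTransformation:
    rule_id: str
    substrate: str  # metabolite id (or InChI for ad-hoc compounds)
    substrate_structure: CompoundStructure
    products: tuple[CompoundStructure, ...]
    chemical_score: float

    def __post_init__(self) -> None:
        if not self.products:
            raise ValueError("transformation must have at least one product")
        if not 0.0 <= self.chemical_score <= 1.0:
            raise ValueError("chemical_score must be in [0,1]")

    @property
    def product_inchis(self) -> frozenset[str]:
        return frozenset(p.inchi for p in self.products)


# ---------------------------------------------------------------------------
# standardization


def _count_atoms(mol: Chem.Mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return counts


def _mol_from_record(record_id: str, molblock: str | None,
                     smiles: str | None, inchi: str | None) -> Chem.Mol:
    if inchi:
        mol = Chem.MolFromInchi(inchi)
        src = "InChI"
    elif molblock:
        mol = Chem.MolFromMolBlock(molblock)
        src = "MOL block"
    elif smiles:
        mol = Chem.MolFromSmiles(smiles)
        src = "SMILES"
    else:
        raise StructureError(
            f"record {record_id!r}: no structure representation present")
    if mol is None:
        raise StructureError(
            f"record {record_id!r}: unparseable {src}")
    return mol


def standardize_structure(
    record_id: str,
    molblock: str | None = None,
    smiles: str | None = None,
    inchi: str | None = None,
) -> CompoundStructure:
    """Turn any one structure representation into a canonical record.

    Identical molecules supplied as MOL block, SMILES or InChI yield the same
    canonical InChI.  Raises :class:`StructureError` carrying the record id on
    unparseable input.
    """
    mol = _mol_from_record(record_id, molblock, smiles, inchi)
    out_inchi = Chem.MolToInchi(mol)
    if not out_inchi:
        raise StructureError(f"record {record_id!r}: InChI generation failed")
    return CompoundStructure(
        inchi=out_inchi,
        smiles=Chem.MolToSmiles(mol),
        formula=_count_atoms(mol),
        charge=Chem.GetFormalCharge(mol),
    )


def structure_from_smiles(record_id: str, smiles: str) -> CompoundStructure:
    return standardize_structure(record_id, smiles=smiles)


# ---------------------------------------------------------------------------
# rule application and scoring


def chemical_similarity(a: CompoundStructure, b: CompoundStructure) -> float:
    """Tanimoto similarity of radius-2 Morgan fingerprints (2048 bits)."""
    fa = _FP_GEN.GetFingerprint(a.mol())
    fb = _FP_GEN.GetFingerprint(b.mol())
    return DataStructs.TanimotoSimilarity(fa, fb)


def _structure_from_any(record_id: str, text: str) -> CompoundStructure:
    if text.startswith("InChI="):
        return standardize_structure(record_id, inchi=text)
    return standardize_structure(record_id, smiles=text)


def apply_rule(
    rule: ReactionRule,
    substrate: CompoundStructure,
    substrate_id: str | None = None,
) -> list[PredictedTransformation]:
    """Apply a mono-substrate SMARTS rule to a standardized substrate.

    Returns one transformation per distinct product set (duplicates by
    canonical product InChIs collapsed), each product standardized; empty
    list when the pattern does not match.  Stereochemistry is ignored during
    matching (the substrate is matched through its achiral graph).
    """
    rxn = rule.rdkit_reaction()
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(substrate.mol()))
    Chem.RemoveStereochemistry(mol)
    chem_score = 1.0
    if rule.template_substrate is not None:
        template = _structure_from_any(
            f"{rule.rule_id}:template", rule.template_substrate)
        chem_score = chemical_similarity(substrate, template)
    results: dict[frozenset[str], PredictedTransformation] = {}
    for product_set in rxn.RunReactants((mol,)):
        structures = []
        ok = True
        for prod in product_set:
            try:
                Chem.SanitizeMol(prod)
                inchi = Chem.MolToInchi(prod)
                if not inchi:
                    ok = False
                    break
                structures.append(CompoundStructure(
                    inchi=inchi, smiles=Chem.MolToSmiles(prod),
                    formula=_count_atoms(prod),
                    charge=Chem.GetFormalCharge(prod)))
            except Exception:
                ok = False
                break
        if not ok or not structures:
            continue
        key = frozenset(s.inchi for s in structures)
        if key not in results:
            results[key] = PredictedTransformation(
                rule_id=rule.rule_id,
                substrate=substrate_id or substrate.inchi,
                substrate_structure=substrate,
                products=tuple(structures),
                chemical_score=chem_score)
    return [results[k] for k in sorted(results, key=sorted)]


@dataclass(frozen=True)
class SearchParams:
    """Search parameters controlling promiscuity and termination.

    Defaults follow the biosensor-mode operating point used for the phenolic
    compound study: diameters 6–16, biological cutoff 0.1, chemical cutoff
    0.6, at most 1000 iterations and an 8-hour wall-clock budget per source.
    """

    diameters: frozenset[int] = frozenset(range(6, 17, 2))
    bio_cutoff: float = 0.1
    chem_cutoff: float = 0.6
    itermax: int = 1000
    time_budget: float = 28_800.0
    max_depth: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.bio_cutoff <= 1.0 and 0.0 <= self.chem_cutoff <= 1.0):
            raise ValueError("cutoffs must be in [0,1]")
        if self.itermax < 0:
            raise ValueError("itermax must be >= 0")


def score_match(rule: ReactionRule, transformation: PredictedTransformation,
                params: SearchParams) -> bool:
    """Accept a rule application iff both scores reach their cutoffs (inclusive)."""
    return (rule.biological_score >= params.bio_cutoff
            and transformation.chemical_score >= params.chem_cutoff)


# ---------------------------------------------------------------------------
# completion and atomic balancing

#: implicit balancer species: protons may appear on either side
_PROTON = CompoundStructure(inchi="InChI=1S/p+1", formula={"H": 1}, charge=1)
_PROTON_ID = "h_plus"


def _formula_charge(entity) -> tuple[dict[str, int], int]:
    if isinstance(entity, CompoundStructure):
        return dict(entity.formula), entity.charge
    # Metabolite with formula map; charge not modelled on plain metabolites
    if getattr(entity, "formula", None):
        return dict(entity.formula), getattr(entity, "charge", 0)
    raise BalanceError(
        f"no formula available for {getattr(entity, 'id', entity)!r}")


def complete_and_balance(
    t: PredictedTransformation,
    template: Reaction,
    structures: Mapping[str, CompoundStructure],
    reaction_id: str,
    product_ids: Mapping[str, str] | None = None,
    taxa: Iterable[str] | None = None,
    allow_protons: bool = True,
) -> Reaction:
    """Complete a mono-substrate prediction into a balanced reaction.

    The rule engine predicts only the main substrate and its products; the
    template reaction supplies the candidate co-substrates and co-products
    (water, cofactor pairs, ...).  The smallest nonnegative-integer
    stoichiometry with zero residual for every element and for net charge is
    found by an integer program minimizing the total coefficient sum, with
    protons admitted as an implicit balancer when ``allow_protons``.

    ``product_ids`` maps a product InChI to the metabolite id to use in the
    emitted reaction (fresh ids derived from the InChIKey otherwise).
    Provenance of the result is ``predicted``; taxa default to the rule's.
    Raises :class:`BalanceError` when no such stoichiometry exists.
    """
    product_ids = dict(product_ids or {})
    sub_formula, sub_charge = _formula_charge(t.substrate_structure)

    # forced species: query substrate (left), predicted products (right)
    species: list[tuple[str, dict[str, int], int, int, bool]] = []
    # (metabolite id, formula, charge, side (-1/+1), forced)
    species.append((t.substrate, sub_formula, sub_charge, -1, True))
    forced_inchis = {t.substrate_structure.inchi}
    for k, p in enumerate(t.products):
        pid = product_ids.get(p.inchi) or f"pred_{p.inchikey[:14]}"
        species.append((pid, dict(p.formula), p.charge, +1, True))
        forced_inchis.add(p.inchi)

    # optional co-species from the template (skip those already forced and
    # the template's principal substrate — the species the rule pattern
    # matched, which must not reappear as a cofactor)
    def _atom_count(mid: str) -> int:
        return sum(structures[mid].formula.values()) if mid in structures else 0

    principal = max(template.substrates, key=_atom_count, default=None)

    def _candidates(side_ids: Mapping[str, Fraction], side: int):
        for mid in sorted(side_ids):
            if mid not in structures or (side < 0 and mid == principal):
                continue
            s = structures[mid]
            if s.inchi in forced_inchis:
                continue
            species.append((mid, dict(s.formula), s.charge, side, False))

    _candidates(template.substrates, -1)
    _candidates(template.products, +1)
    if allow_protons:
        species.append((_PROTON_ID, dict(_PROTON.formula), _PROTON.charge, -1, False))
        species.append((_PROTON_ID, dict(_PROTON.formula), _PROTON.charge, +1, False))

    elements = sorted({e for _, f, _, _, _ in species for e in f})
    n = len(species)
    # balance rows: for each element, sum(side * coeff * count) = 0; + charge
    A = np.zeros((len(elements) + 1, n))
    for j, (_, formula, charge, side, _) in enumerate(species):
        for i, e in enumerate(elements):
            A[i, j] = side * formula.get(e, 0)
        A[-1, j] = side * charge
    lb = np.array([1.0 if forced else 0.0 for *_, forced in species])
    ub = np.full(n, 6.0)  # single-step reactions have small coefficients
    res = milp(
        c=np.ones(n),
        constraints=LinearConstraint(A, 0.0, 0.0),
        integrality=np.ones(n),
        bounds=_Bounds(lb, ub),
    )
    if res.status != 0:
        raise BalanceError(
            f"{reaction_id}: no nonnegative integer stoichiometry closes the "
            f"elemental/charge balance (template {template.id!r})")
    coeffs = np.round(res.x).astype(int)
    stoich: dict[str, Fraction] = {}
    for j, (mid, _, _, side, _) in enumerate(species):
        if coeffs[j]:
            stoich[mid] = stoich.get(mid, Fraction(0)) + side * Fraction(int(coeffs[j]))
    stoich = {m: c for m, c in stoich.items() if c != 0}
    return Reaction(
        id=reaction_id,
        stoichiometry=stoich,
        reversible=False,
        taxa=frozenset(taxa) if taxa is not None else frozenset(),
        provenance="predicted",
    )


def elemental_residual(
    reaction: Reaction,
    structures: Mapping[str, CompoundStructure],
) -> tuple[dict[str, Fraction], Fraction]:
    """Per-element and net-charge residual of a reaction (products − substrates).

    Zero everywhere means the reaction is balanced.  Metabolites missing from
    ``structures`` raise :class:`BalanceError`.
    """
    residual: dict[str, Fraction] = {}
    charge = Fraction(0)
    for mid, coeff in reaction.stoichiometry.items():
        if mid not in structures:
            raise BalanceError(f"no structure for metabolite {mid!r}")
        formula, q = _formula_charge(structures[mid])
        for e, cnt in formula.items():
            residual[e] = residual.get(e, Fraction(0)) + Fraction(coeff) * cnt
        charge += Fraction(coeff) * q
    return {e: v for e, v in residual.items() if v != 0}, charge
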