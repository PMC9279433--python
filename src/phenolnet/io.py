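"""Readers and writers for metabolic networks.

Two dialects:

``tsv``
    A directory (or path prefix) holding two UTF-8 tab-separated tables,
    ``<prefix>.reactions.tsv`` and ``<prefix>.metabolites.tsv``.  This mirrors
    how AGORA/SEED-style content is distributed.  Headers:

    metabolites: ``id  name  inchi  smiles  formula  compartment``
    reactions:   ``id  stoichiometry  reversible  lower_bound  upper_bound
                  taxa  ec_numbers  provenance``

    ``stoichiometry`` is ``met:coeff;met:coeff`` with signed rational
    coefficients (negative = substrate); ``formula`` is a Hill-style string
    (``C6H12O6``); ``taxa`` / ``ec_numbers`` are comma-separated.

``sbml``
    SBML Level 3 core with FBC-style flux bounds, via python-libsbml.
    Taxa, EC numbers and provenance ride in the reaction notes element so a
    write→read round trip is lossless.
"""

from __future__ import annotations

import re
from fractions import Fraction
from pathlib import Path
from typing import Mapping

from .network import Metabolite, MetabolicNetwork, Reaction, ValidationError

__all__ = [
    "load_network", "write_network",
    "formula_to_map", "map_to_formula",
    "read_species_phylum_table",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_to_map(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string (``C6H12O6``) into an element map."""
    if not formula:
        return {}
    pos = 0
    out: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at offset {pos}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + (int(m.group(2) or 1))
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at offset {pos}")
    return out


def map_to_formula(formula: Mapping[str, int]) -> str:
    """Element map to Hill order string (C, H, then alphabetical)."""
    elems = dict(formula)
    parts = []
    for e in ["C", "H"] + sorted(set(elems) - {"C", "H"}):
        n = elems.get(e, 0)
        if n:
            parts.append(e + (str(n) if n != 1 else ""))
    return "".join(parts)


def _stoich_to_str(stoich: Mapping[str, Fraction]) -> str:
    return ";".join(f"{m}:{Fraction(c)}" for m, c in sorted(stoich.items()))


def _stoich_from_str(text: str, where: str) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        if ":" not in token:
            raise ValidationError(f"{where}: malformed stoichiometry token {token!r}")
        m, _, c = token.rpartition(":")
        try:
            out[m] = Fraction(c)
        except (ValueError, ZeroDivisionError) as exc:
            raise ValidationError(
                f"{where}: bad coefficient {c!r} for metabolite {m!r}") from exc
    return out


# ---------------------------------------------------------------------------
# TSV dialect

_MET_COLS = ["id", "name", "inchi", "smiles", "formula", "compartment"]
_RXN_COLS = ["id", "stoichiometry", "reversible", "lower_bound", "upper_bound",
             "taxa", "ec_numbers", "provenance"]


def _paths(prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    return (prefix.with_suffix(prefix.suffix + ".metabolites.tsv"),
            prefix.with_suffix(prefix.suffix + ".reactions.tsv"))


def _write_tsv(net: MetabolicNetwork, prefix: str | Path) -> None:
    mpath, rpath = _paths(prefix)
    with open(mpath, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_MET_COLS) + "\n")
        for mid in net.metabolite_ids():
            m = net.metabolites[mid]
            fh.write("\t".join([
                m.id, m.name, m.inchi or "", m.smiles or "",
                map_to_formula(m.formula) if m.formula else "",
                m.compartment]) + "\n")
    with open(rpath, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RXN_COLS) + "\n")
        for rid in net.reaction_ids():
            r = net.reactions[rid]
            fh.write("\t".join([
                r.id, _stoich_to_str(r.stoichiometry),
                "1" if r.reversible else "0",
                repr(r.lower_bound), repr(r.upper_bound),
                ",".join(sorted(r.taxa)), ",".join(sorted(r.ec_numbers)),
                r.provenance]) + "\n")


def _read_table(path: Path, cols: list[str]) -> list[dict[str, str]]:
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != cols:
            raise ValidationError(
                f"{path}: expected header {cols}, found {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(cols)} fields, "
                    f"found {len(fields)}")
            rows.append(dict(zip(cols, fields)))
    return rows


def _load_tsv(prefix: str | Path) -> MetabolicNetwork:
    mpath, rpath = _paths(prefix)
    net = MetabolicNetwork()
    for row in _read_table(mpath, _MET_COLS):
        net.add_metabolite(Metabolite(
            id=row["id"], name=row["name"],
            inchi=row["inchi"] or None, smiles=row["smiles"] or None,
            formula=formula_to_map(row["formula"]) if row["formula"] else None,
            compartment=row["compartment"] or "c"))
    for row in _read_table(rpath, _RXN_COLS):
        net.add_reaction(Reaction(
            id=row["id"],
            stoichiometry=_stoich_from_str(
                row["stoichiometry"], f"{rpath} reaction {row['id']!r}"),
            reversible=row["reversible"] == "1",
            lower_bound=float(row["lower_bound"]),
            upper_bound=float(row["upper_bound"]),
            taxa=frozenset(t for t in row["taxa"].split(",") if t),
            ec_numbers=frozenset(e for e in row["ec_numbers"].split(",") if e),
            provenance=row["provenance"] or "annotated"))
    return net


# ---------------------------------------------------------------------------
# SBML dialect

_SBML_NOTE = ("taxa", "ec_numbers", "provenance", "inchi", "smiles", "formula")


def _sanitize_sid(raw: str) -> str:
    sid = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "_" + sid
    return sid


def _notes_xml(fields: Mapping[str, str]) -> str:
    body = "".join(
        f"<p>{k}: {v}</p>" for k, v in fields.items() if v)
    return ("<body xmlns=\"http://www.w3.org/1999/xhtml\">" + body + "</body>")


def _parse_notes(notes: str) -> dict[str, str]:
    out = {}
    for m in re.finditer(r"<p>\s*([A-Za-z_]+):\s*(.*?)</p>", notes, re.S):
        out[m.group(1)] = m.group(2).strip()
    return out


def _write_sbml(net: MetabolicNetwork, path: str | Path) -> None:
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId("phenolnet_model")
    # one SBML compartment per distinct tag
    tags = sorted({m.compartment for m in net.metabolites.values()} or {"c"})
    for tag in tags:
        comp = model.createCompartment()
        comp.setId(_sanitize_sid(tag))
        comp.setConstant(True)
    sid_map: dict[str, str] = {}
    for mid in net.metabolite_ids():
        m = net.metabolites[mid]
        sp = model.createSpecies()
        sid = _sanitize_sid("M_" + mid)
        sid_map[mid] = sid
        sp.setId(sid)
        if m.name:
            sp.setName(m.name)
        sp.setCompartment(_sanitize_sid(m.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.setNotes(_notes_xml({
            "orig_id": mid, "inchi": m.inchi or "", "smiles": m.smiles or "",
            "formula": map_to_formula(m.formula) if m.formula else "",
        }))
    for rid in net.reaction_ids():
        r = net.reactions[rid]
        rx = model.createReaction()
        rx.setId(_sanitize_sid("R_" + rid))
        rx.setReversible(r.reversible)
        rx.setNotes(_notes_xml({
            "orig_id": rid,
            "taxa": ",".join(sorted(r.taxa)),
            "ec_numbers": ",".join(sorted(r.ec_numbers)),
            "provenance": r.provenance,
            "lower_bound": repr(r.lower_bound),
            "upper_bound": repr(r.upper_bound),
            "stoichiometry": _stoich_to_str(r.stoichiometry),
        }))
        for mid, coeff in sorted(r.stoichiometry.items()):
            ref = (rx.createReactant() if coeff < 0 else rx.createProduct())
            ref.setSpecies(sid_map[mid])
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
    libsbml.writeSBMLToFile(doc, str(path))


def _load_sbml(path: str | Path) -> MetabolicNetwork:
    import libsbml

    if not Path(path).exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        err = doc.getError(0)
        raise ValidationError(
            f"{path}: SBML parse error at line {err.getLine()}: "
            f"{err.getMessage()}")
    model = doc.getModel()
    if model is None:
        raise ValidationError(f"{path}: no model element")
    net = MetabolicNetwork()
    sid_to_orig: dict[str, str] = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        notes = _parse_notes(sp.getNotesString() if sp.isSetNotes() else "")
        orig = notes.get("orig_id") or sp.getId()
        sid_to_orig[sp.getId()] = orig
        net.add_metabolite(Metabolite(
            id=orig, name=sp.getName() or "",
            inchi=notes.get("inchi") or None,
            smiles=notes.get("smiles") or None,
            formula=(formula_to_map(notes["formula"])
                     if notes.get("formula") else None),
            compartment=sp.getCompartment() or "c"))
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        notes = _parse_notes(rx.getNotesString() if rx.isSetNotes() else "")
        orig = notes.get("orig_id") or rx.getId()
        if "stoichiometry" in notes:
            stoich = _stoich_from_str(notes["stoichiometry"],
                                      f"{path} reaction {orig!r}")
        else:
            stoich = {}
            for j in range(rx.getNumReactants()):
                ref = rx.getReactant(j)
                mid = sid_to_orig[ref.getSpecies()]
                stoich[mid] = stoich.get(mid, Fraction(0)) - Fraction(
                    ref.getStoichiometry()).limit_denominator(10**6)
            for j in range(rx.getNumProducts()):
                ref = rx.getProduct(j)
                mid = sid_to_orig[ref.getSpecies()]
                stoich[mid] = stoich.get(mid, Fraction(0)) + Fraction(
                    ref.getStoichiometry()).limit_denominator(10**6)
        net.add_reaction(Reaction(
            id=orig, stoichiometry=stoich,
            reversible=rx.getReversible(),
            lower_bound=(float(notes["lower_bound"])
                         if notes.get("lower_bound") else
                         (None if not rx.getReversible() else None)),
            upper_bound=(float(notes["upper_bound"])
                         if notes.get("upper_bound") else None),
            taxa=frozenset(t for t in notes.get("taxa", "").split(",") if t),
            ec_numbers=frozenset(
                e for e in notes.get("ec_numbers", "").split(",") if e),
            provenance=notes.get("provenance", "annotated")))
    return net


# ---------------------------------------------------------------------------
# public entry points

_DIALECTS = ("tsv", "sbml")


def load_network(path: str | Path, dialect: str = "tsv") -> MetabolicNetwork:
    """Load a :class:`MetabolicNetwork` from disk.

    ``dialect`` is ``"tsv"`` (a path prefix for the two tables) or ``"sbml"``.
    The returned network satisfies all type invariants; a write→load round
    trip preserves content.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected {_DIALECTS}")
    net = _load_tsv(path) if dialect == "tsv" else _load_sbml(path)
    net.validate()
    return net


def write_network(net: MetabolicNetwork, path: str | Path,
                  dialect: str = "tsv") -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected {_DIALECTS}")
    if dialect == "tsv":
        _write_tsv(net, path)
    else:
        _write_sbml(net, path)


def read_species_phylum_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``species<TAB>phylum`` (header optional)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.lower().startswith("species\t"):
                continue
            species, _, phylum = line.partition("\t")
            out[species] = phylum
    return out
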