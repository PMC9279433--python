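"""Compartmentalized community modelling and output-metabolite prediction.

Each species occupies its own compartment; extracellular metabolites pool in
a shared lumen through which species exchange intermediates, and lumen
exchange reactions move metabolites in and out of the community.  A context
(a food's input compounds plus a sample's species-presence vector) sets the
bounds: uptake is opened only for the food's compounds, absent species are
shut off, and secretion is free.  An output microbial metabolite is one
whose lumen exchange can carry strictly positive secretion flux — per-
exchange flux maximization (the secretion half of FVA) decides the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fluxlp import DEFAULT_EPS, FluxProblem, InfeasibleProblemError, LPSolver
from .network import MetabolicNetwork, Metabolite, Reaction
from .synthetic import CommunityContext

__all__ = [
    "CommunityModel", "CommunityContext",
    "build_community", "contextualize", "predict_outputs", "compare_outputs",
]


def _split_compartment(mid: str) -> tuple[str, str]:
    if mid.endswith("]") and "[" in mid:
        base, _, comp = mid.rpartition("[")
        return base, comp[:-1]
    return mid, ""


@dataclass
class CommunityModel:
    """Multi-species model: per-species compartments around a shared lumen."""

    network: MetabolicNetwork
    species: list[str]
    #: community reaction id -> (original reaction id, species or None)
    origin: dict[str, tuple[str, str | None]]
    #: lumen metabolite base id -> its exchange reaction id
    exchange_of: dict[str, str]
    dropped_species: list[str] = field(default_factory=list)

    @property
    def n_compartments(self) -> int:
        return len(self.species) + 1  # + lumen


def build_community(net: MetabolicNetwork,
                    species: Iterable[str]) -> CommunityModel:
    """Assemble the compartmentalized community model for a species set.

    Every reaction annotated to a species is copied into that species'
    compartment (intracellular metabolites renamed ``m[<species>]``;
    extracellular ones mapped to the shared ``[lumen]``); transports are
    thereby replicated per species from the single-species models.  Each
    extracellular metabolite gets exactly one lumen exchange.  Species with
    no annotated reaction are dropped with a warning entry.
    """
    requested = sorted(set(species))
    if not requested:
        raise ValueError("species set must be non-empty")
    cm_net = MetabolicNetwork(species_catalog=requested)
    origin: dict[str, tuple[str, str | None]] = {}
    exchange_of: dict[str, str] = {}
    kept: list[str] = []
    dropped: list[str] = []

    def lumen_id(base: str) -> str:
        lid = f"{base}[lumen]"
        if lid not in cm_net.metabolites:
            # clone descriptor from any compartment variant
            proto = next((m for m in net.metabolites.values()
                          if _split_compartment(m.id)[0] == base), None)
            cm_net.add_metabolite(Metabolite(
                id=lid, name=base,
                inchi=proto.inchi if proto else None,
                smiles=proto.smiles if proto else None,
                formula=proto.formula if proto else None,
                compartment="lumen"))
        return lid

    exchange_rids = set(net.exchange_reaction_ids())
    for sp in requested:
        rids = sorted(rid for rid, r in net.reactions.items()
                      if sp in r.taxa and rid not in exchange_rids)
        if not rids:
            dropped.append(sp)
            continue
        kept.append(sp)
        for rid in rids:
            r = net.reactions[rid]
            stoich: dict[str, Fraction] = {}
            for mid, c in r.stoichiometry.items():
                base, comp = _split_compartment(mid)
                if comp == "e":
                    new_id = lumen_id(base)
                else:
                    new_id = f"{base}[{sp}]"
                    if new_id not in cm_net.metabolites:
                        m = net.metabolites[mid]
                        cm_net.add_metabolite(Metabolite(
                            id=new_id, name=m.name, inchi=m.inchi,
                            smiles=m.smiles, formula=m.formula,
                            compartment=sp))
                stoich[new_id] = stoich.get(new_id, Fraction(0)) + Fraction(c)
            crid = f"{rid}__{sp}"
            cm_net.add_reaction(Reaction(
                id=crid, stoichiometry=stoich, reversible=r.reversible,
                lower_bound=r.lower_bound, upper_bound=r.upper_bound,
                taxa=frozenset({sp}), ec_numbers=r.ec_numbers,
                provenance=r.provenance))
            origin[crid] = (rid, sp)
    if not kept:
        raise ValueError("no requested species has an annotated reaction")
    # one lumen exchange per exchanged extracellular metabolite
    for rid in sorted(exchange_rids):
        r = net.reactions[rid]
        (mid,) = r.stoichiometry
        base, _ = _split_compartment(mid)
        lid = f"{base}[lumen]"
        if lid not in cm_net.metabolites:
            continue  # metabolite unreachable by the kept species
        if base in exchange_of:
            continue
        erid = f"EX_{base}[lumen]"
        cm_net.add_reaction(Reaction(
            id=erid, stoichiometry={lid: -1}, reversible=True,
            lower_bound=r.lower_bound if r.reversible else -abs(r.lower_bound),
            upper_bound=r.upper_bound, provenance="exchange"))
        origin[erid] = (rid, None)
        exchange_of[base] = erid
    return CommunityModel(cm_net, kept, origin, exchange_of,
                          dropped_species=dropped)


def contextualize(
    cm: CommunityModel, ctx: CommunityContext,
    eps: float = DEFAULT_EPS,
) -> tuple[FluxProblem, list[str]]:
    """Bound the community model for one dietary/microbial context.

    Uptake (negative exchange flux) is opened only for the context's input
    compounds; all other uptakes are closed.  Secretion stays open for every
    exchange.  Reactions of species absent from the context are fixed to
    zero flux.  Unknown compound or species ids are returned as warnings and
    otherwise ignored.
    """
    warnings: list[str] = []
    p = FluxProblem.from_network(cm.network, eps=eps)
    idx = {r: i for i, r in enumerate(p.reaction_ids)}
    lb, ub = p.lb.copy(), p.ub.copy()
    for base, erid in cm.exchange_of.items():
        j = idx[erid]
        lb[j] = 0.0
        ub[j] = max(ub[j], 0.0)
    for compound in sorted(ctx.input_compounds):
        erid = cm.exchange_of.get(compound)
        if erid is None:
            warnings.append(f"unknown input compound {compound!r}")
            continue
        lb[idx[erid]] = -1000.0
    known_species = set(cm.species)
    for sp in sorted(ctx.present_species):
        if sp not in known_species:
            warnings.append(f"unknown species {sp!r}")
    absent = known_species - set(ctx.present_species)
    for rid, (orig, sp) in cm.origin.items():
        if sp is not None and sp in absent:
            j = idx[rid]
            lb[j] = 0.0
            ub[j] = 0.0
    return FluxProblem(p.S, lb, ub, p.reaction_ids, p.metabolite_ids, eps), warnings


def predict_outputs(
    p: FluxProblem, cm: CommunityModel,
    eps: float | None = None,
    solver: LPSolver | None = None,
) -> set[str]:
    """Metabolites whose lumen exchange can carry secretion flux above eps.

    One flux maximization per exchange (the secretion half of FVA).  Input
    compounds may appear if the community can re-secrete them.
    """
    solver = solver or LPSolver()
    eps = p.eps if eps is None else eps
    idx = {r: i for i, r in enumerate(p.reaction_ids)}
    bounds = list(zip(p.lb.tolist(), p.ub.tolist()))
    b_eq = np.zeros(p.S.shape[0])
    out: set[str] = set()
    for base in sorted(cm.exchange_of):
        j = idx[cm.exchange_of[base]]
        c = np.zeros(p.n_reactions)
        c[j] = -1.0  # maximize secretion
        status, x, fun = solver.solve(c, p.S, b_eq, bounds)
        if status != 0:
            raise InfeasibleProblemError(
                f"secretion LP for {base!r} failed with status {status}")
        if -fun > eps:
            out.add(base)
    return out


def compare_outputs(
    net_old: MetabolicNetwork,
    net_new: MetabolicNetwork,
    contexts: Sequence[CommunityContext],
) -> dict:
    """Per-context counts of output metabolites gained by the newer network.

    Both networks must share the species catalogue.  When the old network's
    reactions are a subset of the new one's, the old output set is asserted
    to be contained in the new one (monotonicity of FVA reachability under
    reaction addition).
    """
    if net_old.species_catalog - net_new.species_catalog:
        raise ValueError("networks do not share the species catalogue")
    is_subset = set(net_old.reactions) <= set(net_new.reactions)
    per_context: dict[str, dict] = {}
    counts: list[int] = []
    for ctx in contexts:
        species = sorted(ctx.present_species) or sorted(net_new.species_catalog)
        results = {}
        for tag, net in (("old", net_old), ("new", net_new)):
            cm = build_community(net, species)
            p, _ = contextualize(cm, ctx)
            results[tag] = predict_outputs(p, cm)
        gained = results["new"] - results["old"]
        if is_subset and not results["old"] <= results["new"]:
            raise AssertionError(
                f"context {ctx.context_id}: output set shrank although the "
                f"network only grew")
        per_context[ctx.context_id] = {
            "outputs_old": sorted(results["old"]),
            "outputs_new": sorted(results["new"]),
            "n_new_outputs": len(gained),
        }
        counts.append(len(gained))
    return {
        "per_context": per_context,
        "summary": {
            "mean_new_outputs": float(np.mean(counts)) if counts else 0.0,
            "min_new_outputs": int(min(counts)) if counts else 0,
            "max_new_outputs": int(max(counts)) if counts else 0,
        },
    }
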