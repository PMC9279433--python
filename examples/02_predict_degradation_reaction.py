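"""Predict one degradation reaction by enzyme promiscuity and balance it.

A glucuronide-hydrolysis rule generalized from a luteolin conjugate is
applied to a daidzein conjugate the enzyme was never annotated with; the
mono-substrate prediction is then completed with the template's co-substrate
(water) and balanced to integer stoichiometry with zero elemental residual.
"""

from phenolnet import (ReactionRule, apply_rule, complete_and_balance,
                       elemental_residual, standardize_structure)
from phenolnet.network import Reaction
from phenolnet.synthetic import DECORATIONS, _decorate

DAIDZEIN = "O=c1c(-c2ccc(O)cc2)coc2cc(O)ccc12"
LUTEOLIN = "O=c1cc(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12"
GLUCURONATE = "OC(=O)C1OC(O)C(O)C(O)C1O"

luteolin_glcA = _decorate(LUTEOLIN, "glucuronide")
rule = ReactionRule(
    rule_id="glcA_hydrolysis_d12",
    smarts=DECORATIONS["glucuronide"][1],
    diameter=12, biological_score=0.9,
    template_reaction_id="tmpl",
    template_substrate=luteolin_glcA)

substrate = standardize_structure(
    "daidzein_glcA", smiles=_decorate(DAIDZEIN, "glucuronide"))
(t,) = apply_rule(rule, substrate, "daidzein_glcA")
print("products:", [p.smiles for p in t.products])
print(f"chemical score vs template: {t.chemical_score:.3f}")
# The products are daidzein and D-glucuronate; the score is the Tanimoto
# similarity between the query conjugate and the rule's template substrate.

structures = {
    "lut_glcA": standardize_structure("lg", smiles=luteolin_glcA),
    "water": standardize_structure("w", smiles="O"),
    "lut": standardize_structure("l", smiles=LUTEOLIN),
    "glcA": standardize_structure("g", smiles=GLUCURONATE)}
template = Reaction("tmpl", {"lut_glcA": -1, "water": -1, "lut": 1, "glcA": 1})
rxn = complete_and_balance(t, template, structures, "pred_daidzein_glcA",
                           taxa={"Lactobacillus_gasseri"})
print("balanced stoichiometry:",
      {m: int(c) for m, c in rxn.stoichiometry.items()})
lookup = dict(structures, daidzein_glcA=substrate,
              **{f"pred_{p.inchikey[:14]}": p for p in t.products})
residual, charge = elemental_residual(rxn, lookup)
print("element residual:", residual, "| charge residual:", int(charge))
# Zero residuals: C21H18O10 + H2O = C15H10O4 + C6H10O7, atom by atom.
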