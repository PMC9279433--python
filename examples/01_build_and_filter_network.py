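"""Build a tiny universal reaction database, filter and summarize it.

The universal database only keeps reactions that (a) have taxonomic
evidence to gut species of interest and (b) touch only metabolites with an
InChI — the two requirements for rule-based pathway prediction downstream.
"""

from phenolnet import (Metabolite, MetabolicNetwork, Reaction,
                       filter_universal, merge_with_dedup, summarize)

WATER = "InChI=1S/H2O/h1H2"
METHANOL = "InChI=1S/CH4O/c1-2/h2H,1H3"

net = MetabolicNetwork(
    [Metabolite("h2o", name="water", inchi=WATER),
     Metabolite("meoh", name="methanol", inchi=METHANOL),
     Metabolite("mystery")],  # no structure
    [Reaction("R_ok", {"h2o": -1, "meoh": 1}, taxa={"Bacteroides_fragilis"}),
     Reaction("R_no_taxa", {"h2o": -1, "meoh": 1, "mystery": 1}),
     Reaction("R_no_structure", {"meoh": -1, "mystery": 1},
              taxa={"Escherichia_coli"})])

kept = filter_universal(net, {"Bacteroides_fragilis", "Escherichia_coli"})
print(f"filter: {len(net.reactions)} reactions -> {len(kept.reactions)} kept")
# Only R_ok survives: R_no_taxa lacks species evidence, R_no_structure
# touches a metabolite without an InChI.

other = MetabolicNetwork(
    [Metabolite("water", inchi=WATER)],
    [Reaction("R_other", {"water": -1}, taxa={"Escherichia_coli"})])
merged, conflicts = merge_with_dedup(kept, other)
print(f"merge: {len(merged.metabolites)} metabolites "
      f"({len(conflicts)} conflicts)")
# 'h2o' and 'water' share an InChI, so the merged network has one water.

print("summary:", summarize(merged,
      {"Bacteroides_fragilis": "Bacteroidetes",
       "Escherichia_coli": "Proteobacteria"}))
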