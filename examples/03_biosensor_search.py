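"""Rediscover planted degradation pathways with the biosensor search.

A synthetic universe with known ground truth is generated; two novel
conjugated phenolics are planted with hidden two-step degradation chains and
a rule table derived from analogous annotated reactions.  The best-first
biosensor search must reconnect each source to the sink set (the universe's
own metabolites).
"""

from phenolnet import SearchParams, extract_connected_pathways, search_biosensor
from phenolnet.synthetic import (generate_universe, plant_pathways,
                                 structures_of)

universe = generate_universe(n_species=4, n_metabolites=40,
                             connectivity=0.4, seed=7)
truth = plant_pathways(universe, n_sources=2, depth=2, seed=7)
structures = structures_of(universe)
sinks = {s.inchi: mid for mid, s in structures.items() if mid.endswith("[c]")}
params = SearchParams(chem_cutoff=0.2, itermax=100, max_depth=5)

for sid, source in truth.sources.items():
    scope = search_biosensor(sid, source, sinks, truth.rules, params,
                             templates=truth.templates,
                             template_structures=structures)
    pathways, n_disconnected = extract_connected_pathways(scope, set(sinks))
    found = {(e.substrate_inchi,
              frozenset(p.inchi for p in e.transformation.products))
             for e in scope.edges}
    n_recovered = len(set(truth.steps[sid]) & found)
    print(f"{sid}: {scope.iterations} iterations, {len(scope.edges)} edges, "
          f"{len(pathways)} connected pathways ({n_disconnected} dangling), "
          f"recovered {n_recovered}/{len(truth.steps[sid])} hidden steps")
# Every planted step is found and at least one pathway ends entirely in
# sink metabolites, i.e. the novel compound is connected to the network.
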