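# Methods

## Model and procedure

`phenolnet` treats degradation-pathway prediction for dietary phenolics as
four coupled problems: (i) rule-based expansion of the metabolic space,
(ii) stoichiometric completion of mono-substrate predictions, (iii)
LP-based integration into a curated reconstruction, and (iv) qualitative
capability prediction in a multi-species community.  The assumptions are
those of constraint-based modelling — steady state (`S·v = 0`), capacity
bounds, no kinetics — plus the enzyme-promiscuity assumption that an
enzyme's reaction, generalized to a SMARTS rule around its reaction
centre, applies to substrates resembling the annotated one.

### Rule application and scoring

A rule is accepted on a query substrate when `biological_score ≥ 0.1` and
`chemical_score ≥ 0.6` (inclusive).  The biological score comes from the
rule table as given; the chemical score is Tanimoto similarity of radius-2
circular (Morgan) fingerprints, 2048 bits, between the query and the
rule's template substrate.  The cutoff values are the operating point used
for the phenolic-compound study; the similarity *metric* is our choice
(the cited retrosynthesis tooling's convention), since only the cutoff is
fixed by the study design.  Self-similarity is exactly 1, so a rule always
accepts its own template.  Stereochemistry is kept in InChI identity but
removed before SMARTS matching — rule tables are largely stereo-agnostic.
When several diameters of the same template rule produce the same product
set, the highest (most specific) diameter wins; across templates, the
higher combined score wins, ties broken by rule id.

### Completion and atomic balancing

Rules are mono-substrate, so predictions lack co-substrates (water,
cofactor pairs).  These are taken from the rule's template reaction: the
emitted reaction's substrates are the query plus optional template
co-substrates, its products the predicted products plus optional template
co-products; the template's principal substrate (largest species on the
substrate side — what the rule matched) is excluded.  Coefficients are the
solution of an integer program minimizing the total coefficient sum
subject to zero residual for every element and for net charge, with
protons admitted as an implicit balancer on either side and per-species
coefficients capped at 6 (single enzymatic steps have small
stoichiometries; the cap also excludes degenerate multi-copy solutions).
Infeasibility raises a balance error and the prediction is discarded and
logged.

### Biosensor search

The search is a deterministic best-first expansion: a priority queue over
unexplored non-sink compounds, priority = chemical×biological score of the
discovering transformation, ties by insertion order.  A node is expanded
at most once; sinks are never expanded; iteration count, wall-clock budget
and maximum depth (default 6) bound the search.  Determinism replaces the
stochastic tree search of general retrosynthesis tools deliberately: the
pipeline consumes only the tool's inputs and outputs, and a deterministic
frontier makes every downstream artifact reproducible and testable.  The
`seed` parameter is reserved for an optional stochastic rollout mode
behind the same contract.  Pathways are read out as linear chains; a
compound already expanded on a path is not re-expanded on that path
(cycle rule), and a chain is *connected* when every terminal metabolite is
a sink — only those are returned, dangling chains are counted.

### Gap-filling and consistency

Weighted FASTCORE follows the published LP-7/LP-10 scheme with
per-reaction weights scaling the L1 sparsity surrogate.  Defaults:
`ε = 10⁻⁴` for the support threshold inside FASTCORE, `ε = 10⁻⁶` for
blocked-reaction calls, flux caps ±1000 (the study states neither; these
are community conventions, all configurable).  Weights: annotated
reactions and exchanges 1, reactions without taxonomic annotation 100 —
the 100:1 ratio implements "minimize inclusion of unannotated reactions"
and is configurable.  Compounds are gap-filled sequentially in sorted-id
order (the study says "sequentially" without an order; sorted ids make the
pipeline deterministic — FASTCORE is order-sensitive in principle, so
order-insensitivity is checked, not assumed, on fixtures).  The extracted
context is verified flux-consistent before return; blocked non-core
leftovers are pruned to a fixpoint.

Single-species repair: a dead-end metabolite in an organism's sub-network
(produced-only or consumed-only under the bounds — the standard
definition) gains a transport + exchange pair only when the (species,
metabolite) pair appears in an evidence table, which externalizes the
study's editorial "sufficient evidence" criterion; otherwise the species
is removed from the stranded reactions' annotation, and reactions left
with no taxa are dropped.

### Community model and contexts

Each species' reactions are copied into a private compartment;
extracellular metabolites pool in one shared lumen with exactly one
exchange each.  Contexts are qualitative: food composition opens uptake
bounds uniformly (−1000) for listed compounds only, species absent from a
sample's 16S profile are fixed to zero flux, secretion is free, and there
is no biomass objective — a pure FVA reachability analysis, matching the
qualitative predictive rule (output present iff maximum secretion flux
> ε).  16S abundances are thresholded to presence/absence (> 0 after
filtering; configurable), the simplest faithful reading of community
membership.

### Validation statistics

One global 2×2 table pools all (metabolite, sample) cells over the fixed
scored universe (both the all-cells and differing-cells poolings are
computable; the differing-metabolite universe is the default in the
acceptance study).  The two-sided Fisher p-value uses the probability-mass
criterion, computed by exact hypergeometric enumeration in integer
arithmetic (the common denominator cancels, so the two-sidedness
comparison is exact); a zero margin returns p = 1 with a warning.

## Synthetic data: what it emulates and what it does not

`generate_universe` builds a flux-consistent universal database from ten
phenolic-like scaffolds (simple phenols, benzoic and cinnamic acids)
conjugated with glucosides, glucuronides and methyl ethers — the
conjugations gut bacteria actually remove — each conjugate carrying an
annotated, elementally balanced hydrolysis/demethylation reaction, plus
transport and exchange machinery.  Transports are open to every species
while catalysis is species-specific: uptake/export is generically
available in gut communities, and this convention keeps each organism's
sub-model free of trivial dead ends by construction.  `connectivity`
(default 0.3) is the probability of a second conjugation, producing
depth-2 annotated chains.  Default study sizes (4 species, 40 metabolites
for the integration study; 3 species, 30 metabolites for replicate
batteries) keep the vertex-enumeration and exhaustive-subset oracles exact
and the whole suite desk-scale.

`plant_pathways` conjugates existing compounds further to create novel
sources with hidden degradation chains, recorded but not added to the
universe.  The rule table is derived from annotated universe reactions of
the same transformation type on *different* scaffolds (analog templates),
at diameters 6–16 with biological scores drawn from [0.5, 0.95].  Two
admissibility constraints implement the generator's contract that planted
chains be rediscoverable: at least one species must be competent for the
entire chain (otherwise single-species repair would legitimately
disconnect it), and every chain substrate must have fingerprint similarity
≥ 0.2 to its analog template (the permissive chemical cutoff used in the
recovery studies; a chain below it is undiscoverable by design, not by
defect).  `simulate_metabolomics` draws presence calls per (metabolite,
sample) cell with stated sensitivity and specificity.

What passing tests on this data do **not** show: real rule tables are far
larger (tens of thousands of rules) and noisier; real universal databases
contain unbalanced and mis-annotated reactions; real metabolomics
identification errors are correlated (shared masses, matrix effects), not
independent Bernoulli draws; and real communities exchange far more than
the phenolic slice modelled here.  Results on synthetic data certify the
machinery, not field performance.

Seeding: one global seed fans out via `numpy.random.SeedSequence([seed,
k])` with a distinct component index `k` per artifact (universe 0/plant
2/contexts 3/metabolomics 4), so artifacts are independently reproducible
and uncorrelated.

## Numerical choices and degenerate inputs

LPs and MILPs run on the HiGHS backend through `scipy.optimize`; the LP
adapter (`LPSolver`) exposes solve/status/primal so backends can be
swapped.  FVA of an infeasible polytope raises naming the first failing
LP.  Duplicate reactions merge by canonical stoichiometry over InChI-keyed
metabolite identities and equal directionality — the study does not state
its duplicate criterion, so structural equality is our choice.  Metabolite
formula conflicts at equal InChI are reported and resolved in favour of
the structure.  Empty cores return empty gap-fills; compounds whose core
is infeasible are skipped and reported, never fatal; zero-margin
contingency tables return p = 1 with a warning.

## Known limitations

No MILP-exact minimal gap-filling, no thermodynamic/loopless constraints,
no biomass objective, no abundance-weighted or dynamic community
simulation, no pKa/protonation enumeration, no atom-atom mapping (rules
are consumed, not derived), and FVA-based presence calls are permissive —
an output that *can* be secreted in some flux state may still be absent in
vitro, which is the dominant source of false positives in this kind of
validation.
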