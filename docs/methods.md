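# Methods

This note documents the models, conventions, and numerical choices behind
fertevol, and what the simulation-based tests do and do not establish.

## Trees and phylogenetic diversity

Trees are rooted, with branch lengths in millions of years. Newick parsing
is delegated to dendropy; the package keeps its own minimal node structure
because rerooting, NNI/SPR rearrangement and vectorized parsimony scoring
are simpler on it. A named clade is an internal node label; clades given as
species sets must be monophyletic.

Faith's phylogenetic diversity (PD) of a clade is the sum of branch lengths
inside it. The clade's stem (basal) branch is **included by default**, the
same convention used to attribute events on the stem to the clade; a flag
exposes the exclusive variant. PD is additive: clade PD plus the branches
outside the clade equals total tree length.

### The packaged reference tree

`reference_tree()` returns a 19-species bony-vertebrate phylogeny —
5 teleosts (zebrafish, medaka, stickleback, two pufferfishes), *Xenopus
tropicalis*, chicken and zebra finch, platypus, opossum and 9 eutherians —
with named internal nodes (Teleostei, Aves, Eutheria, Tetrapoda, Amniota,
Mammalia, Theria, and others). Divergence times are stated approximations
assembled from standard calibration literature: root (actinopterygian–
sarcopterygian) 430 Ma, amphibian–amniote 350 Ma, sauropsid–synapsid
315 Ma, bird crown 100 Ma, mammal crown 166 Ma, sampled placental crown
97 Ma, teleost crown 250 Ma. Analyses should depend only on ordinal
properties of these lengths; the one such property relied on is
PD(Teleostei) = 945 Myr > PD(Eutheria) = 618 Myr — the deep teleost crown
outweighs the larger eutherian species sample.

## Gene-content characters and parsimony events

Each gene is a 4-state character per species: ABSENT (`0`), SINGLE (`1`),
MULTIPLE (`2+`), PSEUDOGENE (`P`), with optional copy counts (validated for
consistency, e.g. `2+:14`). MULTIPLE is a single state regardless of copy
number: per-copy histories are not identifiable from tip counts under
parsimony, so a duplication is counted once per branch.

Ancestral reconstruction is minimum-change parsimony, implemented as
unit-cost Sankoff dynamic programming (exact on polytomies; a custom 4×4
cost matrix switches to generalized Sankoff for sensitivity analyses). On
binary unit-cost trees the per-node sets of cost-minimizing states equal
the classical Fitch up-pass sets, and the suite verifies score equality
against exhaustive enumeration on small trees.

Ambiguity is resolved top-down without ever increasing the score:

* **Root.** If the minimal set contains ABSENT, absence is taken as
  primitive. Otherwise a SINGLE copy is preferred over MULTIPLE and over
  PSEUDOGENE (the most common condition is likely primitive). Any residual
  tie follows the fixed preference ABSENT > SINGLE > PSEUDOGENE > MULTIPLE.
* **Other nodes.** The parent's resolved state is inherited whenever it is
  in the node's minimal set; otherwise the same preference order applies.

Nodes decided by the bare preference order (not forced, inherited, or
covered by the two primitive-state rules) are flagged in
`AncestralStateAssignment.preference_resolved` so downstream users can see
where this package's tie-break—rather than a biologically motivated
rule—made the call.

Branch events are typed from (parent state, child state):
ABSENT→functional = gain; SINGLE→MULTIPLE = duplication;
functional→PSEUDOGENE = pseudogenization; any→ABSENT and MULTIPLE→SINGLE
(copy reduction) = loss. PSEUDOGENE→functional (reactivation) and
ABSENT→PSEUDOGENE are outside the canonical algebra; both are counted as
gains and emit a `UserWarning`.

**Applicability.** A gain is possible for a gene in a clade iff the gene is
absent at the clade's stem-parent node; duplication, pseudogenization and
loss are possible iff the gene is present (single or multiple) at the
stem-parent or anywhere inside the clade. This feeds the applicable-gene
correction of the rates.

## Clade event rates and the binomial test

`rate = n_events / PD / (n_applicable / n_total)` — events per Myr,
normalized to the fraction of studied genes at risk. A rate with zero
applicable genes is reported as not-applicable (NaN), never 0. Doubling all
branch lengths halves all rates (verified as a pipeline property).

Clade comparison uses an exact binomial test: conditional on the total
event count `n = k_A + k_B`, the null probability that an event falls in
clade A is `p0 = PD_A·g_A / (PD_A·g_A + PD_B·g_B)`. The product of
lineage-Myr and genes at risk is used as the exposure weight because events
accrue per gene per Myr; it is the only symmetric bilinear combination of
the two factors. Two-sided p-values use the minimum-likelihood ("small-p")
convention via `scipy.stats.binomtest`; a one-sided alternative is exposed.
Each event type is tested separately and no multiplicity correction is
applied across the pairwise tests. Calibration: with total event counts
Poisson-distributed at the scale the default generator produces (~49
events across Teleostei+Eutheria for 69 genes) the exact test's measured
size at α = 0.05 is slightly below nominal (exact computation 0.042,
simulation within sampling error of 0.05) — the usual discreteness of exact
tests.

## Ancestral selection intensity and the CI-overlap test

The trait is the per-species proportion of genes under positive selection,
analyzed untransformed (an arcsine-square-root option exists for
sensitivity checks). Under Brownian motion:

* **Point estimate.** Branch-length-weighted squared-change parsimony: the
  node value minimizing Σ (Δx)²/branch length over the whole tree, equal to
  the GLS estimate. Computed by rerooting the tree at the node and running
  Felsenstein's pruning to the new root (multifurcations combine children
  by precision weighting, which is exact). An unweighted variant treats all
  branches as length 1. Estimates always lie within the tip range, and all
  taxa contribute.
* **Uncertainty.** σ² is estimated as the mean squared standardized
  contrast (n−1 contrasts); the nodal unit-rate variance `v` is the final
  harmonic term of the rerooted pruning. The CI is
  `x̂ ± t(df) sqrt(σ̂² v)` with df = n−2 by convention (one contrast's worth
  of information is spent on the nodal value); df is configurable. Root CI
  coverage on the 19-species tree is 95% ± 2% over 1000 Brownian
  replicates.
* **Comparison.** Two clades differ at overall level α iff their CIs at the
  `100 − ⌊100√α⌋` percent level are strictly disjoint (touching intervals
  are not significant). The levels are 78/90/97% for α = 0.05/0.01/0.001;
  rounding the level up makes the rule conservative relative to the exact
  square-root threshold. A 1e-9 guard is added before the floor because
  `100·sqrt(0.01)` is not exactly representable in binary floating point.
  Significance tiers are nested: CIs widen as α shrinks, so rejection at
  0.001 implies rejection at 0.01 and 0.05.

### Calibration of the overlap rule, and a known limitation

"No difference between clades" means the two true clade-ancestral values
coincide. `equal_ancestor_null_trait` draws from exactly that null: an
unconditional Brownian draw is corrected by Gaussian conditioning on the
linear constraint `a_A = a_B` (each tip shifted by its covariance with the
constraint). Per-node CI coverage under this null remains at the nominal
level and σ̂² is essentially unbiased.

Under this null the overlap rule at the 78% level behaves asymmetrically:

* For **adjacent clades** (e.g. Teleostei vs Tetrapoda), whose estimates
  share most of their data, rejection is ≈ 0.005 — strongly conservative,
  as the shared-information argument predicts.
* For **distant clades with very unequal CI widths** the rule runs hot:
  Teleostei vs Eutheria rejects at ≈ 0.080 (nominal 0.05; Teleostei nodal
  variance factor ≈ 80 vs ≈ 17 for Eutheria, a direct consequence of the
  deep teleost crown). The squared-threshold argument assumes a false
  positive requires both nodal values to miss their own CIs (0.22² ≈
  0.048), but two intervals of very different width can be disjoint after a
  single large miss.

The corresponding calibration test in the suite asserts the nominal bound
and therefore fails by design, documenting the miscalibration rather than
hiding it; users comparing clades on opposite sides of a deep root should
treat p ≈ 0.05 results with caution (the 0.01/0.001 tiers are less
affected). Note that an *unconditional* Brownian simulation is not a
type-I design: true ancestral values then differ by drift
(sd = σ√513 Myr for this pair) and the rule flags them in ≈ 42% of draws —
correct detections of realized divergence, not errors.

## Signature parsimony

Cells take one of NO_GENE, NO_EVENT, DUP, POSSEL, DUP_POSSEL, PSEUDO, or
MISSING, built from tip states, inferred duplication events on the
root-to-species path, per-species selection calls, and an explicit list of
(species, gene) pairs where selection was not computable. Precedence:
NO_GENE > PSEUDO > DUP_POSSEL > DUP > POSSEL > MISSING > NO_EVENT, i.e. a
cell is MISSING only when selection is untestable *and* no other signature
applies.

Scoring is unordered multistate parsimony (vectorized unit-cost Sankoff
over all genes at once); MISSING has standard `?` semantics and never
forces a change. Search is exhaustive for ≤ 8 species (all (2n−5)!!
unrooted topologies) and heuristic above: random-addition starting trees
(ties among insertion points broken at random), NNI hill-climbing (SPR
behind a flag), then breadth-first exploration of the equal-score plateau
so tied optima enter the strict consensus (computed with dendropy,
`min_freq = 1`). NNI plateaus can be disconnected — on small matrices SPR
reaches tie islands NNI cannot — so exhaustive or SPR mode is preferred
when the complete set of optima matters. Searches are deterministic given
the seed. Monophyly is checked on splits of the unrooted topology, avoiding
rooting artifacts.

## Synthetic data

The generators define the study conditions for all statistical tests:

* **Gene content** evolves as a continuous-time Markov jump process
  (exponential waiting times) with transitions gain ABSENT→SINGLE,
  duplication SINGLE→MULTIPLE, pseudogenization SINGLE/MULTIPLE→PSEUDOGENE,
  loss →ABSENT. Default rates per gene per Myr: gain 1e-4, duplication
  1.5e-4, pseudogenization 1e-4, loss 1e-4 — with 69 genes on the ~2900-Myr
  reference tree this yields on the order of a hundred events, the scale of
  the study system (dozens of duplicated and pseudogenized fertilization
  genes across 19 species). Optional per-clade multipliers scale all rates
  on a clade's branches, stem included. The exact event log (branch, type,
  time) is returned alongside tip states.
* **Traits** follow Brownian motion with increments N(0, σ²·t); default
  σ² = 1e-4 per Myr and root 0.3 give tip proportions that wander a few
  tenths across the tree depth, as a proportion-valued trait plausibly
  would. Clade mean shifts are added on the stem branch. Clipping to [0,1]
  is **off by default** so null simulations stay exactly Brownian, and on
  when emulating proportions; clipped tips are recorded.
* **Signature matrices** assign each gene to a clade profile (default:
  teleost-enriched POSSEL, eutherian-enriched DUP, enrichment 0.8, 5%
  missing cells — mimicking the strong clade-specific signature blocks of
  real fertilization-gene data); other cells draw from a fixed baseline
  distribution dominated by NO_EVENT.

All generators require a seed and are bit-reproducible.

## Problem sizes used by the statistical tests

Chosen as the package's standard validation settings: parsimony/GLS oracle
equivalence on 500 (resp. 100) random trees of ≤ 6 leaves; CI coverage and
overlap-test calibration with 1000 Brownian replicates on the 19-species
tree; binomial calibration with 1000 replicates at ~49 expected events;
rate recovery from 500 genes at 1.5e-4 events/gene/Myr — rates are
estimated per stratum (gain from 250 root-absent genes; duplication,
pseudogenization and loss from 250 root-present genes) as inferred events
divided by reconstructed branch-time in the event's source state, because
pooling lets parsimony reinterpret multi-loss configurations in
root-present genes as deep absences with regains, inflating the gain
estimate; signature clade recovery over 50 seeded matrices (40 genes,
3 search replicates each).

## What the tests do and do not show

The simulations share the assumptions of the methods (single-rate Brownian
motion; Markovian, lineage-independent gene events except for planted
multipliers; complete and error-free tip states). Passing tests therefore
validate the implementation and the methods' internal consistency, not
their robustness to annotation error, ascertainment of genes toward one
clade, rate heterogeneity among genes, or non-Brownian trait evolution —
all present in real fertilization-gene data. The parsimony event counts are
known to be biased at high event densities (multiple hits on a branch
collapse; multi-loss patterns can be reinterpreted as regains), which is
why rate recovery is only claimed at low densities.
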