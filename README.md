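# fertevol

Comparative evolution of fertilization genes across vertebrates: a toolkit
for reconstructing gene gain, duplication, pseudogenization and loss on a
time-calibrated species tree, comparing clade-specific event rates and
positive-selection intensity, and clustering species by their
gene-evolution signatures.

Genes mediating sperm–egg interaction evolve fast and unevenly across
lineages: some are repeatedly duplicated, others decay into pseudogenes or
disappear, and many accumulate positively selected substitutions. Given a
rooted phylogeny with branch lengths in millions of years (Myr), a
genes × species state matrix (absent / single copy / multiple copies /
pseudogene), and per-species summaries of positive selection, this package
answers three questions a molecular evolutionist would ask:

1. **Do gene-content events accumulate faster in some clades?**
   Ancestral states are reconstructed by minimum-change (Fitch) parsimony
   with explicit polarity rules (absence primitive at the root; a single
   copy primitive over multiple copies or a pseudogene), branch events are
   typed (gain, duplication, pseudogenization, loss), and each clade's
   per-type rate is

   `rate = n_events / PD / (n_applicable / n_total)`

   where `PD` is the clade's Faith phylogenetic diversity in Myr (stem
   branch included) and the last factor corrects for genes in which the
   event cannot occur there. Two clades are compared with an exact binomial
   test under the exposure-weighted null
   `p0 = PD_A·g_A / (PD_A·g_A + PD_B·g_B)`.

2. **Is positive selection more intense in some clades?** The per-species
   proportion of selected genes is treated as a continuous trait evolving
   by Brownian motion. Clade-ancestral values are estimated by
   branch-length-weighted squared-change parsimony (equal to the GLS
   estimate, computed by rerooting and pruning), with confidence intervals
   `x̂ ± t(n−2) · sqrt(σ̂² · v)` where `σ̂²` is the mean squared standardized
   independent contrast and `v` the nodal unit-rate variance. Two clades
   differ significantly at level α when their CIs at the
   `100 − ⌊100√α⌋` percent level are disjoint (78%/90%/97% for
   α = 0.05/0.01/0.001).

3. **Do gene-evolution signatures group species into their clades?** Each
   species × gene cell is coded as one of
   {no gene, no event, duplication, positive selection, both, pseudogene,
   missing} and the matrix is analyzed by unordered multistate parsimony
   with exhaustive search (≤ 8 species) or random-addition + NNI/SPR
   hill-climbing, summarizing ties by strict consensus.

A packaged 19-species bony-vertebrate reference tree (5 teleosts,
*Xenopus*, 2 birds, 11 mammals; named clades Teleostei, Aves, Eutheria,
Tetrapoda, Amniota, …) and seeded generators for gene content (exact event
logs), Brownian traits (with clade shifts and an equal-ancestor null), and
signature matrices make every stage testable without any downloads.

## Worked example

```python
from fertevol import (SimulationConfig, ancestral_ci, ci_level_for_alpha,
                      compare_clades, reference_tree, simulate_brownian_trait)

tree = reference_tree()
config = SimulationConfig(seed=7, sigma2=1e-4, root_value=0.3,
                          clade_shifts={"Teleostei": 0.35}, clip_to_unit=True)
trait, _ = simulate_brownian_trait(tree, config)   # proportion per species

level = float(ci_level_for_alpha(0.05))            # -> 78 (% per-clade CI)
estimates = {c: ancestral_ci(tree, trait, c, level_percent=level)
             for c in ("Teleostei", "Aves", "Eutheria")}
for a, b in [("Teleostei", "Aves"), ("Teleostei", "Eutheria"), ("Aves", "Eutheria")]:
    print(a, "vs", b, compare_clades(estimates[a], estimates[b], alpha=0.05).tier)
```

prints (see `examples/selection_intensity_demo.py` for the full script):

```
Teleostei  ancestral proportion = 0.529 [0.430, 0.628] at 78%
Aves       ancestral proportion = 0.242 [0.169, 0.315] at 78%
Eutheria   ancestral proportion = 0.146 [0.100, 0.192] at 78%
Teleostei vs Aves: DISJOINT CIs -> significant (p<0.01)
Teleostei vs Eutheria: DISJOINT CIs -> significant (p<0.001)
Aves vs Eutheria: overlap -> ns (ns)
```

The simulated teleost elevation in selection intensity is detected at the
tier its size warrants, while the two unshifted clades stay
indistinguishable. The `examples/` directory holds one narrative script per
capability: event rates with the binomial clade test, selection-intensity
comparison, signature parsimony clustering, and dataset generation.

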