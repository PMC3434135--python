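"""Clustering species by their gene-evolution signatures.

Builds a synthetic species x gene signature matrix with teleost-enriched
positive selection and eutherian-enriched duplication (mimicking
clade-specific signature blocks), searches for most-parsimonious species
trees, and checks which clades the strict consensus recovers.
"""

from fertevol import (
    SimulationConfig,
    make_signature_fixture,
    monophyly_check,
    reference_tree,
    search_trees,
)

tree = reference_tree()
config = SimulationConfig(seed=11, n_genes=40, enrichment=0.8)
matrix = make_signature_fixture(config)
print(f"signature matrix: {len(matrix.species)} species x {len(matrix.genes)} genes")
print("cell states:", ", ".join(sorted(set(matrix.data.values.ravel()))), "\n")

result = search_trees(matrix, replicates=5, seed=11)
print(f"best parsimony score: {result.best_score}")
print(f"equally parsimonious trees kept: {len(result.best_trees)}")
print(f"search log: {result.log}\n")

print("strict consensus:")
print(result.consensus.to_newick(include_internal_labels=False), "\n")

for clade in ("Teleostei", "Eutheria", "Aves"):
    members = tree.leafset(tree.clade_node(clade))
    ok = monophyly_check(result.consensus, members)
    print(f"{clade:10s} recovered as a clade: {ok}")
print(
    "\nClades whose species share signature states act as synapomorphies, so"
    "\nthe enriched Teleostei and Eutheria blocks are recovered; Aves (no"
    "\nplanted signal) need not be."
)
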