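"""Gene gain/duplication/pseudogenization/loss rates per clade.

Simulates a 69-gene content matrix on the packaged 19-species vertebrate
tree with a 3x elevated event intensity in eutherians, reconstructs
ancestral states by parsimony with the absence/single-copy polarity rules,
types the branch events, and prints PD-normalized rates plus the
exposure-weighted binomial comparison of Teleostei vs Eutheria.
"""

import warnings

from fertevol import (
    SimulationConfig,
    compare_clades_events,
    fitch_optimize,
    infer_events,
    rate_table,
    reference_tree,
    resolve_polarity,
    simulate_gene_content,
)

tree = reference_tree()
config = SimulationConfig(seed=42, clade_rate_multipliers={"Eutheria": 3.0})
characters, _history = simulate_gene_content(tree, config)

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    assignments = {
        ch.gene: resolve_polarity(fitch_optimize(tree, ch), tree)
        for ch in characters
    }
    events = [ev for a in assignments.values() for ev in infer_events(tree, a)]

print(f"{len(events)} events inferred across {len(characters)} genes\n")

rates = rate_table(tree, events, assignments, ["Teleostei", "Aves", "Eutheria"])
print(rates.to_string(index=False, float_format=lambda x: f"{x:.5f}"))
print(
    "\nrate = events / clade PD (Myr, stem included) / fraction of genes in"
    "\nwhich the event could occur there; NaN marks events impossible in a"
    "\nclade (e.g. no gene is absent at its stem)."
)

comparison = compare_clades_events(tree, events, assignments, "Teleostei", "Eutheria")
print("\nTeleostei vs Eutheria, one exact binomial test per event type:")
print(comparison.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print(
    "\np0 is the null share of events expected in Teleostei from its"
    "\nPD x applicable-gene exposure; small p-values flag clade-dependent"
    "\nevent accumulation (here planted in Eutheria)."
)
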