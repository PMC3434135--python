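"""Comparing positive-selection intensity between clades.

Simulates the per-species proportion of positively selected genes as
Brownian motion on the packaged tree with an elevated teleost level, then
estimates each clade's ancestral proportion by squared-change parsimony,
attaches PIC confidence intervals at the squared-threshold levels, and
reports which clade differences are significant by CI overlap.
"""

from fertevol import (
    SimulationConfig,
    ancestral_ci,
    ci_level_for_alpha,
    compare_clades,
    reference_tree,
    simulate_brownian_trait,
)

tree = reference_tree()
config = SimulationConfig(
    seed=7,
    sigma2=1e-4,              # Brownian rate per Myr for a proportion in [0,1]
    root_value=0.3,
    clade_shifts={"Teleostei": 0.35},
    clip_to_unit=True,
)
trait, _ = simulate_brownian_trait(tree, config)

alpha = 0.05
level = float(ci_level_for_alpha(alpha))
print(f"per-clade CI level for overall alpha={alpha}: {level:.0f}%")
print("(78%/90%/97% correspond to testing at 0.05/0.01/0.001)\n")

estimates = {
    clade: ancestral_ci(tree, trait, clade, level_percent=level)
    for clade in ("Teleostei", "Aves", "Eutheria")
}
for clade, est in estimates.items():
    print(
        f"{clade:10s} ancestral proportion = {est.estimate:.3f} "
        f"[{est.ci[0]:.3f}, {est.ci[1]:.3f}] at {level:.0f}%"
    )

print()
pairs = [("Teleostei", "Aves"), ("Teleostei", "Eutheria"), ("Aves", "Eutheria")]
for a, b in pairs:
    res = compare_clades(estimates[a], estimates[b], alpha=alpha)
    print(f"{a} vs {b}: {'DISJOINT CIs -> significant' if res.significant else 'overlap -> ns'} ({res.tier})")
print(
    "\nDisjoint intervals mean the clades' ancestral selection intensities"
    "\ndiffer at the chosen threshold; the planted teleost shift should be"
    "\ndetected while Aves vs Eutheria stays non-significant."
)
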