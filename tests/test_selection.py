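"""Squared-change parsimony, PIC confidence intervals, clade comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from fertevol import (
    SimulationConfig,
    ancestral_ci,
    ci_level_for_alpha,
    compare_clades,
    random_bifurcating_tree,
    read_newick,
    scp_ancestral,
    simulate_brownian_trait,
)
from fertevol.errors import InsufficientDataError, ValidationError


class TestSCP:
    def test_cherry_midpoint(self):
        t = read_newick("(A:2,B:2);")
        assert scp_ancestral(t, {"A": 0.2, "B": 0.4}, t.root) == pytest.approx(0.3)

    def test_star_tree_mean(self):
        t = read_newick("(A:1,B:1,C:1,D:1);")
        trait = {"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.8}
        assert scp_ancestral(t, trait, t.root) == pytest.approx(np.mean(list(trait.values())))

    def test_matches_numeric_minimizer(self, six_leaf_tree):
        """The SCP value equals the numeric minimum of the weighted
        squared-change objective over all internal-node assignments."""
        t = six_leaf_tree
        rng = np.random.default_rng(9)
        trait = {sp: float(rng.uniform()) for sp in t.leaf_labels}
        internals = [n for n in t.nodes if not n.is_leaf]
        idx = {n.id: i for i, n in enumerate(internals)}

        def objective(z):
            val = {}
            for n in internals:
                val[n.id] = z[idx[n.id]]
            for lf in t.leaves():
                val[lf.id] = trait[lf.label]
            return sum(
                (val[n.id] - val[n.parent.id]) ** 2 / n.length
                for n in t.nodes
                if n.parent is not None
            )

        # the objective is quadratic: reconstruct it numerically from point
        # evaluations and solve exactly (an optimizer-free convex oracle)
        k = len(internals)
        e = np.eye(k)
        f0 = objective(np.zeros(k))
        M = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                M[i, j] = (
                    objective(e[i] + e[j]) - objective(e[i]) - objective(e[j]) + f0
                ) / 2.0
        b = np.array([(M[i, i] + f0 - objective(e[i])) / 2.0 for i in range(k)])
        z_star = np.linalg.solve(M, b)
        assert objective(z_star) <= optimize.minimize(
            objective, np.zeros(k), method="BFGS"
        ).fun + 1e-10
        for n in internals:
            assert scp_ancestral(t, trait, n) == pytest.approx(
                z_star[idx[n.id]], abs=1e-8
            )

    def test_estimate_within_tip_range(self, ref_tree):
        rng = np.random.default_rng(11)
        for _ in range(10):
            trait = {sp: float(rng.uniform()) for sp in ref_tree.leaf_labels}
            for clade in ("Teleostei", "Aves", "Eutheria", "Tetrapoda"):
                est = scp_ancestral(ref_tree, trait, clade)
                assert min(trait.values()) <= est <= max(trait.values())

    def test_leaf_node_rejected(self, six_leaf_tree):
        leaf = six_leaf_tree.leaves()[0]
        with pytest.raises(ValidationError):
            scp_ancestral(six_leaf_tree, {sp: 0.0 for sp in six_leaf_tree.leaf_labels}, leaf)


class TestAncestralCI:
    def test_degenerate_equal_tips_point_interval(self, six_leaf_tree):
        est = ancestral_ci(
            six_leaf_tree, {sp: 0.25 for sp in six_leaf_tree.leaf_labels},
            six_leaf_tree.root, level_percent=95.0,
        )
        assert est.sigma2 == pytest.approx(0.0)
        assert est.ci[0] == pytest.approx(est.estimate)
        assert est.ci[1] == pytest.approx(est.estimate)

    def test_var_factor_closed_form_three_leaf(self, three_leaf_tree):
        """For ((A:10,B:10):5,C:15) the root var factor is the harmonic
        composition: vAB = 10*10/20 + 5 = 10, then 10*15/25 = 6."""
        trait = {"A": 0.1, "B": 0.5, "C": 0.9}
        est = ancestral_ci(three_leaf_tree, trait, three_leaf_tree.root)
        assert est.var_factor == pytest.approx(6.0)

    def test_interval_brackets_estimate(self, ref_tree):
        cfg = SimulationConfig(seed=21, sigma2=1e-4)
        trait, _ = simulate_brownian_trait(ref_tree, cfg)
        est = ancestral_ci(ref_tree, trait, "Eutheria", level_percent=78.0)
        assert est.ci[0] <= est.estimate <= est.ci[1]
        assert est.df == len(ref_tree.leaf_labels) - 2

    def test_too_few_tips(self):
        t = read_newick("(A:1,B:1);")
        with pytest.raises(InsufficientDataError):
            ancestral_ci(t, {"A": 0.0, "B": 1.0}, t.root)


class TestCILevelRule:
    @pytest.mark.parametrize("alpha,level", [(0.05, 78), (0.01, 90), (0.001, 97)])
    def test_canonical_levels(self, alpha, level):
        assert ci_level_for_alpha(alpha) == level

    def test_monotone_and_conservative(self):
        grid = np.linspace(0.0005, 0.5, 400)
        levels = [ci_level_for_alpha(a) for a in grid]
        assert all(l2 <= l1 for l1, l2 in zip(levels, levels[1:]))
        for a, l in zip(grid, levels):
            assert (1 - l / 100.0) ** 2 <= a + 1e-9

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=1e-6, max_value=0.999))
    def test_squared_complement_never_exceeds_alpha(self, alpha):
        level = ci_level_for_alpha(alpha)
        # below alpha = 1e-4 the whole-percent rule degenerates to a 100%
        # (never-rejecting) level, which is conservative but unusable
        assert 0 < level <= 100
        assert (1 - level / 100.0) ** 2 <= alpha + 1e-9

    def test_domain_error(self):
        for bad in (0.0, 1.0, -0.2, 3.0):
            with pytest.raises(ValidationError):
                ci_level_for_alpha(bad)


def _estimate(tree, trait, clade, alpha):
    return ancestral_ci(tree, trait, clade, level_percent=ci_level_for_alpha(alpha))


class TestCompareClades:
    def _fake(self, node, lo, hi, level=78.0):
        from fertevol.selection import AncestralEstimate

        mid = (lo + hi) / 2
        return AncestralEstimate(
            node=node, estimate=mid, sigma2=1.0,
            var_factor=((hi - lo) / 2) ** 2, df=17, level_percent=level,
            ci=(lo, hi),
        )

    def test_disjoint_significant(self):
        a = self._fake("A", 0.1, 0.2)
        b = self._fake("B", 0.3, 0.4)
        res = compare_clades(a, b, alpha=0.05)
        assert res.significant and not res.overlap

    def test_touching_intervals_not_significant(self):
        a = self._fake("A", 0.1, 0.3)
        b = self._fake("B", 0.3, 0.5)
        res = compare_clades(a, b, alpha=0.05)
        assert res.overlap and not res.significant

    def test_mismatched_levels_rejected(self):
        a = self._fake("A", 0.1, 0.2, level=78.0)
        b = self._fake("B", 0.3, 0.4, level=90.0)
        with pytest.raises(ValidationError):
            compare_clades(a, b, alpha=0.05)

    def test_tier_nesting(self, ref_tree):
        """A comparison significant at a smaller alpha is significant at all
        larger ones (wider CIs at stricter levels)."""
        cfg = SimulationConfig(
            seed=5, sigma2=1e-4, clade_shifts={"Teleostei": 0.4}
        )
        trait, _ = simulate_brownian_trait(ref_tree, cfg)
        a = _estimate(ref_tree, trait, "Teleostei", 0.05)
        b = _estimate(ref_tree, trait, "Eutheria", 0.05)
        res = compare_clades(a, b, alpha=0.05)
        if res.tier == "p<0.001":
            for alpha in (0.01, 0.05):
                lvl = float(ci_level_for_alpha(alpha))
                from fertevol.selection import _disjoint

                assert _disjoint(a.ci_at(lvl), b.ci_at(lvl))

    def test_identical_traits_not_significant(self, ref_tree):
        trait = {sp: 0.3 for sp in ref_tree.leaf_labels}
        a = _estimate(ref_tree, trait, "Teleostei", 0.05)
        b = _estimate(ref_tree, trait, "Eutheria", 0.05)
        res = compare_clades(a, b, alpha=0.05)
        assert not res.significant and res.tier == "ns"


class TestTables:
    def test_estimate_and_comparison_frames(self, ref_tree):
        from fertevol.selection import comparisons_frame, estimates_frame

        trait = {sp: 0.2 for sp in ref_tree.leaf_labels}
        ests = [_estimate(ref_tree, trait, c, 0.05) for c in ("Teleostei", "Aves")]
        df = estimates_frame(ests)
        assert list(df.columns) == [
            "clade", "estimate", "sigma2", "ci_low", "ci_high", "level_percent",
        ]
        comp = compare_clades(ests[0], ests[1], alpha=0.05)
        cdf = comparisons_frame([comp])
        assert cdf.loc[0, "tier"] == "ns"


class TestPower:
    def test_power_monotone_in_shift(self, ref_tree):
        """Rejection rate grows with the size of the planted clade shift."""
        def reject_rate(delta, n=120):
            hits = 0
            for rep in range(n):
                cfg = SimulationConfig(
                    seed=10_000 + rep, sigma2=1e-4,
                    clade_shifts={"Teleostei": delta} if delta else {},
                )
                trait, _ = simulate_brownian_trait(ref_tree, cfg)
                a = _estimate(ref_tree, trait, "Teleostei", 0.05)
                b = _estimate(ref_tree, trait, "Eutheria", 0.05)
                hits += compare_clades(a, b, alpha=0.05).significant
            return hits / n

        delta = 0.08
        assert reject_rate(2 * delta) >= reject_rate(delta)
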