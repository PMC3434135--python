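"""Clade-ancestral selection intensity: squared-change parsimony estimates,
PIC confidence intervals, and the squared-threshold CI-overlap test.

The trait is a per-species proportion (here: the fraction of studied genes
under positive selection in that species). Ancestral values at clade nodes
are computed by branch-length-weighted squared-change parsimony — the value
assignment minimizing sum((delta value)^2 / branch length) over the whole
tree, which equals the GLS estimate under Brownian motion. Confidence
intervals use the Brownian rate estimated from phylogenetic independent
contrasts and a t-quantile with n-2 degrees of freedom.

Two clades are compared by checking whether their CIs overlap. Because both
nodal values must fall outside their own CIs for a false positive, the
per-clade CI level for an overall error probability alpha is the complement
of floor(100*sqrt(alpha)) percent — e.g. 78% CIs test at alpha = 0.05,
90% at 0.01 and 97% at 0.001 — which makes the test slightly conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .pic import gls_nodal_estimate, pic_contrasts
from .tree import Node, TimeTree

__all__ = [
    "AncestralEstimate",
    "CladeComparison",
    "scp_ancestral",
    "ancestral_ci",
    "ci_level_for_alpha",
    "compare_clades",
]

_TIERS = ((0.001, "p<0.001"), (0.01, "p<0.01"), (0.05, "p<0.05"))


@dataclass(frozen=True)
class AncestralEstimate:
    """Nodal trait estimate with the quantities needed to rebuild its CI."""

    node: str                 # clade name or node identifier
    estimate: float
    sigma2: float             # Brownian rate from standardized contrasts
    var_factor: float         # unit-rate variance of the nodal GLS estimate
    df: int
    level_percent: float
    ci: tuple[float, float]

    def ci_at(self, level_percent: float) -> tuple[float, float]:
        """Recompute the CI at a different confidence level."""
        half = _half_width(self.sigma2, self.var_factor, self.df, level_percent)
        return (self.estimate - half, self.estimate + half)


@dataclass(frozen=True)
class CladeComparison:
    """CI-overlap comparison of two clade-ancestral estimates."""

    clade_a: str
    clade_b: str
    level_percent: float
    overlap: bool
    significant: bool
    tier: str                 # "ns", "p<0.05", "p<0.01" or "p<0.001"


def _half_width(sigma2: float, var_factor: float, df: int, level_percent: float) -> float:
    if not 0 < level_percent < 100:
        raise ValidationError("CI level must be in (0, 100) percent")
    tq = stats.t.ppf(0.5 + level_percent / 200.0, df)
    return tq * math.sqrt(sigma2 * var_factor)


def scp_ancestral(
    tree: TimeTree,
    trait: Mapping[str, float],
    node: str | Node | int,
    weighted: bool = True,
    epsilon: float = 1e-8,
) -> float:
    """Squared-change parsimony ancestral value at an internal node.

    The default weighted variant divides each squared change by the branch
    length and equals the Brownian GLS estimate; ``weighted=False`` gives the
    unweighted variant (all branches treated as length 1). All taxa on the
    tree contribute to the estimate.
    """
    work = tree if weighted else tree.map_branch_lengths(lambda _: 1.0)
    estimate, _ = gls_nodal_estimate(work, trait, _resolve_node(work, tree, node), epsilon=epsilon)
    return estimate


def _resolve_node(work: TimeTree, original: TimeTree, node: str | Node | int):
    # node ids are preorder-stable, so they agree between a tree and its
    # branch-length-mapped copy; Node objects must be translated by id
    if isinstance(node, Node):
        return work.node_by_id(node.id)
    if isinstance(node, int):
        return work.node_by_id(node)
    return work.clade_node(node)


def ancestral_ci(
    tree: TimeTree,
    trait: Mapping[str, float],
    node: str | Node | int,
    level_percent: float = 95.0,
    polytomies: str = "reject",
    epsilon: float = 1e-8,
) -> AncestralEstimate:
    """Ancestral estimate with a PIC-based confidence interval.

    sigma^2 is the mean squared standardized contrast over the full tree;
    the nodal unit-rate variance comes from rerooting the tree at the node
    and pruning to the new root; the interval is
    estimate +/- t(df = n-2) * sqrt(sigma2 * var_factor).
    """
    n = len(tree.leaf_labels)
    if n < 3:
        raise InsufficientDataError("confidence intervals require >= 3 tips")
    cs = pic_contrasts(tree, trait, polytomies=polytomies, epsilon=epsilon)
    sigma2 = cs.sigma2
    target = _resolve_node(tree, tree, node)
    estimate, var_factor = gls_nodal_estimate(tree, trait, target, epsilon=epsilon)
    df = n - 2
    half = _half_width(sigma2, var_factor, df, level_percent)
    name = node if isinstance(node, str) else (target.label or f"node{target.id}")
    return AncestralEstimate(
        node=name,
        estimate=estimate,
        sigma2=sigma2,
        var_factor=var_factor,
        df=df,
        level_percent=level_percent,
        ci=(estimate - half, estimate + half),
    )


def ci_level_for_alpha(alpha: float) -> int:
    """Per-clade CI level (percent) whose squared complement tests at alpha.

    When two CIs are compared, a false positive needs both nodal values
    outside their own intervals, so the per-clade miss probability may be
    sqrt(alpha). The complement is taken at whole-percent resolution,
    rounding the CI level up (slightly conservative): alpha 0.05 -> 78,
    0.01 -> 90, 0.001 -> 97.

    A 1e-9 guard is added before the floor because 100*sqrt(alpha) for
    round thresholds (e.g. alpha = 0.01) is not exactly representable in
    binary floating point. For alpha < 1e-4 the whole-percent complement is
    0 and the returned level is 100 — a degenerate, never-rejecting (hence
    conservative) setting.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    return 100 - int(math.floor(100.0 * math.sqrt(alpha) + 1e-9))


def compare_clades(
    est_a: AncestralEstimate,
    est_b: AncestralEstimate,
    alpha: float = 0.05,
) -> CladeComparison:
    """Compare two clade-ancestral estimates by CI overlap.

    Both estimates must carry CIs at ``ci_level_for_alpha(alpha)``. The
    difference is significant at ``alpha`` iff the intervals are strictly
    disjoint (touching endpoints count as overlap). The reported tier is the
    smallest alpha in {0.001, 0.01, 0.05} at which the recomputed CIs are
    disjoint; larger alphas give narrower intervals, so the tiers are nested.
    """
    expected = float(ci_level_for_alpha(alpha))
    if est_a.level_percent != expected or est_b.level_percent != expected:
        raise ValidationError(
            f"estimates carry CIs at ({est_a.level_percent}, {est_b.level_percent})%"
            f" but alpha={alpha} requires {expected}%"
        )
    disjoint = _disjoint(est_a.ci, est_b.ci)
    tier = "ns"
    for a, label in _TIERS:
        lvl = float(ci_level_for_alpha(a))
        if _disjoint(est_a.ci_at(lvl), est_b.ci_at(lvl)):
            tier = label
            break
    return CladeComparison(
        clade_a=est_a.node,
        clade_b=est_b.node,
        level_percent=expected,
        overlap=not disjoint,
        significant=disjoint,
        tier=tier,
    )


def _disjoint(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> bool:
    return ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]


def estimates_frame(estimates) -> "pd.DataFrame":
    """Tabulate ancestral estimates (write with ``df.to_csv(sep='\\t')``)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "clade": e.node,
                "estimate": e.estimate,
                "sigma2": e.sigma2,
                "ci_low": e.ci[0],
                "ci_high": e.ci[1],
                "level_percent": e.level_percent,
            }
            for e in estimates
        ]
    )


def comparisons_frame(comparisons) -> "pd.DataFrame":
    """Tabulate clade comparisons with their significance tiers."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "clade_a": c.clade_a,
                "clade_b": c.clade_b,
                "level_percent": c.level_percent,
                "overlap": c.overlap,
                "significant": c.significant,
                "tier": c.tier,
            }
            for c in comparisons
        ]
    )
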