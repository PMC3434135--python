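"""Phylogenetic independent contrasts and Brownian nodal estimation.

Implements Felsenstein's pruning recursion: at each internal node the trait
values of the two descendant lineages are differenced (a contrast, with
variance equal to the sum of the two extended branch lengths) and combined
into a weighted nodal value, with the parent branch extended by the harmonic
term v1*v2/(v1+v2). Under Brownian motion the standardized contrasts are
i.i.d. normal with variance equal to the Brownian rate sigma^2.

Nodal estimates at arbitrary internal nodes are obtained by rerooting the
tree at that node and pruning to the new root; the nodal value then equals
the generalized-least-squares (GLS) Brownian estimate, and the pruning's
final harmonic term is the unit-rate variance of that estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import StructureError, ValidationError
from .tree import Node, TimeTree

__all__ = ["Contrast", "ContrastSet", "pic_contrasts", "gls_nodal_estimate"]


@dataclass(frozen=True)
class Contrast:
    """One independent contrast at an internal node."""

    node_id: int
    value: float          # x1 - x2 (order: first vs second child)
    variance: float       # v1 + v2 (extended branch lengths)

    @property
    def standardized(self) -> float:
        return self.value / math.sqrt(self.variance)


@dataclass
class ContrastSet:
    """All n-1 contrasts of a bifurcating tree plus root-level quantities."""

    contrasts: list[Contrast]
    root_value: float
    root_var_factor: float          # unit-rate variance of the root estimate
    nodal_values: dict[int, float]  # interim weighted values per internal node
    extended_lengths: dict[int, float] = field(default_factory=dict)

    @property
    def n_contrasts(self) -> int:
        return len(self.contrasts)

    @property
    def sigma2(self) -> float:
        """Brownian rate estimate: mean of squared standardized contrasts."""
        if not self.contrasts:
            raise ValidationError("no contrasts (tree too small)")
        return sum(c.standardized ** 2 for c in self.contrasts) / len(self.contrasts)


def _check_trait(tree: TimeTree, trait: Mapping[str, float]) -> None:
    missing = [lbl for lbl in tree.leaf_labels if lbl not in trait]
    if missing:
        raise ValidationError(f"trait missing for species {missing}")
    for lbl in tree.leaf_labels:
        v = trait[lbl]
        if not math.isfinite(v):
            raise ValidationError(f"non-finite trait value for {lbl!r}")


def _guard(length: float, epsilon: float) -> float:
    return length if length > 0 else epsilon


def _resolve_polytomies(tree: TimeTree) -> TimeTree:
    """Arbitrarily binarize polytomies with zero-length internal branches."""
    new = tree.copy()
    stack = [new.root]
    changed = False
    while stack:
        node = stack.pop()
        while len(node.children) > 2:
            a = node.children.pop()
            b = node.children.pop()
            joint = Node(label=None, length=0.0)
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
            changed = True
        stack.extend(node.children)
    return TimeTree(new.root) if changed else new


def pic_contrasts(
    tree: TimeTree,
    trait: Mapping[str, float],
    polytomies: str = "reject",
    epsilon: float = 1e-8,
) -> ContrastSet:
    """Compute phylogenetic independent contrasts on a bifurcating tree.

    Parameters
    ----------
    tree:
        Rooted tree with branch lengths in Myr.
    trait:
        Mapping species -> trait value, defined for every leaf.
    polytomies:
        ``"reject"`` (default) raises :class:`StructureError` on any
        multifurcation; ``"resolve"`` binarizes polytomies arbitrarily with
        zero-length internal branches (the epsilon guard then applies).
    epsilon:
        Replacement for zero-length branches in the pruning recursion, in Myr.
    """
    _check_trait(tree, trait)
    if len(tree.leaf_labels) < 2:
        raise ValidationError("contrasts require at least two leaves")
    if polytomies not in ("reject", "resolve"):
        raise ValueError(f"unknown polytomy policy {polytomies!r}")
    work = tree
    if not tree.is_binary:
        if polytomies == "reject":
            raise StructureError("tree contains polytomies; pass polytomies='resolve'")
        work = _resolve_polytomies(tree)
        if not work.is_binary:
            raise StructureError("polytomy resolution failed")

    contrasts: list[Contrast] = []
    nodal: dict[int, float] = {}
    ext: dict[int, float] = {}
    xs: dict[int, float] = {}
    vs: dict[int, float] = {}

    for node in work.postorder():
        if node.is_leaf:
            xs[node.id] = float(trait[node.label])
            vs[node.id] = _guard(node.length, epsilon)
            continue
        c1, c2 = node.children
        x1, x2 = xs[c1.id], xs[c2.id]
        v1, v2 = vs[c1.id], vs[c2.id]
        contrasts.append(Contrast(node_id=node.id, value=x1 - x2, variance=v1 + v2))
        x = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
        corr = v1 * v2 / (v1 + v2)
        xs[node.id] = x
        nodal[node.id] = x
        ext[node.id] = corr
        if node is work.root:
            root_value = x
            root_var_factor = corr
        else:
            vs[node.id] = _guard(node.length, epsilon) + corr

    return ContrastSet(
        contrasts=contrasts,
        root_value=root_value,
        root_var_factor=root_var_factor,
        nodal_values=nodal,
        extended_lengths=ext,
    )


def _prune_to_root(
    tree: TimeTree, trait: Mapping[str, float], epsilon: float
) -> tuple[float, float]:
    """Generalized pruning (handles multifurcations) to the tree's root.

    Returns ``(estimate, var_factor)``: the GLS Brownian value at the root and
    its unit-rate variance. Multifurcating nodes combine all children at once
    by precision weighting, which is exact under Brownian motion.
    """
    xs: dict[int, float] = {}
    vs: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            xs[node.id] = float(trait[node.label])
            vs[node.id] = _guard(node.length, epsilon)
            continue
        weights = [1.0 / vs[c.id] for c in node.children]
        total_w = sum(weights)
        x = sum(w * xs[c.id] for w, c in zip(weights, node.children)) / total_w
        corr = 1.0 / total_w
        xs[node.id] = x
        if node is tree.root:
            return x, corr
        vs[node.id] = _guard(node.length, epsilon) + corr
    raise AssertionError("unreachable")


def gls_nodal_estimate(
    tree: TimeTree,
    trait: Mapping[str, float],
    node: Node | int | str,
    epsilon: float = 1e-8,
) -> tuple[float, float]:
    """GLS Brownian estimate and unit-rate variance at an internal node.

    The tree is rerooted at ``node`` (given as a Node, a node id, or an
    internal-node label) and the pruning recursion is run to the new root.
    All taxa contribute to the estimate.
    """
    _check_trait(tree, trait)
    if isinstance(node, str):
        node = tree.clade_node(node)
    target = node if isinstance(node, Node) else tree.node_by_id(node)
    if target.is_leaf:
        raise ValidationError("nodal estimates are defined at internal nodes only")
    if target is tree.root:
        return _prune_to_root(tree, trait, epsilon)
    rerooted = tree.rerooted_at(target)
    return _prune_to_root(rerooted, trait, epsilon)
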