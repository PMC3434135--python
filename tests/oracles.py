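"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: ancestral values come
from explicit Brownian covariance matrices, parsimony scores from exhaustive
enumeration of ancestral assignments, p-values from direct pmf summation,
and tree-search minima from independent topology enumeration.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

from fertevol.tree import TimeTree


def _adjacency(tree: TimeTree):
    adj: dict[int, list[tuple[int, float]]] = {n.id: [] for n in tree.nodes}
    for n in tree.nodes:
        if n.parent is not None:
            adj[n.id].append((n.parent.id, n.length))
            adj[n.parent.id].append((n.id, n.length))
    return adj


def _distances_from(tree: TimeTree, src: int) -> dict[int, float]:
    adj = _adjacency(tree)
    dist = {src: 0.0}
    stack = [src]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                stack.append(v)
    return dist


def gls_matrix_estimate(tree: TimeTree, trait: dict[str, float], node_id: int):
    """Brownian GLS estimate and unit-rate variance at a node, by direct
    matrix inversion of the node-rooted covariance C[i,j] =
    (d(node,i) + d(node,j) - d(i,j)) / 2."""
    leaves = tree.leaves()
    n = len(leaves)
    dn = _distances_from(tree, node_id)
    dl = {lf.id: _distances_from(tree, lf.id) for lf in leaves}
    C = np.zeros((n, n))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            C[i, j] = (dn[a.id] + dn[b.id] - dl[a.id][b.id]) / 2.0
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    x = np.array([trait[lf.label] for lf in leaves])
    denom = one @ Ci @ one
    return float(one @ Ci @ x / denom), float(1.0 / denom)


def exhaustive_parsimony_min(tree: TimeTree, tip_states: dict[str, object], alphabet):
    """Minimum number of state changes over all ancestral assignments."""
    internals = [n for n in tree.nodes if not n.is_leaf]
    best = None
    for combo in itertools.product(alphabet, repeat=len(internals)):
        assign = {n.id: s for n, s in zip(internals, combo)}
        for leaf in tree.leaves():
            assign[leaf.id] = tip_states[leaf.label]
        changes = sum(
            1
            for n in tree.nodes
            if n.parent is not None and assign[n.id] != assign[n.parent.id]
        )
        best = changes if best is None else min(best, changes)
    return best


def binom_two_sided_minlike(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value: sum of P(X=i) <= P(X=k)."""
    pmf = [comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    ref = pmf[k]
    return sum(p for p in pmf if p <= ref * (1 + 1e-9))


def five_taxon_topologies(taxa):
    """All 15 unrooted binary topologies over 5 taxa, as Newick strings.

    Each topology is determined by its two disjoint cherry splits.
    """
    assert len(taxa) == 5
    out = []
    for pair1 in itertools.combinations(taxa, 2):
        rest = [t for t in taxa if t not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            if pair1 > pair2:  # dedupe unordered pair-of-pairs
                continue
            lone = next(t for t in rest if t not in pair2)
            out.append(
                f"(({pair1[0]},{pair1[1]}),({pair2[0]},{pair2[1]}),{lone});"
            )
    return sorted(set(out))
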