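"""Species gene-evolution signatures and most-parsimonious tree search.

Each species x gene cell records the evolutionary signature of that gene in
that species: duplication, positive selection, both, pseudogene, gene absent,
no event, or missing (positive selection not computable). Treating each gene
as an unordered multistate character, species can be clustered by searching
for most-parsimonious trees; clades of species with shared signatures (e.g.
teleosts, eutherian mammals) are then recovered as monophyletic groups.

Missing cells have standard "?" semantics: they never force a change.
Searches are exhaustive for up to 8 species and heuristic (random-addition
starting trees + NNI hill-climbing) above that, deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .characters import EventRecord, EventType, GeneStateCharacter, State
from .errors import CladeLookupError, ValidationError
from .tree import Node, TimeTree, read_newick

__all__ = [
    "SIGNATURE_STATES",
    "MISSING",
    "SignatureMatrix",
    "TreeSearchResult",
    "build_signature_matrix",
    "parsimony_score",
    "search_trees",
    "monophyly_check",
]

#: observable cell states, in the order used for scoring vectors
SIGNATURE_STATES: tuple[str, ...] = (
    "NO_GENE",
    "NO_EVENT",
    "DUP",
    "POSSEL",
    "DUP_POSSEL",
    "PSEUDO",
)
MISSING = "MISSING"
_STATE_IDX = {s: i for i, s in enumerate(SIGNATURE_STATES)}

#: single-character symbols for NEXUS output ("?" encodes MISSING)
NEXUS_SYMBOLS = {s: str(i) for i, s in enumerate(SIGNATURE_STATES)}

_INF = 1e9


@dataclass
class SignatureMatrix:
    """Species x gene matrix of categorical evolution signatures."""

    data: pd.DataFrame  # index: species, columns: genes, values: state strings

    def __post_init__(self) -> None:
        bad = set(np.unique(self.data.values)) - set(SIGNATURE_STATES) - {MISSING}
        if bad:
            raise ValidationError(f"unknown signature states {sorted(bad)}")
        if self.data.index.duplicated().any() or self.data.columns.duplicated().any():
            raise ValidationError("duplicate species or gene names")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def encoded(self) -> np.ndarray:
        """Integer-coded matrix (missing = -1), species x genes."""
        lut = dict(_STATE_IDX)
        lut[MISSING] = -1
        return np.vectorize(lut.__getitem__)(self.data.values).astype(np.int64)

    # -------------------------------------------------------------- I/O

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="species", dtype=str))

    def to_nexus(self, path) -> None:
        """Write a NEXUS characters block (one symbol per state, '?' missing)."""
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={len(self.species)} NCHAR={len(self.genes)};",
            f"    FORMAT DATATYPE=STANDARD SYMBOLS=\"{''.join(NEXUS_SYMBOLS.values())}\" MISSING=?;",
            "    MATRIX",
        ]
        for sp in self.species:
            row = "".join(
                "?" if v == MISSING else NEXUS_SYMBOLS[v] for v in self.data.loc[sp]
            )
            lines.append(f"    {sp.replace(' ', '_')}    {row}")
        lines += ["    ;", "END;", ""]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines))

    @classmethod
    def from_nexus(cls, path, genes: Optional[Sequence[str]] = None) -> "SignatureMatrix":
        cm = dendropy.StandardCharacterMatrix.get(
            path=str(path), schema="nexus", preserve_underscores=True
        )
        reverse = {v: k for k, v in NEXUS_SYMBOLS.items()}
        rows = {}
        for taxon in cm.taxon_namespace:
            symbols = [str(c) for c in cm[taxon].symbols_as_list()]
            rows[taxon.label] = [
                MISSING if s == "?" else reverse[s] for s in symbols
            ]
        n_char = len(next(iter(rows.values())))
        cols = list(genes) if genes is not None else [f"g{i}" for i in range(n_char)]
        df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        df.index.name = "species"
        return cls(df)


def build_signature_matrix(
    tree: TimeTree,
    events: Iterable[EventRecord],
    selection_calls: Mapping[str, Iterable[str]],
    gene_presence: Sequence[GeneStateCharacter],
    selection_untestable: Optional[Iterable[tuple[str, str]]] = None,
) -> SignatureMatrix:
    """Assemble the species x gene signature matrix.

    Parameters
    ----------
    tree:
        The species tree the events were inferred on (branch ids in
        ``events`` refer to it).
    events:
        Typed event records; a duplication anywhere on the path from the
        root to a species marks that species' cell as duplicated.
    selection_calls:
        Mapping species -> iterable of genes called under positive selection
        in that species.
    gene_presence:
        Tip states per gene; absent tips become NO_GENE and pseudogene tips
        PSEUDO.
    selection_untestable:
        Optional (species, gene) pairs where positive selection could not be
        computed; such cells are MISSING unless another event applies.

    Cell precedence: NO_GENE > PSEUDO > DUP_POSSEL > DUP > POSSEL > MISSING
    > NO_EVENT.
    """
    species = tree.leaf_labels
    genes = [ch.gene for ch in gene_presence]
    char_by_gene = {ch.gene: ch for ch in gene_presence}
    for ch in gene_presence:
        ch.validate_against(tree)
    sel = {sp: set(gs) for sp, gs in selection_calls.items()}
    unknown_sp = set(sel) - set(species)
    if unknown_sp:
        raise ValidationError(f"selection calls for unknown species {sorted(unknown_sp)}")
    unknown_genes = set().union(*sel.values()) - set(genes) if sel else set()
    if unknown_genes:
        raise ValidationError(f"selection calls for unknown genes {sorted(unknown_genes)}")
    untestable = set(map(tuple, selection_untestable or ()))

    # species with a duplication on their root-to-leaf path, per gene
    dup_species: dict[str, set[str]] = {g: set() for g in genes}
    for ev in events:
        if ev.event_type is not EventType.DUPLICATION:
            continue
        if ev.gene not in dup_species:
            raise ValidationError(f"event for unknown gene {ev.gene!r}")
        node = tree.node_by_id(ev.branch)
        dup_species[ev.gene] |= set(tree.leafset(node))

    cells = {}
    for sp in species:
        row = []
        for g in genes:
            state = char_by_gene[g].states[sp]
            if state is State.ABSENT:
                row.append("NO_GENE")
            elif state is State.PSEUDOGENE:
                row.append("PSEUDO")
            else:
                dup = sp in dup_species[g]
                possel = g in sel.get(sp, ())
                if dup and possel:
                    row.append("DUP_POSSEL")
                elif dup:
                    row.append("DUP")
                elif possel:
                    row.append("POSSEL")
                elif (sp, g) in untestable:
                    row.append(MISSING)
                else:
                    row.append("NO_EVENT")
        cells[sp] = row
    df = pd.DataFrame.from_dict(cells, orient="index", columns=genes)
    df.index.name = "species"
    return SignatureMatrix(df)


# ------------------------------------------------------------------ scoring


class _ScoreContext:
    """Vectorized unit-cost Sankoff scorer over all genes at once."""

    def __init__(self, matrix: SignatureMatrix):
        codes = matrix.encoded()  # species x genes
        self.species = matrix.species
        self.sp_index = {sp: i for i, sp in enumerate(self.species)}
        n_states = len(SIGNATURE_STATES)
        n_sp, n_genes = codes.shape
        # leaf cost vectors: (species, states, genes)
        leaf = np.full((n_sp, n_states, n_genes), _INF)
        for i in range(n_sp):
            for j in range(n_genes):
                c = codes[i, j]
                if c < 0:
                    leaf[i, :, j] = 0.0
                else:
                    leaf[i, c, j] = 0.0
        self.leaf_costs = leaf
        self.n_genes = n_genes

    def score(self, tree: TimeTree) -> int:
        costs: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                costs[node.id] = self.leaf_costs[self.sp_index[node.label]]
                continue
            acc = None
            for child in node.children:
                cc = costs[child.id]
                contrib = np.minimum(cc, cc.min(axis=0, keepdims=True) + 1.0)
                acc = contrib if acc is None else acc + contrib
            costs[node.id] = acc
        total = costs[tree.root.id].min(axis=0).sum()
        return int(round(total))


def parsimony_score(tree: TimeTree, matrix: SignatureMatrix) -> int:
    """Unordered multistate parsimony length of the matrix on the topology.

    Missing cells are assigned freely (never force a change). Branch lengths
    are irrelevant; only the topology matters, and the score is invariant
    under rerooting.
    """
    if set(tree.leaf_labels) != set(matrix.species):
        raise ValidationError("tree leaves do not match matrix species")
    return _ScoreContext(matrix).score(tree)


# ------------------------------------------------------------- tree moves


def _tuple_to_tree(tup) -> TimeTree:
    def build(t) -> Node:
        if isinstance(t, str):
            return Node(label=t, length=1.0)
        node = Node(length=1.0)
        for sub in t:
            node.add_child(build(sub))
        return node

    root = Node(length=0.0)
    for sub in tup:
        root.add_child(build(sub))
    return TimeTree(root)


def _splits(tree: TimeTree) -> frozenset[frozenset[str]]:
    """Canonical unrooted split set (nontrivial splits, smaller side kept)."""
    all_leaves = tree.leafset(tree.root)
    out = set()
    for node in tree.nodes:
        if node is tree.root or node.is_leaf:
            continue
        side = tree.leafset(node)
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(frozenset(canon))
    return frozenset(out)


def _enumerate_topologies(taxa: Sequence[str]):
    """All unrooted binary topologies over the taxa, as nested tuples.

    The top level is a trifurcation (the standard unrooted representation);
    there are (2n-5)!! topologies for n taxa.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValidationError("need at least 3 taxa to enumerate topologies")

    def insert_everywhere(sub, taxon):
        # yield copies of `sub` with `taxon` attached on each edge inside it
        if isinstance(sub, str):
            yield (sub, taxon)
            return
        a, b = sub
        for new_a in insert_everywhere(a, taxon):
            yield (new_a, b)
        for new_b in insert_everywhere(b, taxon):
            yield (a, new_b)
        yield (sub, taxon)

    def expand(base, remaining):
        if not remaining:
            yield base
            return
        taxon, rest = remaining[0], remaining[1:]
        x, y, z = base
        variants = []
        for nx in insert_everywhere(x, taxon):
            variants.append((nx, y, z))
        for ny in insert_everywhere(y, taxon):
            variants.append((x, ny, z))
        for nz in insert_everywhere(z, taxon):
            variants.append((x, y, nz))
        for v in variants:
            yield from expand(v, rest)

    yield from expand((taxa[0], taxa[1], taxa[2]), taxa[3:])


def _nni_neighbors(tree: TimeTree) -> list[TimeTree]:
    """All NNI rearrangements of a binary tree with a trifurcating root."""
    neighbors = []
    seen = set()
    for node in tree.nodes:
        if node.is_leaf or node is tree.root or node.parent is None:
            continue
        parent = node.parent
        siblings = [c for c in parent.children if c is not node]
        for child_idx in range(len(node.children)):
            for sib in siblings:
                new = tree.copy()
                v = new.node_by_id(node.id)
                u = new.node_by_id(parent.id)
                w = v.children[child_idx]
                s = next(c for c in u.children if c.id == sib.id)
                # swap w and s
                v.children[v.children.index(w)] = s
                u.children[u.children.index(s)] = w
                w.parent, s.parent = u, v
                rebuilt = TimeTree(new.root)
                key = _splits(rebuilt)
                if key not in seen:
                    seen.add(key)
                    neighbors.append(rebuilt)
    return neighbors


@dataclass
class TreeSearchResult:
    """Outcome of a most-parsimonious tree search."""

    best_score: int
    best_trees: list[TimeTree]
    consensus: TimeTree
    log: dict = field(default_factory=dict)


def _strict_consensus(trees: Sequence[TimeTree]) -> TimeTree:
    """Strict consensus of unrooted topologies (via dendropy)."""
    if len(trees) == 1:
        return trees[0].copy()
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        dt = dendropy.Tree.get(
            data=t.to_newick(include_internal_labels=False),
            schema="newick",
            taxon_namespace=tns,
            preserve_underscores=True,
        )
        dt.is_rooted = False
        tl.append(dt)
    cons = tl.consensus(min_freq=1.0)
    return read_newick(
        cons.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    )


def search_trees(
    matrix: SignatureMatrix,
    replicates: int = 10,
    seed: int = 0,
    mode: str = "auto",
    rearrangement: str = "nni",
    max_best: int = 64,
) -> TreeSearchResult:
    """Search for most-parsimonious species trees for a signature matrix.

    ``mode="auto"`` enumerates all topologies exhaustively for up to 8
    species and otherwise runs ``replicates`` random-addition starting trees,
    each refined by NNI (or SPR with ``rearrangement="spr"``) hill-climbing.
    Deterministic given ``seed``. All topologies attaining the best score
    (up to ``max_best`` distinct ones) are kept and summarized by their
    strict consensus.
    """
    species = matrix.species
    if len(species) < 4:
        raise ValidationError("tree search requires at least 4 species")
    codes = matrix.encoded()
    all_missing = (codes < 0).all(axis=1)
    if all_missing.any():
        bad = [sp for sp, m in zip(species, all_missing) if m]
        raise ValidationError(f"species with all-missing signatures: {bad}")
    if mode not in ("auto", "exhaustive", "heuristic"):
        raise ValidationError(f"unknown search mode {mode!r}")
    if mode == "exhaustive" or (mode == "auto" and len(species) <= 8):
        return _search_exhaustive(matrix, max_best=max_best)
    return _search_heuristic(
        matrix,
        replicates=replicates,
        seed=seed,
        rearrangement=rearrangement,
        max_best=max_best,
    )


def _collect(best_trees, best_splits, tree, max_best):
    key = _splits(tree)
    if key not in best_splits and len(best_trees) < max_best:
        best_splits.add(key)
        best_trees.append(tree)


def _search_exhaustive(matrix: SignatureMatrix, max_best: int) -> TreeSearchResult:
    ctx = _ScoreContext(matrix)
    best_score = None
    best_trees: list[TimeTree] = []
    best_splits: set = set()
    n_scored = 0
    for tup in _enumerate_topologies(matrix.species):
        tree = _tuple_to_tree(tup)
        s = ctx.score(tree)
        n_scored += 1
        if best_score is None or s < best_score:
            best_score = s
            best_trees, best_splits = [], set()
            _collect(best_trees, best_splits, tree, max_best)
        elif s == best_score:
            _collect(best_trees, best_splits, tree, max_best)
    return TreeSearchResult(
        best_score=int(best_score),
        best_trees=best_trees,
        consensus=_strict_consensus(best_trees),
        log={"mode": "exhaustive", "topologies_scored": n_scored},
    )


def _random_addition_tree(
    ctx: _ScoreContext, species: Sequence[str], rng: np.random.Generator
) -> TimeTree:
    """Greedy stepwise addition in random taxon order."""
    order = list(species)
    rng.shuffle(order)
    current = (order[0], order[1], order[2])
    for taxon in order[3:]:
        x, y, z = current
        candidates = []
        for i, sub in enumerate((x, y, z)):
            for new_sub in _insert_positions(sub, taxon):
                cand = list(current)
                cand[i] = new_sub
                candidates.append(tuple(cand))
        scores = np.array([ctx.score(_tuple_to_tree(c)) for c in candidates])
        ties = np.flatnonzero(scores == scores.min())
        current = candidates[int(rng.choice(ties))]  # random among tied placements
    return _tuple_to_tree(current)


def _insert_positions(sub, taxon):
    if isinstance(sub, str):
        yield (sub, taxon)
        return
    a, b = sub
    for na in _insert_positions(a, taxon):
        yield (na, b)
    for nb in _insert_positions(b, taxon):
        yield (a, nb)
    yield (sub, taxon)


def _spr_neighbors(tree: TimeTree) -> list[TimeTree]:
    """Subtree-prune-regraft neighborhood (unrooted, via re-insertion)."""
    neighbors = []
    seen = {_splits(tree)}
    for node in tree.nodes:
        if node is tree.root or node.parent is None:
            continue
        pruned = _prune_subtree(tree, node.id)
        if pruned is None:
            continue
        backbone, sub_tup = pruned
        x, y, z = backbone
        for i, part in enumerate((x, y, z)):
            for new_part in _regraft_positions(part, sub_tup):
                cand = list(backbone)
                cand[i] = new_part
                t = _tuple_to_tree(tuple(cand))
                key = _splits(t)
                if key not in seen:
                    seen.add(key)
                    neighbors.append(t)
    return neighbors


def _regraft_positions(part, sub_tup):
    if isinstance(part, str):
        yield (part, sub_tup)
        return
    a, b = part
    for na in _regraft_positions(a, sub_tup):
        yield (na, b)
    for nb in _regraft_positions(b, sub_tup):
        yield (a, nb)
    yield (part, sub_tup)


def _node_to_tuple(node: Node):
    if node.is_leaf:
        return node.label
    subs = [_node_to_tuple(c) for c in node.children]
    if len(subs) == 1:
        return subs[0]
    out = subs[0]
    for s in subs[1:]:
        out = (out, s)
    return out


def _prune_subtree(tree: TimeTree, node_id: int):
    """Remove the subtree below node_id; return (backbone 3-tuple, subtree)."""
    work = tree.copy()
    node = work.node_by_id(node_id)
    sub_tup = _node_to_tuple(node)
    parent = node.parent
    parent.children.remove(node)
    # suppress degree-2 nodes up the path
    while parent is not None and len(parent.children) == 1 and parent.parent is not None:
        only = parent.children[0]
        gp = parent.parent
        gp.children[gp.children.index(parent)] = only
        only.parent = gp
        parent = gp
    root = work.root
    if len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    parts = [_node_to_tuple(c) for c in root.children]
    # normalize the backbone to an unrooted trifurcation
    while len(parts) > 3:
        parts = [(parts[0], parts[1])] + parts[2:]
    if len(parts) == 2:
        a, b = parts
        if not isinstance(b, str):
            parts = [a, b[0], b[1]]
        elif not isinstance(a, str):
            parts = [a[0], a[1], b]
        else:
            return None  # backbone too small to regraft meaningfully
    if len(parts) != 3:
        return None
    return tuple(parts), sub_tup


def _search_heuristic(
    matrix: SignatureMatrix,
    replicates: int,
    seed: int,
    rearrangement: str,
    max_best: int,
) -> TreeSearchResult:
    if rearrangement not in ("nni", "spr"):
        raise ValidationError(f"unknown rearrangement {rearrangement!r}")
    ctx = _ScoreContext(matrix)
    rng = np.random.default_rng(seed)
    neighbor_fn = _nni_neighbors if rearrangement == "nni" else _spr_neighbors

    best_score = None
    best_trees: list[TimeTree] = []
    best_splits: set = set()
    moves_tried = 0
    for _ in range(replicates):
        tree = _random_addition_tree(ctx, matrix.species, rng)
        score = ctx.score(tree)
        while True:
            # hill-climb on strictly improving moves
            improved = True
            while improved:
                improved = False
                for nb in neighbor_fn(tree):
                    moves_tried += 1
                    s = ctx.score(nb)
                    if s < score:
                        tree, score = nb, s
                        improved = True
                        break
            # explore the plateau of equally parsimonious neighbors so tied
            # optima enter the strict consensus; restart if the plateau edge
            # exposes a strictly better tree
            plateau = [tree]
            seen = {_splits(tree)}
            better = None
            qi = 0
            while qi < len(plateau) and len(plateau) < max_best and better is None:
                for nb in neighbor_fn(plateau[qi]):
                    key = _splits(nb)
                    if key in seen:
                        continue
                    moves_tried += 1
                    s = ctx.score(nb)
                    if s < score:
                        better = (nb, s)
                        break
                    if s == score:
                        seen.add(key)
                        plateau.append(nb)
                qi += 1
            if better is None:
                break
            tree, score = better
        if best_score is None or score < best_score:
            best_score = score
            best_trees, best_splits = [], set()
        if score == best_score:
            for t in plateau:
                _collect(best_trees, best_splits, t, max_best)
    return TreeSearchResult(
        best_score=int(best_score),
        best_trees=best_trees,
        consensus=_strict_consensus(best_trees),
        log={
            "mode": "heuristic",
            "replicates": replicates,
            "rearrangement": rearrangement,
            "moves_tried": moves_tried,
            "seed": seed,
        },
    )


def monophyly_check(tree: TimeTree, species: Iterable[str]) -> bool:
    """True iff the species set forms a clade of the unrooted topology.

    Checked as a split: some edge must have exactly this species set on one
    side. Working unrooted avoids artifacts from arbitrary rooting of search
    results.
    """
    target = frozenset(species)
    all_leaves = tree.leafset(tree.root)
    unknown = target - all_leaves
    if unknown:
        raise CladeLookupError(f"unknown species {sorted(unknown)}")
    if target == all_leaves or len(target) == 1:
        return True
    for node in tree.nodes:
        if node is tree.root:
            continue
        side = tree.leafset(node)
        if side == target or (all_leaves - side) == target:
            return True
    return False
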