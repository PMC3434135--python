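"""Rooted time-calibrated trees: Newick I/O, clade resolution, phylogenetic diversity.

Branch lengths are in millions of years (Myr) throughout the package. Trees
are rooted; every non-root node carries the length of the branch connecting
it to its parent. Internal nodes may carry clade labels (e.g. ``Teleostei``),
which resolve to the unique internal node spanning exactly that clade's
species.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator, Optional

import dendropy

from .errors import CladeLookupError, NewickParseError, ValidationError

__all__ = ["Node", "TimeTree", "read_newick", "write_newick"]


class Node:
    """A single tree node. ``length`` is the branch to the parent in Myr."""

    __slots__ = ("label", "length", "parent", "children", "id")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.id: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.id} {self.label!r} {kind} len={self.length}>"


class TimeTree:
    """A rooted tree with Myr branch lengths and optional named clades.

    Node ids are assigned in preorder and are stable for the lifetime of the
    object; they identify branches (a branch is named by its child node).
    """

    def __init__(self, root: Node):
        self.root = root
        self._index()
        self._validate()

    # ------------------------------------------------------------------ #
    # construction and indexing

    def _index(self) -> None:
        self._nodes: list[Node] = []
        for i, node in enumerate(self.preorder()):
            node.id = i
            self._nodes.append(node)
        self._label_to_node: dict[str, Node] = {}
        for node in self._nodes:
            if node.label is not None:
                # leaf labels are unique (validated); internal labels may not
                # clash with each other either
                if node.label in self._label_to_node:
                    raise ValidationError(f"duplicate node label {node.label!r}")
                self._label_to_node[node.label] = node
        self._leafset_cache: dict[int, frozenset[str]] = {}
        for node in reversed(self._nodes):  # postorder by reversed preorder
            if node.is_leaf:
                if node.label is None:
                    raise ValidationError("leaf without a label")
                self._leafset_cache[node.id] = frozenset([node.label])
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= self._leafset_cache[c.id]
                self._leafset_cache[node.id] = frozenset(acc)

    def _validate(self) -> None:
        for node in self._nodes:
            if node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} at node {node.id}"
                )
            if node is not self.root and node.parent is None:
                raise ValidationError("non-root node without a parent")
        labels = [n.label for n in self.leaves()]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate leaf labels")

    # ------------------------------------------------------------------ #
    # traversal

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    @property
    def nodes(self) -> list[Node]:
        return list(self._nodes)

    def leaves(self) -> list[Node]:
        return [n for n in self._nodes if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    def node_by_id(self, node_id: int) -> Node:
        return self._nodes[node_id]

    def leafset(self, node: Node | int) -> frozenset[str]:
        node_id = node if isinstance(node, int) else node.id
        return self._leafset_cache[node_id]

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self._nodes if not n.is_leaf)

    # ------------------------------------------------------------------ #
    # clades

    def clade_node(self, clade: str | Iterable[str]) -> Node:
        """Resolve a clade given by internal-node label or by species set.

        A species set resolves to the MRCA, which must span exactly that set.
        """
        if isinstance(clade, Node):
            return clade
        if isinstance(clade, str):
            node = self._label_to_node.get(clade)
            if node is None or node.is_leaf:
                raise CladeLookupError(f"no internal node labelled {clade!r}")
            return node
        species = frozenset(clade)
        unknown = species - self._leafset_cache[self.root.id]
        if unknown:
            raise CladeLookupError(f"unknown species {sorted(unknown)}")
        node = self.mrca(species)
        if self.leafset(node) != species:
            raise CladeLookupError(
                f"species set {sorted(species)} is not monophyletic here"
            )
        return node

    def mrca(self, species: Iterable[str]) -> Node:
        species = frozenset(species)
        node = self.root
        while True:
            for child in node.children:
                if species <= self.leafset(child):
                    node = child
                    break
            else:
                return node

    def clade_nodes(self, clade: str | Iterable[str], include_mrca: bool = True) -> list[Node]:
        """All nodes inside the clade (subtree of its MRCA)."""
        top = self.clade_node(clade)
        out: list[Node] = []
        stack = [top]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        if not include_mrca:
            out.remove(top)
        return out

    def branch_in_clade(self, node: Node, clade_mrca: Node) -> bool:
        """True iff the branch above ``node`` belongs to the clade.

        The stem branch (the branch above the clade's MRCA) counts as part of
        the clade, matching the convention that the basal branch subtending a
        clade is attributed to it.
        """
        n: Optional[Node] = node
        while n is not None:
            if n is clade_mrca:
                return True
            n = n.parent
        return False

    # ------------------------------------------------------------------ #
    # measures

    @property
    def total_length(self) -> float:
        return sum(n.length for n in self._nodes if n is not self.root)

    def phylogenetic_diversity(
        self, clade: str | Iterable[str], include_stem: bool = True
    ) -> float:
        """Faith's PD of a clade: the sum of branch lengths inside it, in Myr.

        By default the clade's subtending (stem) branch is included, the
        convention used when events on the stem are attributed to the clade.
        """
        top = self.clade_node(clade)
        pd = sum(n.length for n in self.clade_nodes(top) if n is not top)
        if include_stem and top is not self.root:
            pd += top.length
        return pd

    def distance_matrix(self) -> tuple[list[str], "list[list[float]]"]:
        """Patristic distances between all pairs of leaves (used by oracles)."""
        labels = self.leaf_labels
        depth: dict[int, float] = {self.root.id: 0.0}
        for n in self.preorder():
            if n is not self.root:
                depth[n.id] = depth[n.parent.id] + n.length
        leaves = self.leaves()
        dist = [[0.0] * len(leaves) for _ in leaves]
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                if j <= i:
                    continue
                m = self.mrca([a.label, b.label])
                d = depth[a.id] + depth[b.id] - 2 * depth[m.id]
                dist[i][j] = dist[j][i] = d
        return labels, dist

    # ------------------------------------------------------------------ #
    # transformations

    def copy(self) -> "TimeTree":
        return TimeTree(_copy_subtree(self.root))

    def map_branch_lengths(self, fn: Callable[[float], float]) -> "TimeTree":
        new_root = _copy_subtree(self.root)
        stack = [new_root]
        while stack:
            n = stack.pop()
            if n is not new_root:
                n.length = fn(n.length)
            stack.extend(n.children)
        return TimeTree(new_root)

    def rerooted_at(self, node: Node | int) -> "TimeTree":
        """Return a new tree rooted at the given internal node.

        The tree is treated as unrooted for this purpose: parent pointers along
        the path to the old root are reversed and, if the old root is left with
        degree two, it is suppressed (its two incident branch lengths merge).
        """
        target = node if isinstance(node, Node) else self.node_by_id(node)
        if target.is_leaf:
            raise ValidationError("cannot reroot at a leaf")
        if target is self.root:
            return self.copy()

        # undirected adjacency over node ids
        adj: dict[int, list[tuple[int, float]]] = {n.id: [] for n in self._nodes}
        for n in self._nodes:
            if n is not self.root:
                adj[n.id].append((n.parent.id, n.length))
                adj[n.parent.id].append((n.id, n.length))

        new_nodes: dict[int, Node] = {}

        def build(old_id: int, came_from: Optional[int]) -> Node:
            old = self._nodes[old_id]
            nn = Node(label=old.label, length=0.0)
            new_nodes[old_id] = nn
            for nbr, length in adj[old_id]:
                if nbr == came_from:
                    continue
                child = build(nbr, old_id)
                child.length = length
                nn.add_child(child)
            return nn

        import sys

        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, 4 * len(self._nodes) + 100))
        try:
            new_root = build(target.id, None)
        finally:
            sys.setrecursionlimit(old_limit)

        # suppress the old root if it became a degree-2 pass-through node
        old_root_new = new_nodes[self.root.id]
        if len(old_root_new.children) == 1 and old_root_new.parent is not None:
            child = old_root_new.children[0]
            child.length += old_root_new.length
            parent = old_root_new.parent
            parent.children[parent.children.index(old_root_new)] = child
            child.parent = parent
        return TimeTree(new_root)

    # ------------------------------------------------------------------ #
    # serialization

    def to_newick(self, include_internal_labels: bool = True) -> str:
        return write_newick(self, include_internal_labels=include_internal_labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree {len(self.leaf_labels)} leaves>"


def _copy_subtree(node: Node) -> Node:
    new = Node(label=node.label, length=node.length)
    for c in node.children:
        new.add_child(_copy_subtree(c))
    return new


# ---------------------------------------------------------------------- #
# Newick I/O (parsing delegated to dendropy)


def read_newick(text: str) -> TimeTree:
    """Parse a Newick string into a :class:`TimeTree`.

    Branch lengths follow colons; internal node labels are kept as clade
    names. Raises :class:`NewickParseError` on malformed input (the message
    carries dendropy's position report) and :class:`ValidationError` on
    duplicate leaf labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,  # duplicate labels caught by our validation
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length or 0.0)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return TimeTree(convert(dtree.seed_node))


def write_newick(tree: TimeTree, include_internal_labels: bool = True) -> str:
    """Serialize a tree to Newick (lengths after colons, root length omitted)."""

    def fmt_len(x: float) -> str:
        return format(x, "g")

    def rec(node: Node, is_root: bool) -> str:
        if node.is_leaf:
            body = node.label or ""
        else:
            inner = ",".join(rec(c, False) for c in node.children)
            label = node.label if (include_internal_labels and node.label) else ""
            body = f"({inner}){label}"
        if is_root:
            return body
        return f"{body}:{fmt_len(node.length)}"

    return rec(tree.root, True) + ";"


def read_newick_file(path) -> TimeTree:
    with open(path, "r", encoding="utf-8") as fh:
        return read_newick(fh.read())
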