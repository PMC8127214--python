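"""Rooted trees over labeled entities.

A :class:`Tree` stores a rooted, connected, acyclic hierarchy over ``K``
leaves (the measured entities) and ``M - K`` internal nodes.  Nodes carry
integer identifiers: leaves are ``1..K`` in order of first appearance,
internal nodes are ``K+1..M`` in post-order, so the root is always ``M``.
This numbering makes "is this a leaf?" an O(1) comparison and matches the
convention used throughout the hierarchical-testing literature.

Two queries drive everything downstream:

* ``b(i)`` — the descendant leaves of node ``i`` (:meth:`Tree.descendant_leaves`),
* ``B(i)`` — node ``i`` together with all of its descendants, internal and
  leaf (:meth:`Tree.branch_set`).

Multifurcating (non-binary) trees are fully supported; taxonomic trees and
biogenesis hierarchies are rarely binary.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Tree",
    "TreeError",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "tree_from_linkage",
    "descendant_leaves",
    "branch_set",
]


class TreeError(ValueError):
    """Invalid tree structure or query."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class _Node:
    """Builder node used while assembling a :class:`Tree`."""

    __slots__ = ("label", "length", "children")

    def __init__(self, label=None, length=None, children=None):
        self.label = label
        self.length = length
        self.children = children if children is not None else []


_SPECIAL = set("(),:;'\"[]\t\n ")


def _escape(label: str) -> str:
    if any(c in _SPECIAL for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


class Tree:
    """Rooted tree with leaves-first integer node numbering.

    Do not call the constructor directly; use :func:`parse_newick`,
    :func:`tree_from_linkage` or :meth:`Tree._from_builder`.
    """

    def __init__(self, parent, children, labels, lengths, auto_label):
        self._parent = parent          # np.ndarray (M+1,), parent[root] = 0
        self._children = children      # tuple of tuples, index 0 unused
        self._labels = labels          # list[str], index 0 unused
        self._lengths = lengths        # list[float | None]
        self._auto_label = auto_label  # list[bool]; True = synthesized label
        self.n_nodes = len(labels) - 1
        self.n_leaves = sum(1 for i in range(1, self.n_nodes + 1) if not children[i])
        self.root = self.n_nodes
        self._postorder = None
        self._b_cache = None
        self._branch_cache = {}
        self._label2node = None
        self._validate()

    # ------------------------------------------------------------------ build

    @classmethod
    def _from_builder(cls, root: _Node) -> "Tree":
        # Leaves numbered 1..K by first (preorder, left-to-right) appearance;
        # internal nodes K+1..M in post-order, hence root = M.
        leaves: list[_Node] = []
        internals: list[_Node] = []
        stack = [(root, False)]
        while stack:
            node, done = stack.pop()
            if not node.children:
                continue
            if done:
                internals.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    if child.children:
                        stack.append((child, False))

        # preorder leaf collection
        pre = [root]
        while pre:
            node = pre.pop(0)
            if not node.children:
                leaves.append(node)
            else:
                pre = list(node.children) + pre

        K = len(leaves)
        if K < 2:
            raise TreeError(f"a tree needs at least 2 leaves, got {K}")
        ordered = leaves + internals
        ids = {id(n): i + 1 for i, n in enumerate(ordered)}
        M = len(ordered)
        parent = np.zeros(M + 1, dtype=np.int64)
        children: list[tuple[int, ...]] = [() for _ in range(M + 1)]
        labels: list[str] = [""] * (M + 1)
        lengths: list[float | None] = [None] * (M + 1)
        auto: list[bool] = [False] * (M + 1)
        for node in ordered:
            i = ids[id(node)]
            lengths[i] = node.length
            if node.children:
                children[i] = tuple(ids[id(c)] for c in node.children)
                for c in node.children:
                    parent[ids[id(c)]] = i
                if node.label:
                    labels[i] = str(node.label)
                else:
                    labels[i] = f"node_{i}"
                    auto[i] = True
            else:
                if node.label is None or str(node.label) == "":
                    raise TreeError("every leaf must carry a label")
                labels[i] = str(node.label)
        return cls(parent, tuple(children), labels, lengths, auto)

    def _validate(self) -> None:
        K, M = self.n_leaves, self.n_nodes
        if K < 2:
            raise TreeError(f"a tree needs at least 2 leaves, got {K}")
        leaf_labels = [self._labels[i] for i in range(1, K + 1)]
        if any(lab == "" for lab in leaf_labels):
            raise TreeError("leaf labels must be non-empty")
        dupes = {lab for lab in leaf_labels if leaf_labels.count(lab) > 1}
        if dupes:
            raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")
        n_root = sum(1 for i in range(1, M + 1) if self._parent[i] == 0)
        if n_root != 1 or self._parent[self.root] != 0:
            raise TreeError("tree must have exactly one root (the last node)")
        for i in range(1, M + 1):
            if i > K and not self._children[i]:
                raise TreeError(f"internal node {i} has no children")
        for i in range(1, M + 1):
            ln = self._lengths[i]
            if ln is not None and (not np.isfinite(ln) or ln < 0):
                raise TreeError(f"branch length of node {i} must be nonnegative")

    # ------------------------------------------------------------------ basic

    def is_leaf(self, i: int) -> bool:
        self._check(i)
        return i <= self.n_leaves

    def _check(self, i: int) -> None:
        if not (isinstance(i, (int, np.integer)) and 1 <= i <= self.n_nodes):
            raise TreeError(f"unknown node id {i!r} (valid: 1..{self.n_nodes})")

    def parent(self, i: int) -> int | None:
        self._check(i)
        p = int(self._parent[i])
        return None if p == 0 else p

    def children(self, i: int) -> tuple[int, ...]:
        self._check(i)
        return self._children[i]

    def label(self, i: int) -> str:
        self._check(i)
        return self._labels[i]

    def branch_length(self, i: int) -> float | None:
        self._check(i)
        return self._lengths[i]

    @property
    def leaves(self) -> range:
        return range(1, self.n_leaves + 1)

    @property
    def leaf_labels(self) -> list[str]:
        return [self._labels[i] for i in range(1, self.n_leaves + 1)]

    @property
    def internal_nodes(self) -> range:
        return range(self.n_leaves + 1, self.n_nodes + 1)

    def node_by_label(self, label: str) -> int:
        """Resolve a node id from its (unique) label."""
        if self._label2node is None:
            seen: dict[str, int | None] = {}
            for i in range(1, self.n_nodes + 1):
                lab = self._labels[i]
                seen[lab] = None if lab in seen else i
            self._label2node = seen
        try:
            i = self._label2node[label]
        except KeyError:
            raise TreeError(f"unknown node label {label!r}") from None
        if i is None:
            raise TreeError(f"ambiguous node label {label!r}")
        return i

    def postorder(self) -> list[int]:
        """All node ids, children before parents (cached)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [(self.root, False)]
            while stack:
                node, done = stack.pop()
                if done or not self._children[node]:
                    order.append(node)
                else:
                    stack.append((node, True))
                    stack.extend((c, False) for c in reversed(self._children[node]))
            self._postorder = order
        return self._postorder

    # ----------------------------------------------------------------- b / B

    def descendant_leaves(self, i: int) -> frozenset[int]:
        """b(i): the set of descendant leaf ids of node ``i`` (a leaf maps to itself)."""
        self._check(i)
        if self._b_cache is None:
            cache: dict[int, frozenset[int]] = {}
            for node in self.postorder():
                if not self._children[node]:
                    cache[node] = frozenset((node,))
                else:
                    acc: set[int] = set()
                    for c in self._children[node]:
                        acc |= cache[c]
                    cache[node] = frozenset(acc)
            self._b_cache = cache
        return self._b_cache[i]

    def branch_set(self, i: int) -> frozenset[int]:
        """B(i): node ``i`` plus all of its descendants, internal and leaf."""
        self._check(i)
        if i not in self._branch_cache:
            acc = set()
            stack = [i]
            while stack:
                node = stack.pop()
                acc.add(node)
                stack.extend(self._children[node])
            self._branch_cache[i] = frozenset(acc)
        return self._branch_cache[i]

    def n_descendant_leaves(self, i: int) -> int:
        return len(self.descendant_leaves(i))

    def is_ancestor(self, a: int, d: int) -> bool:
        """True when ``a`` lies on the path from ``d`` to the root (a != d)."""
        self._check(a)
        self._check(d)
        p = int(self._parent[d])
        while p != 0:
            if p == a:
                return True
            p = int(self._parent[p])
        return False

    # ----------------------------------------------------------------- output

    @property
    def has_branch_lengths(self) -> bool:
        return any(self._lengths[i] is not None for i in range(1, self.n_nodes + 1))

    def to_table(self) -> pd.DataFrame:
        """Node annotation table (node_id, label, is_leaf, parent_id)."""
        rows = [
            {
                "node_id": i,
                "label": self._labels[i],
                "is_leaf": i <= self.n_leaves,
                "parent_id": int(self._parent[i]) or pd.NA,
            }
            for i in range(1, self.n_nodes + 1)
        ]
        return pd.DataFrame(rows)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Tree(K={self.n_leaves}, M={self.n_nodes})"


# ---------------------------------------------------------------------- I/O


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Leaf numbering follows first appearance in the string; internal nodes are
    numbered in post-order after the leaves; branch lengths are preserved when
    present.  Unlabeled internal nodes receive synthetic ``node_<id>`` labels.
    """
    import dendropy

    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy error messages carry the position
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> _Node:
        node = _Node()
        node.length = dnode.edge.length
        if dnode.is_leaf():
            node.label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        else:
            node.label = dnode.label
            node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        root = convert(dtree.seed_node)
    finally:
        sys.setrecursionlimit(old)
    return Tree._from_builder(root)


def write_newick(tree: Tree) -> str:
    """Serialize a :class:`Tree` to Newick.

    The round trip ``parse_newick(write_newick(t))`` reproduces topology,
    labels and branch lengths.  Synthesized internal labels are not emitted
    (re-parsing regenerates them identically).
    """
    parts: dict[int, str] = {}
    for i in tree.postorder():
        if tree.is_leaf(i):
            s = _escape(tree.label(i))
        else:
            inner = ",".join(parts[c] for c in tree.children(i))
            lab = "" if tree._auto_label[i] else _escape(tree.label(i))
            s = f"({inner}){lab}"
        length = tree.branch_length(i)
        if length is not None:
            s += f":{length:.10g}"
        parts[i] = s
    return parts[tree.root] + ";"


def tree_from_linkage(
    dissimilarity,
    linkage_method: str = "complete",
    labels: Sequence[str] | None = None,
) -> Tree:
    """Agglomerate a dissimilarity matrix into a binary dendrogram tree.

    Parameters
    ----------
    dissimilarity
        Square, symmetric, nonnegative matrix with zero diagonal; a labeled
        ``pandas.DataFrame`` supplies item labels via its index.
    linkage_method
        Any method accepted by :func:`scipy.cluster.hierarchy.linkage`.
    labels
        Item labels; defaults to the DataFrame index or ``item_1..item_n``.

    The result has ``K`` leaves and ``M = 2K - 1`` nodes; each node's branch
    length is the merge-height difference to its parent.
    """
    from scipy.cluster.hierarchy import linkage, to_tree
    from scipy.spatial.distance import squareform

    if isinstance(dissimilarity, pd.DataFrame):
        if labels is None:
            labels = [str(x) for x in dissimilarity.index]
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise TreeError("dissimilarity must be a square matrix")
    n = d.shape[0]
    if n < 2:
        raise TreeError("need at least 2 items")
    if not np.allclose(d, d.T, rtol=1e-8, atol=1e-12):
        raise TreeError("dissimilarity matrix must be symmetric")
    if (d < 0).any():
        raise TreeError("dissimilarity entries must be nonnegative")
    if not np.allclose(np.diag(d), 0.0):
        raise TreeError("dissimilarity diagonal must be zero")
    if labels is None:
        labels = [f"item_{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise TreeError("labels must match matrix size")

    Z = linkage(squareform(d, checks=False), method=linkage_method)
    root = to_tree(Z)

    def convert(cnode, parent_height: float | None) -> _Node:
        node = _Node()
        if parent_height is not None:
            node.length = max(0.0, parent_height - cnode.dist)
        if cnode.is_leaf():
            node.label = str(labels[cnode.id])
        else:
            node.children = [
                convert(cnode.get_left(), cnode.dist),
                convert(cnode.get_right(), cnode.dist),
            ]
        return node

    return Tree._from_builder(convert(root, None))


# ------------------------------------------------------------ free functions


def descendant_leaves(tree: Tree, i: int) -> frozenset[int]:
    """b(i) — see :meth:`Tree.descendant_leaves`."""
    return tree.descendant_leaves(i)


def branch_set(tree: Tree, i: int) -> frozenset[int]:
    """B(i) — see :meth:`Tree.branch_set`."""
    return tree.branch_set(i)
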