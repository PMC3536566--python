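"""Vectorization of phylogenetic trees via dissimilarity maps.

A tree with ``n`` leaves is mapped to a point in ``R^m``, ``m = n(n-1)/2``,
by listing the leaf-to-leaf path lengths (the *dissimilarity map*) or the
leaf-to-leaf edge counts (the *topological dissimilarity map*) in
lexicographic order over taxon pairs ``[(1,2), (1,3), ..., (n-1,n)]``.
Both maps depend only on the unrooted weighted topology, so rooted inputs
are treated as unrooted: a degree-2 root contributes a single edge to the
paths that cross it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "TaxonOrder",
    "TreeVector",
    "dissimilarity_vector",
    "topological_vector",
    "vectorize_trees",
    "pair_labels",
]


@dataclass(frozen=True)
class TaxonOrder:
    """A fixed ordering of taxon labels shared by all trees in an analysis.

    The ordering determines which coordinate of a :class:`TreeVector`
    corresponds to which leaf pair.  Any fixed order yields an equivalent
    test (the SVM statistic is invariant to a coordinate permutation applied
    to both samples); by default labels are sorted lexicographically so the
    vectors are deterministic across runs.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("taxon labels must be distinct")
        if len(self.labels) < 3:
            raise ValueError("need at least 3 taxa to vectorize trees")

    @classmethod
    def from_labels(cls, labels: Iterable[str], sort: bool = True) -> "TaxonOrder":
        labels = list(labels)
        if sort:
            labels = sorted(labels)
        return cls(tuple(labels))

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "TaxonOrder":
        return cls.from_labels(leaf_labels(tree))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_pairs(self) -> int:
        n = len(self.labels)
        return n * (n - 1) // 2


@dataclass(frozen=True)
class TreeVector:
    """A tree flattened to a point in ``R^{n(n-1)/2}``."""

    values: np.ndarray
    order: TaxonOrder
    map_kind: str  # "branch-length" | "topological"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.order.n_pairs,):
            raise ValueError(
                f"vector length {vals.shape} does not match "
                f"{self.order.n_pairs} taxon pairs"
            )
        if np.any(vals < 0):
            raise ValueError("dissimilarity entries must be non-negative")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def pair_labels(order: TaxonOrder) -> list[str]:
    """Names of the vector coordinates, e.g. ``a|b``, in lexicographic pair order."""
    labs = order.labels
    return [f"{labs[i]}|{labs[j]}" for i in range(len(labs)) for j in range(i + 1, len(labs))]


def _check_labels(tree: dendropy.Tree, order: TaxonOrder) -> None:
    tree_labels = set(leaf_labels(tree))
    want = set(order.labels)
    if tree_labels != want:
        missing = sorted(want - tree_labels)
        extra = sorted(tree_labels - want)
        raise ValueError(
            f"tree taxa do not match the taxon order; missing={missing}, unexpected={extra}"
        )


def _path_matrices(tree: dendropy.Tree, order: TaxonOrder) -> tuple[np.ndarray, np.ndarray]:
    """Leaf-to-leaf path-length sums and edge counts, unrooted convention.

    Single postorder sweep: each visited node carries, for every leaf below
    it, the path length and edge count up to the node; pairs are emitted when
    two subtrees meet.  A bifurcating root is suppressed (one edge fewer on
    paths crossing it), matching the unrooted reading of the tree.
    """
    idx = order.index
    n = len(order)
    plen = np.zeros((n, n))
    ecnt = np.zeros((n, n))

    root = tree.seed_node
    # node -> {leaf index: (path length, edge count)} from that node down
    below: dict[int, dict[int, tuple[float, int]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            try:
                i = idx[node.taxon.label]
            except (AttributeError, KeyError):
                _check_labels(tree, order)
                raise
            below[id(node)] = {i: (0.0, 0)}
            continue
        children = node.child_nodes()
        # extra edges contributed by the junction at this node; a degree-2
        # root is a subdivision point of one unrooted edge, not a vertex
        root_fusion = node is root and len(children) == 2
        merged: dict[int, tuple[float, int]] = {}
        for child in children:
            bl = child.edge.length
            if bl is None:
                bl = 0.0
            if bl < 0:
                where = child.taxon.label if child.is_leaf() else "an internal node"
                raise ValueError(f"negative branch length {bl} on the edge above {where}")
            sub = below.pop(id(child))
            lifted = {i: (d + bl, e + 1) for i, (d, e) in sub.items()}
            for i, (di, ei) in lifted.items():
                for j, (dj, ej) in merged.items():
                    a, b = (i, j) if i < j else (j, i)
                    plen[a, b] = di + dj
                    ecnt[a, b] = ei + ej - (1 if root_fusion else 0)
            merged.update(lifted)
        below[id(node)] = merged
    return plen, ecnt


def _flatten_upper(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    iu = np.triu_indices(n, k=1)
    return mat[iu]


def dissimilarity_vector(tree: dendropy.Tree, order: TaxonOrder | None = None) -> TreeVector:
    """Map a tree to the vector of pairwise leaf path-length sums.

    Parameters
    ----------
    tree
        Leaf-labeled tree with non-negative branch lengths (missing lengths
        count as 0).
    order
        Fixed taxon order; defaults to the tree's labels sorted.
    """
    if order is None:
        order = TaxonOrder.from_tree(tree)
    _check_labels(tree, order)
    plen, _ = _path_matrices(tree, order)
    return TreeVector(_flatten_upper(plen), order, "branch-length")


def topological_vector(tree: dendropy.Tree, order: TaxonOrder | None = None) -> TreeVector:
    """Map a tree to the vector of pairwise leaf edge counts.

    Identical to :func:`dissimilarity_vector` applied to the same topology
    with every branch length set to 1.
    """
    if order is None:
        order = TaxonOrder.from_tree(tree)
    _check_labels(tree, order)
    _, ecnt = _path_matrices(tree, order)
    return TreeVector(_flatten_upper(ecnt), order, "topological")


def vectorize_trees(
    trees: Sequence[dendropy.Tree],
    order: TaxonOrder,
    map_kind: str = "topological",
) -> np.ndarray:
    """Stack a list of trees into a ``(len(trees), n(n-1)/2)`` float array."""
    if map_kind not in ("branch-length", "topological"):
        raise ValueError(f"unknown map_kind {map_kind!r}")
    out = np.empty((len(trees), order.n_pairs))
    pick = 0 if map_kind == "branch-length" else 1
    for k, tree in enumerate(trees):
        _check_labels(tree, order)
        mats = _path_matrices(tree, order)
        out[k] = _flatten_upper(mats[pick])
    return out


def vectors_to_table(vectors: Sequence[TreeVector]) -> "object":
    """Export vectors as a pandas DataFrame with taxon-pair column names."""
    import pandas as pd

    if not vectors:
        raise ValueError("no vectors to export")
    order = vectors[0].order
    for v in vectors:
        if v.order != order:
            raise ValueError("vectors use different taxon orders")
    return pd.DataFrame(
        np.stack([v.values for v in vectors]), columns=pair_labels(order)
    )
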