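"""Hierarchical clustering on a pseudo-distance with dendsort-style ordering.

Agglomerative clustering (complete / average / single linkage) with a
deterministic smallest-label-pair tie-break, a dendsort-style leaf
reordering (children sorted by minimum merge height within the subtree),
cluster extraction at a given k, and reordering of concordance matrices
by the sorted leaf order. The merge table follows the scipy linkage
convention: leaves are nodes 0..n-1 and the i-th merge creates node n+i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from txconcord.infoconcord import ConcordanceMatrix

__all__ = [
    "Dendrogram",
    "hierarchical_cluster",
    "dendsort_order",
    "ordered_matrix",
    "cut_clusters",
    "save_heatmap",
]

LINKAGES = ("complete", "average", "single")


@dataclass
class Dendrogram:
    """Merge tree over labelled leaves.

    ``merges`` is a list of (left_node, right_node, height) with nodes in
    scipy convention; ``leaf_order`` is the current left-to-right order
    of leaf labels.
    """

    merges: list[tuple[int, int, float]]
    leaf_labels: list[str]
    leaf_order: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_linkage_matrix(self) -> np.ndarray:
        """Scipy-compatible (n-1) x 4 linkage matrix."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for i, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + i] = size
            Z[i] = [a, b, h, size]
        return Z

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.leaf_labels[i] for i in range(n)}
        for i, (a, b, h) in enumerate(self.merges):
            la, lb = h - height[a], h - height[b]
            node[n + i] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[n + i] = h
        return node[n + len(self.merges) - 1] + ";"


def hierarchical_cluster(
    distance: pd.DataFrame, linkage: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering of a symmetric pseudo-distance matrix.

    At each step the pair of clusters with the smallest inter-cluster
    distance merges; exact ties are broken by the smallest (node, node)
    id pair. Inter-cluster distances follow the chosen linkage (complete
    = max, average = size-weighted mean, single = min).
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    labels = list(distance.index)
    D = distance.to_numpy(dtype=float)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if list(distance.columns) != labels:
        raise ValueError("distance matrix must have identical row/column labels")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12) or (np.diag(D) < 0).any():
        raise ValueError("distance matrix must have a zero diagonal")

    # active cluster id -> (size, current index into dist dict)
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best: tuple[int, int] | None = None
        best_d = np.inf
        for pair in sorted(dist):  # ascending id pairs => deterministic ties
            d = dist[pair]
            if d < best_d:
                best_d = d
                best = pair
        a, b = best
        merges.append((a, b, best_d))
        # Lance-Williams update against every other active cluster
        for c in active:
            if c in (a, b):
                continue
            da = dist[(min(a, c), max(a, c))]
            db = dist[(min(b, c), max(b, c))]
            if linkage == "complete":
                d_new = max(da, db)
            elif linkage == "single":
                d_new = min(da, db)
            else:
                d_new = (size[a] * da + size[b] * db) / (size[a] + size[b])
            dist[(c, next_id)] = d_new
        for pair in [p for p in dist if a in p or b in p]:
            del dist[pair]
        active -= {a, b}
        size[next_id] = size[a] + size[b]
        active.add(next_id)
        next_id += 1

    order = _traverse_order(merges, n)
    return Dendrogram(
        merges=merges,
        leaf_labels=labels,
        leaf_order=[labels[i] for i in order],
    )


def _traverse_order(merges, n: int) -> list[int]:
    children = {n + i: (a, b) for i, (a, b, _) in enumerate(merges)}
    out: list[int] = []
    stack = [n + len(merges) - 1]
    while stack:
        node = stack.pop()
        if node < n:
            out.append(node)
        else:
            a, b = children[node]
            stack.extend([b, a])
    return out


def dendsort_order(d: Dendrogram) -> Dendrogram:
    """Reorder children so tighter subtrees come first (dendsort-style).

    At each internal node the two children are sorted by key = minimum
    merge height within the child subtree (a leaf's key is +inf); key
    ties break by lexicographically smallest leaf label. Topology and
    heights are untouched; the output leaf order is invariant to the
    input's leaf ordering.
    """
    n = d.n_leaves
    children = {n + i: (a, b) for i, (a, b, _) in enumerate(d.merges)}
    height = {n + i: h for i, (_, _, h) in enumerate(d.merges)}

    min_h: dict[int, float] = {}
    min_label: dict[int, str] = {}

    def annotate(node: int) -> None:
        if node < n:
            min_h[node] = np.inf
            min_label[node] = d.leaf_labels[node]
            return
        a, b = children[node]
        annotate(a)
        annotate(b)
        min_h[node] = min(height[node], min_h[a], min_h[b])
        min_label[node] = min(min_label[a], min_label[b])

    root = n + len(d.merges) - 1
    annotate(root)

    order: list[int] = []

    def walk(node: int) -> None:
        if node < n:
            order.append(node)
            return
        a, b = children[node]
        if (min_h[b], min_label[b]) < (min_h[a], min_label[a]):
            a, b = b, a
        walk(a)
        walk(b)

    walk(root)
    return Dendrogram(
        merges=list(d.merges),
        leaf_labels=list(d.leaf_labels),
        leaf_order=[d.leaf_labels[i] for i in order],
    )


def ordered_matrix(c: ConcordanceMatrix | pd.DataFrame, d: Dendrogram) -> pd.DataFrame:
    """Reorder a (distance or correlation) matrix by the dendrogram's leaf order.

    Accepts a ConcordanceMatrix (its pseudo-distance is reordered) or any
    square labelled DataFrame.
    """
    mat = c.pseudo_distance if isinstance(c, ConcordanceMatrix) else c
    if set(mat.index) != set(d.leaf_order):
        raise ValueError("matrix labels do not match dendrogram leaves")
    return mat.loc[d.leaf_order, d.leaf_order]


def save_heatmap(matrix: pd.DataFrame, path, *, cmap: str = "viridis",
                 title: str | None = None) -> None:
    """Optional PNG heatmap of an (ordered) matrix.

    Rendering is a convenience; the ordered TSV remains the canonical,
    bit-exact output. Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(), cmap=cmap, aspect="equal")
    ax.set_xticks(range(len(matrix.columns)))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(matrix.index)))
    ax.set_yticklabels(matrix.index, fontsize=5)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cut_clusters(d: Dendrogram, k: int) -> dict[str, int]:
    """Cut the tree into exactly k clusters; label -> cluster id (1-based).

    Applies the first n-k merges (merge heights are non-decreasing for
    monotone linkages); cluster ids are assigned in order of each
    cluster's smallest leaf index, so the result is deterministic.
    """
    n = d.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    node_rep = {i: i for i in range(n)}  # tree node -> a member leaf
    for i, (a, b, _) in enumerate(d.merges[: n - k]):
        ra, rb = find(node_rep[a]), find(node_rep[b])
        parent[rb] = ra
        node_rep[n + i] = ra
    for i, (a, b, _) in enumerate(d.merges):
        if n + i not in node_rep:
            node_rep[n + i] = node_rep[a]

    roots: dict[int, int] = {}
    assign: dict[str, int] = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        assign[d.leaf_labels[leaf]] = roots[r]
    return assign
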