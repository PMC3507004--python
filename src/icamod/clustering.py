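"""Hierarchical clustering of gene signatures, Cluster 3.0 style.

Similarity is the *uncentered* correlation (cosine of the angle, no mean
subtraction — Cluster 3.0's "correlation (uncentered)") or the Pearson
correlation; distance is 1 - similarity; linkage is average (UPGMA).  Merges
are recorded on the similarity scale, and ties between equal-distance
candidate merges are broken by the lexicographically smallest
(min node id, max node id) pair so the merge sequence is deterministic
across platforms and input orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


class DegenerateInputError(ValueError):
    """A vector without the variation the similarity measure requires."""


@dataclass(frozen=True)
class Merge:
    """One agglomeration: ``node`` joins ``left`` and ``right`` at ``similarity``."""

    node: int
    left: int
    right: int
    similarity: float


@dataclass
class Dendrogram:
    """Merge tree over genes.

    Leaves are numbered 0..n-1 in ``leaves`` order; internal nodes n..2n-2 in
    merge order.  ``leaf_order`` is the left-to-right display order obtained
    by traversing the tree left-child-first.
    """

    leaves: list[str]
    merges: list[Merge]
    leaf_order: list[int]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}")
        sims = [m.similarity for m in self.merges]
        if any(b > a + 1e-9 for a, b in zip(sims, sims[1:])):
            raise ValueError("merge similarities must be non-increasing (no inversions)")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


@dataclass
class ClusterAssignment:
    """Flat gene -> cluster labeling; labels are contiguous ints from 0."""

    labels: dict[str, int]
    n_clusters: int

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(self.n_clusters)}
        for gid, c in self.labels.items():
            out[c].append(gid)
        return out


def uncentered_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Cosine of the angle between x and y (no mean-centering)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise DegenerateInputError("zero-norm vector has no direction")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def _similarity_matrix(values: np.ndarray, similarity: str, gene_ids: Sequence[str]) -> np.ndarray:
    if similarity == "uncentered":
        norms = np.linalg.norm(values, axis=1)
        bad = np.where(norms == 0)[0]
        if bad.size:
            raise DegenerateInputError(
                f"zero-norm signature rows for genes: {', '.join(gene_ids[i] for i in bad)}"
            )
        unit = values / norms[:, None]
        sim = unit @ unit.T
    elif similarity == "pearson":
        sds = values.std(axis=1)
        bad = np.where(sds == 0)[0]
        if bad.size:
            raise DegenerateInputError(
                f"constant signature rows for genes: {', '.join(gene_ids[i] for i in bad)}"
            )
        sim = np.corrcoef(values)
    else:
        raise ValueError(f"unknown similarity {similarity!r}")
    return np.clip(sim, -1.0, 1.0)


def hca(
    values: np.ndarray,
    gene_ids: Sequence[str],
    similarity: str = "uncentered",
    linkage: str = "average",
) -> Dendrogram:
    """Average-linkage agglomerative clustering on distance 1 - similarity.

    Uses the Lance-Williams update (the average of cluster-cross pair
    distances), which for UPGMA is exact.  Raises on a single row or on
    degenerate rows (named in the error).
    """
    if linkage != "average":
        raise ValueError(f"unsupported linkage {linkage!r}")
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    gene_ids = list(gene_ids)
    n = values.shape[0]
    if n != len(gene_ids):
        raise ValueError("row count does not match gene_ids")
    if n < 2:
        raise ValueError("need at least 2 genes to cluster")

    dist = 1.0 - _similarity_matrix(values, similarity, gene_ids)
    np.fill_diagonal(dist, np.inf)

    node_of_slot = np.arange(n)  # dendrogram node id occupying each matrix slot
    size = np.ones(n)
    merges: list[Merge] = []
    children: dict[int, tuple[int, int]] = {}

    for t in range(n - 1):
        dmin = dist.min()
        ii, jj = np.where(dist == dmin)
        best = None
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            na, nb = node_of_slot[a], node_of_slot[b]
            key = (min(na, nb), max(na, nb))
            if best is None or key < best[0]:
                best = (key, a, b)
        (lo, hi), a, b = best
        new_node = n + t
        merges.append(Merge(node=new_node, left=lo, right=hi, similarity=float(1.0 - dmin)))
        children[new_node] = (lo, hi)
        # Lance-Williams average-linkage update into slot a
        sa, sb = size[a], size[b]
        new_row = (sa * dist[a] + sb * dist[b]) / (sa + sb)
        dist[a, :] = new_row
        dist[:, a] = new_row
        dist[a, a] = np.inf
        dist[b, :] = np.inf
        dist[:, b] = np.inf
        size[a] = sa + sb
        node_of_slot[a] = new_node

    order: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            lo, hi = children[node]
            stack.append(hi)  # popped after lo: left-child-first traversal
            stack.append(lo)
    return Dendrogram(leaves=gene_ids, merges=merges, leaf_order=order)


def cut_tree(
    dendrogram: Dendrogram,
    n_clusters: int | None = None,
    min_similarity: float | None = None,
) -> ClusterAssignment:
    """Cut a dendrogram into flat clusters.

    Exactly one criterion must be given: ``n_clusters`` undoes the last
    (n_clusters - 1) merges; ``min_similarity`` applies every merge whose
    similarity is at or above the threshold.  Cluster labels are contiguous
    integers ordered by each cluster's smallest leaf index.
    """
    if (n_clusters is None) == (min_similarity is None):
        raise ValueError("give exactly one of n_clusters or min_similarity")
    n = dendrogram.n_leaves
    if n_clusters is not None:
        if not 1 <= n_clusters <= n:
            raise ValueError(f"n_clusters must be in [1, {n}]")
        applied = dendrogram.merges[: n - n_clusters]
    else:
        if not -1.0 <= min_similarity <= 1.0:
            raise ValueError("min_similarity must be in [-1, 1]")
        applied = [m for m in dendrogram.merges if m.similarity >= min_similarity]

    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for m in applied:
        root = find(m.left)
        parent[root] = m.node
        root = find(m.right)
        parent[root] = m.node
    groups: dict[int, list[int]] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(groups.values(), key=min)
    labels = {
        dendrogram.leaves[leaf]: c for c, leaves in enumerate(ordered) for leaf in leaves
    }
    return ClusterAssignment(labels=labels, n_clusters=len(ordered))
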