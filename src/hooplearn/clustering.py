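"""Prospective/retrospective dissimilarity and agglomerative Ward clustering.

The averaged learning matrix is asymmetric, so its rows and columns carry
different information: row ``i`` describes how outcomes in region ``i`` affect
all subsequent regions (prospective), column ``j`` how region ``j`` is
affected by outcomes everywhere (retrospective). Clustering the rows and the
columns separately asks whether the two notions of similarity agree.

Ward's linkage is used throughout: the distance between clusters A and B is

    d(A, B) = sqrt(2 n_A n_B / (n_A + n_B)) * ||c_A - c_B||

with centroids c and Euclidean norm; for singletons this reduces to the plain
Euclidean distance, so the dendrogram heights start on the same scale as the
dissimilarity matrix. A squared variant (same merge order, squared heights) is
available via ``form="squared"``. Minimum-distance ties are broken by the
lexicographically smallest pair of cluster ids, making output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

PROSPECTIVE = "PROSPECTIVE"
RETROSPECTIVE = "RETROSPECTIVE"


@dataclass
class DissimilarityMatrix:
    """Symmetric Euclidean distances between labeled vectors."""

    values: np.ndarray
    labels: tuple

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def reordered(self, order: Sequence[int]) -> "DissimilarityMatrix":
        order = list(order)
        return DissimilarityMatrix(
            self.values[np.ix_(order, order)], tuple(self.labels[i] for i in order)
        )


def row_dissimilarity(agg, axis: str = PROSPECTIVE, include_self: bool = True) -> DissimilarityMatrix:
    """Euclidean distances between rows (PROSPECTIVE) or columns (RETROSPECTIVE).

    ``agg`` is an :class:`~hooplearn.learning.AggregateLearning` or a plain
    labeled matrix (``values``/``labels`` attributes or a bare ndarray with
    integer labels). With ``include_self=False`` the self-coordinates (the
    diagonal entries) are dropped from each vector before computing distances.
    """
    if hasattr(agg, "labels"):
        values = agg.mean if hasattr(agg, "sem") else agg.values
        labels = tuple(agg.labels)
    else:
        values = np.asarray(agg, dtype=float)
        labels = tuple(range(1, values.shape[0] + 1))
    M = np.asarray(values, dtype=float)
    if np.isnan(M).any():
        raise ValueError("dissimilarity requires a complete matrix (no invalid entries)")
    V = M if axis == PROSPECTIVE else M.T
    if axis not in (PROSPECTIVE, RETROSPECTIVE):
        raise ValueError(f"unknown axis: {axis!r}")
    if not include_self:
        n = V.shape[0]
        V = np.array([np.delete(V[i], i) for i in range(n)])
    D = squareform(pdist(V, metric="euclidean"))
    return DissimilarityMatrix(D, labels)


@dataclass
class Dendrogram:
    """Agglomerative merge tree.

    Leaves are numbered 0..n-1 (with display ``labels``); merge ``t`` joins
    cluster ids ``a`` and ``b`` at ``height`` into new cluster id ``n + t``.
    Ward linkage guarantees non-decreasing heights.
    """

    labels: tuple
    merges: list[tuple[int, int, float, int]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def members(self) -> dict[int, frozenset[int]]:
        """Cluster id -> leaf indices, for every cluster ever formed."""
        out = {i: frozenset([i]) for i in range(self.n_leaves)}
        for a, b, _, new in self.merges:
            out[new] = out[a] | out[b]
        return out

    def to_linkage(self) -> np.ndarray:
        """SciPy linkage-format array (for plotting / cross-checks)."""
        members = self.members()
        Z = np.zeros((len(self.merges), 4))
        for t, (a, b, h, new) in enumerate(self.merges):
            Z[t] = [a, b, h, len(members[new])]
        return Z

    def leaf_order(self) -> list[int]:
        """Display order of leaves: recursive, smaller cluster first."""
        members = self.members()

        def expand(cid: int) -> list[int]:
            if cid < self.n_leaves:
                return [cid]
            a, b = next((m[0], m[1]) for m in self.merges if m[3] == cid)
            fa, fb = expand(a), expand(b)
            return fa + fb if len(fa) <= len(fb) else fb + fa

        return expand(self.merges[-1][3]) if self.merges else list(range(self.n_leaves))

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences to the parent merge."""
        height_of = {i: 0.0 for i in range(self.n_leaves)}
        node = {i: str(self.labels[i]) for i in range(self.n_leaves)}
        for a, b, h, new in self.merges:
            la = h - height_of[a]
            lb = h - height_of[b]
            node[new] = f"({node[a]}:{la:.10g},{node[b]}:{lb:.10g})"
            height_of[new] = h
        root = self.merges[-1][3] if self.merges else 0
        return node[root] + ";"

    def cut(self, k: int) -> list[set]:
        return cut_clusters(self, k)


def _pair_distance(size_a, cent_a, size_b, cent_b, form: str) -> float:
    gap = float(np.linalg.norm(cent_a - cent_b))
    w = 2.0 * size_a * size_b / (size_a + size_b)
    return np.sqrt(w) * gap if form == "sqrt" else w * gap * gap


def ward_cluster(vectors, labels: Sequence | None = None, form: str = "sqrt") -> Dendrogram:
    """Agglomerative Ward clustering of labeled vectors.

    At each step the active cluster pair with minimal Ward distance is merged;
    exact ties go to the smallest (a, b) id pair. Centroids are recomputed
    from members at every step (O(n^3) overall — intended for region-scale
    inputs, not large n).
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two vectors of equal dimension")
    if form not in ("sqrt", "squared"):
        raise ValueError(f"unknown Ward form: {form!r}")
    n = X.shape[0]
    if labels is None:
        labels = tuple(range(n))
    labels = tuple(labels)
    if len(labels) != n:
        raise ValueError("labels/vectors length mismatch")

    sizes = {i: 1 for i in range(n)}
    cents = {i: X[i].astype(float) for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                d = _pair_distance(sizes[a], cents[a], sizes[b], cents[b], form)
                if best is None or d < best[0] or (d == best[0] and (a, b) < best[1:]):
                    best = (d, a, b)
        d, a, b = best
        new = n + step
        cents[new] = (sizes[a] * cents[a] + sizes[b] * cents[b]) / (sizes[a] + sizes[b])
        sizes[new] = sizes[a] + sizes[b]
        active -= {a, b}
        active.add(new)
        merges.append((a, b, d, new))
    return Dendrogram(labels, merges)


def cut_clusters(tree: Dendrogram, k: int) -> list[set]:
    """Partition the leaves into ``k`` groups by removing the k-1 highest merges.

    Ward heights are monotone, so this keeps the first ``n - k`` merges.
    Returns label sets sorted by each group's smallest leaf index.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    parent = list(range(n + len(tree.merges)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b, _, new in tree.merges[: n - k]:
        parent[find(a)] = new
        parent[find(b)] = new
    groups: dict[int, set] = {}
    first: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        groups.setdefault(root, set()).add(tree.labels[leaf])
        first.setdefault(root, leaf)
    return [groups[r] for r in sorted(groups, key=lambda r: first[r])]
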