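"""Two-way agglomerative clustering of the binary mutation matrix.

Tumours (rows) and alterations (columns) are clustered on the complete-case
binary matrix with a binary dissimilarity (Hamming mismatch fraction or
Jaccard on the altered sets) and average or complete linkage.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

__all__ = ["Dendrogram", "binary_distance", "cluster", "cut"]


@dataclasses.dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy linkage matrix plus item labels."""

    linkage: np.ndarray             # (n-1, 4) scipy format
    items: tuple[str, ...]
    metric: str
    linkage_method: str

    @property
    def n(self) -> int:
        return len(self.items)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> tuple[str, ...]:
        order = sch.leaves_list(self.linkage)
        return tuple(self.items[i] for i in order)

    def validate(self) -> None:
        if self.linkage.shape != (self.n - 1, 4):
            raise ValueError("wrong number of merges")
        if (np.diff(self.heights) < -1e-12).any():
            raise ValueError("merge heights not monotone non-decreasing")


def binary_distance(x, y, metric: str = "hamming") -> float:
    """Dissimilarity of two binary vectors.

    ``hamming`` = mismatch fraction; ``jaccard`` = 1 − |x∩y| / |x∪y| over the
    altered positions, defined as 0 when both vectors are all-zero.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if metric == "hamming":
        return float(np.mean(x != y))
    if metric == "jaccard":
        union = np.sum((x == 1) | (y == 1))
        if union == 0:
            return 0.0
        inter = np.sum((x == 1) & (y == 1))
        return float(1 - inter / union)
    raise ValueError(f"unknown metric {metric!r}")


def cluster(matrix, metric: str = "hamming",
            linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of the rows of a binary matrix.

    Deterministic for fixed input (scipy's nearest-neighbour chain
    tie-handling).  Rows with missing entries must be removed beforehand
    (the cohort accessor drops them).
    """
    if isinstance(matrix, pd.DataFrame):
        if matrix.isna().any().any():
            raise ValueError("matrix must be complete cases")
        items = tuple(str(i) for i in matrix.index)
        arr = matrix.to_numpy(dtype=float)
    else:
        arr = np.asarray(matrix, dtype=float)
        items = tuple(f"item{i}" for i in range(arr.shape[0]))
    if arr.shape[0] < 2:
        raise ValueError("need at least two items")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if metric not in ("hamming", "jaccard"):
        raise ValueError(f"unknown metric {metric!r}")
    # canonicalize row order so the tree depends only on the data multiset,
    # not on input order (distance ties are common on binary data); leaf ids
    # are then mapped back so labels align with the caller's row order
    perm = np.lexsort(arr.T[::-1])
    dists = ssd.pdist(arr[perm], metric=metric)
    dists = np.nan_to_num(dists, nan=0.0)   # scipy jaccard: 0/0 -> 0 convention
    Z = sch.linkage(dists, method=linkage)
    n = arr.shape[0]
    leaves = Z[:, :2]
    leaf_mask = leaves < n
    leaves[leaf_mask] = perm[leaves[leaf_mask].astype(int)]
    d = Dendrogram(Z, items, metric, linkage)
    d.validate()
    return d


def cut(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Partition into k clusters by removing the k−1 highest merges.

    Returns integer labels (1..k) indexed by item; deterministic.
    """
    if not 1 <= k <= dendrogram.n:
        raise ValueError(f"k must be in [1, {dendrogram.n}]")
    labels = sch.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=list(dendrogram.items), name="cluster")
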