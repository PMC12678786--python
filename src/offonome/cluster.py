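"""Ward clustering of offonome matrices and cluster-label agreement.

Both the continuous LSS matrix and the binarized 0/1 state matrix can be
clustered, on either axis, with Ward's minimum-variance linkage on
Euclidean distances (the metric Ward's criterion requires).  Sample
clusters are scored against known labels (e.g. tumor types) by the
classification rate: each cluster takes its majority label and the rate is
the fraction of samples so explained.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

__all__ = [
    "ClusterResult",
    "LabelledAssignment",
    "ClassificationResult",
    "ward_cluster",
    "cut_clusters",
    "classification_rate",
]


@dataclass
class ClusterResult:
    """Ward linkage over one axis of a genes x samples matrix."""

    axis: str
    ids: tuple[str, ...]
    linkage: np.ndarray  # scipy (n-1) x 4 merge tree
    leaf_order: np.ndarray
    method: str = "ward"
    metric: str = "euclidean"


@dataclass
class LabelledAssignment:
    sample_ids: tuple[str, ...]
    cluster_id: tuple[int, ...]
    true_label: tuple[str, ...]

    def __post_init__(self) -> None:
        if not len(self.sample_ids) == len(self.cluster_id) == len(self.true_label):
            raise ValueError("sample_ids, cluster_id and true_label must align")
        if len(self.sample_ids) == 0:
            raise ValueError("assignment is empty")


@dataclass
class ClassificationResult:
    rate: float  # raw percentage
    rate_rounded: int
    majority_label: dict[int, str]
    ties: tuple[int, ...] = field(default_factory=tuple)


def _as_items(matrix, axis: str) -> tuple[np.ndarray, tuple[str, ...]]:
    """Rows = items to cluster on the requested axis."""
    if hasattr(matrix, "to_frame"):
        matrix = matrix.to_frame()
    if isinstance(matrix, pd.DataFrame):
        if axis == "samples":
            return matrix.to_numpy(dtype=float).T, tuple(matrix.columns)
        return matrix.to_numpy(dtype=float), tuple(matrix.index)
    arr = np.asarray(matrix, dtype=float)
    if axis == "samples":
        arr = arr.T
    return arr, tuple(str(i) for i in range(arr.shape[0]))


def ward_cluster(matrix, axis: str = "samples") -> ClusterResult:
    """Agglomerative Ward linkage on Euclidean distances over one axis.

    ``matrix`` may be an LSSMatrix, OnOffMatrix, DataFrame (genes x
    samples) or plain array.  Deterministic given the input; a constant
    matrix yields zero merge heights.
    """
    if axis not in ("samples", "genes"):
        raise ValueError("axis must be 'samples' or 'genes'")
    items, ids = _as_items(matrix, axis)
    if items.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.isfinite(items).all():
        raise ValueError("matrix contains NaN or infinite values")
    Z = linkage(items, method="ward", metric="euclidean")
    return ClusterResult(axis=axis, ids=ids, linkage=Z, leaf_order=leaves_list(Z))


def cut_clusters(result: ClusterResult, k: int) -> dict[str, int]:
    """The k groups obtained by removing the k-1 highest merges.

    Cluster ids are contiguous from 1, assigned in dendrogram leaf order.
    """
    n = len(result.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    raw = fcluster(result.linkage, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for leaf in result.leaf_order:
        if raw[leaf] not in relabel:
            relabel[raw[leaf]] = len(relabel) + 1
    return {result.ids[i]: relabel[raw[i]] for i in range(n)}


def classification_rate(assignment: LabelledAssignment) -> ClassificationResult:
    """Majority-label accuracy of unsupervised clusters, as a percentage.

    Each cluster is assigned its most frequent true label (ties resolved
    toward the alphabetically first label and flagged); the rate is the
    summed majority counts over the total sample count, x100.
    """
    clusters = sorted(set(assignment.cluster_id))
    majority: dict[int, str] = {}
    ties: list[int] = []
    correct = 0
    for c in clusters:
        labels = [l for cid, l in zip(assignment.cluster_id, assignment.true_label) if cid == c]
        counts = Counter(labels)
        best = max(counts.values())
        winners = sorted(l for l, v in counts.items() if v == best)
        if len(winners) > 1:
            ties.append(c)
        majority[c] = winners[0]
        correct += best
    rate = correct / len(assignment.sample_ids) * 100.0
    return ClassificationResult(
        rate=rate,
        rate_rounded=int(round(rate)),
        majority_label=majority,
        ties=tuple(ties),
    )
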