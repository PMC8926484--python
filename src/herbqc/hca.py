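"""Hierarchical cluster analysis of batches.

Batches are clustered on their common-peak areas or on a derived scalar
(e.g. the macro-quantitative similarity P_m).  Defaults follow the common
statistical-package convention of squared Euclidean distance with
between-groups (average) linkage; both are configurable.  The meaningful
contract is cluster membership at a chosen cut, not merge heights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DomainError, ValidationError

_METRICS = {"sq_euclidean": "sqeuclidean", "euclidean": "euclidean"}
_LINKAGES = ("average", "ward", "complete")


@dataclass
class Dendrogram:
    """Agglomeration history: (cluster-a, cluster-b, height) per merge.

    Cluster indices follow the scipy convention: leaves are 0..n−1 and the
    cluster formed by merge m gets index n+m.
    """

    merge_history: list[tuple[int, int, float]]
    leaf_labels: list[str]
    linkage_matrix: np.ndarray      # scipy (n−1, 4) linkage matrix

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)


def cluster(
    matrix: np.ndarray | Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    distance: str = "sq_euclidean",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of the rows of ``matrix``.

    Ward linkage requires plain Euclidean distances and rejects the squared
    metric.  1-D inputs (one variable per batch) may be passed as a flat
    sequence.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.ndim != 2:
        raise DomainError("matrix must be 1-D or 2-D")
    n = X.shape[0]
    if n < 2:
        raise ValidationError(f"need >= 2 rows to cluster, got {n}")
    if np.any(~np.isfinite(X)):
        raise ValidationError("matrix contains missing or non-finite values")
    if distance not in _METRICS:
        raise DomainError(f"distance must be one of {sorted(_METRICS)}")
    if linkage not in _LINKAGES:
        raise DomainError(f"linkage must be one of {_LINKAGES}")
    if linkage == "ward" and distance != "euclidean":
        raise DomainError("ward linkage requires the euclidean distance")

    d = pdist(X, metric=_METRICS[distance])
    Z = hierarchy.linkage(d, method=linkage)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    if labels is None:
        labels = [str(i + 1) for i in range(n)]
    return Dendrogram(
        merge_history=merges,
        leaf_labels=[str(l) for l in labels],
        linkage_matrix=Z,
    )


def cut(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Assign each batch to one of k clusters.

    Cluster labels are renumbered 1..k by first appearance in leaf order,
    so assignments are stable under internal relabeling.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise DomainError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.fcluster(dendrogram.linkage_matrix, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for label, r in zip(dendrogram.leaf_labels, raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        out[label] = relabel[r]
    return out
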