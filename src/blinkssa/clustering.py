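"""Unsupervised grouping of trajectory-matrix windows and per-cluster reconstruction.

k-means assigns each lagged window (a column of the trajectory matrix,
represented by its 4-D feature vector) to one of L clusters.  Splitting the
trajectory matrix column-wise by cluster and diagonal-averaging each part
decomposes the input signal into L additive components: because the column
partition is exact and diagonal averaging is linear, the components always
sum back to the original signal.

The clustering backend is pluggable (any callable mapping points to labels);
only seeded k-means (k-means++ init, 10 restarts, scikit-learn) ships.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.cluster import KMeans

from .errors import DegenerateClusteringError
from .features import FeatureMatrix
from .ssa import Signal1D, TrajectoryMatrix, diagonal_average

__all__ = [
    "ClusterAssignment",
    "kmeans_cluster",
    "partition_matrix",
    "reconstruct_components",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """Window-to-cluster labels (0-based, in {0..L-1}) for K windows."""

    labels: np.ndarray
    n_clusters: int
    seed: int

    def __post_init__(self) -> None:
        labels = np.array(self.labels, dtype=np.intp, copy=True).ravel()
        if labels.size == 0:
            raise ValueError("empty label vector")
        if labels.min() < 0 or labels.max() >= self.n_clusters:
            raise ValueError(
                f"labels must lie in [0, {self.n_clusters}); got range "
                f"[{labels.min()}, {labels.max()}]"
            )
        labels.flags.writeable = False
        object.__setattr__(self, "labels", labels)

    @property
    def n_windows(self) -> int:
        return int(self.labels.size)


ClusterBackend = Callable[[np.ndarray, int, int], np.ndarray]
"""Pluggable backend: (points [K x d], n_clusters, seed) -> labels [K]."""


def _kmeans_backend(points: np.ndarray, n_clusters: int, seed: int) -> np.ndarray:
    model = KMeans(
        n_clusters=n_clusters, init="k-means++", n_init=10, random_state=seed
    )
    return model.fit_predict(points)


def kmeans_cluster(
    features: FeatureMatrix,
    n_clusters: int,
    seed: int,
    backend: ClusterBackend = _kmeans_backend,
) -> ClusterAssignment:
    """Cluster the K feature columns into ``n_clusters`` groups.

    Deterministic given (features, n_clusters, seed): k-means++ with 10
    restarts and a fixed random state, best within-cluster sum of squares
    kept.

    Raises
    ------
    DegenerateClusteringError
        If there are fewer distinct feature columns than clusters.
    """
    points = features.values.T
    k = points.shape[0]
    if not 1 <= n_clusters <= k:
        raise ValueError(f"n_clusters {n_clusters} outside [1, {k}]")
    n_distinct = np.unique(points, axis=0).shape[0]
    if n_clusters > n_distinct:
        raise DegenerateClusteringError(
            f"{n_clusters} clusters requested but only {n_distinct} distinct "
            "feature columns"
        )
    labels = np.asarray(backend(points, n_clusters, seed))
    return ClusterAssignment(labels=labels, n_clusters=n_clusters, seed=seed)


def partition_matrix(
    trajectory: TrajectoryMatrix, assignment: ClusterAssignment, cluster: int
) -> TrajectoryMatrix:
    """Column partition: keep the columns labelled ``cluster``, zero the rest."""
    if not 0 <= cluster < assignment.n_clusters:
        raise IndexError(
            f"cluster {cluster} outside [0, {assignment.n_clusters})"
        )
    if assignment.n_windows != trajectory.n_windows:
        raise ValueError("assignment length does not match trajectory columns")
    values = np.where(assignment.labels == cluster, trajectory.values, 0.0)
    return TrajectoryMatrix(values=values, source_length=trajectory.source_length)


def reconstruct_components(
    trajectory: TrajectoryMatrix,
    assignment: ClusterAssignment,
    fs: float = 1.0,
) -> list[Signal1D]:
    """Diagonal-average each cluster's partition into a length-N component.

    The L components sum to the source signal exactly (up to float
    accumulation): the column partition is exhaustive and diagonal
    averaging is linear.  Empty clusters give all-zero components.
    """
    return [
        Signal1D(
            diagonal_average(partition_matrix(trajectory, assignment, i)), fs
        )
        for i in range(assignment.n_clusters)
    ]
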