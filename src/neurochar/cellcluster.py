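"""Nested dimensionality reduction and clustering of cell-model features.

Three levels over a prepared (complete, transformed, standardized)
feature matrix: density clustering (HDBSCAN, minimum cluster size 10) on
PCA scores retaining 95% of variance at levels 1 and 2, then K-means with
the cluster count chosen by silhouette score over k = 2..10 at level 3.
Levels 2 and 3 recurse into the largest cluster of the level above, with
the PCA refit on that subset.  Points HDBSCAN flags as noise are
reassigned to the cluster whose geometric center (arithmetic mean of
member scores) is nearest in PCA space, so every model ends up labeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.cluster import HDBSCAN, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

__all__ = [
    "PCAModel",
    "pca_reduce",
    "cluster_density",
    "cluster_kmeans_silhouette",
    "assign_noise",
    "ClusterLevel",
    "ClusterTree",
    "run_nested_clustering",
    "correlate_within_cluster",
]


@dataclass(frozen=True, eq=False)
class PCAModel:
    """Retained principal components of one PCA fit."""

    component_loadings: np.ndarray          # (n_retained, n_features)
    explained_variance_fractions: np.ndarray
    n_retained: int
    variance_threshold: float
    _pca: PCA = field(repr=False)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return self._pca.transform(np.asarray(x, float))


def pca_reduce(
    matrix, variance_threshold: float = 0.95
) -> tuple[PCAModel, np.ndarray]:
    """PCA keeping the smallest component count whose cumulative explained
    variance reaches the threshold; returns the model and the scores."""
    x = np.asarray(matrix, float)
    if x.shape[0] < 2:
        raise ValueError("PCA requires at least 2 rows")
    pca = PCA(n_components=variance_threshold, svd_solver="full")
    scores = pca.fit_transform(x)
    model = PCAModel(
        component_loadings=pca.components_,
        explained_variance_fractions=pca.explained_variance_ratio_,
        n_retained=int(pca.n_components_),
        variance_threshold=variance_threshold,
        _pca=pca,
    )
    return model, scores


def cluster_density(scores: np.ndarray, min_cluster_size: int = 10) -> np.ndarray:
    """HDBSCAN labels over PCA scores; -1 flags noise points.

    A sample in which no density cluster at all is found (one homogeneous
    blob) is returned as a single cluster rather than all-noise.
    """
    scores = np.asarray(scores, float)
    if scores.shape[0] < min_cluster_size:
        raise ValueError(
            f"need at least min_cluster_size={min_cluster_size} rows, "
            f"got {scores.shape[0]}"
        )
    labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(scores)
    if (labels == -1).all():
        return np.zeros(scores.shape[0], dtype=int)
    return labels


def cluster_kmeans_silhouette(
    scores: np.ndarray,
    k_range=range(2, 11),
    seed: int = 0,
    n_init: int = 10,
) -> tuple[np.ndarray, int, dict[int, float]]:
    """K-means for each k in range; keep the k with the largest mean
    silhouette score.  Seeded initialization with multiple restarts."""
    scores = np.asarray(scores, float)
    if np.allclose(scores, scores[0]):
        raise ValueError("degenerate data: all rows identical")
    by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if k >= scores.shape[0]:
            continue
        km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
        labels = km.fit_predict(scores)
        if np.unique(labels).size < 2:
            continue
        by_k[k] = float(silhouette_score(scores, labels))
        labels_by_k[k] = labels
    if not by_k:
        raise ValueError("no valid k produced a silhouette score")
    best_k = max(by_k, key=by_k.get)
    return labels_by_k[best_k], best_k, by_k


def assign_noise(noise_points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Label each noise point with its nearest center (Euclidean); ties
    break toward the lowest cluster index."""
    centers = np.atleast_2d(np.asarray(centers, float))
    if centers.shape[0] == 0:
        raise ValueError("no cluster centers to assign noise points to")
    pts = np.atleast_2d(np.asarray(noise_points, float))
    if pts.size == 0:
        return np.array([], dtype=int)
    d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
    return np.argmin(d, axis=1)


def _cluster_centers(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels[labels >= 0])
    return np.vstack([scores[labels == i].mean(axis=0) for i in ids])


def _density_level(
    scores: np.ndarray, min_cluster_size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One HDBSCAN level with noise reassignment.

    Returns (final labels, pre-reassignment noise mask, centers).  If
    everything is noise, the level degenerates to a single cluster.
    """
    raw = cluster_density(scores, min_cluster_size)
    noise = raw == -1
    labels = raw.copy()
    if (labels >= 0).sum() == 0:
        return np.zeros(scores.shape[0], int), noise, scores.mean(axis=0, keepdims=True)
    centers = _cluster_centers(scores, labels)
    if noise.any():
        labels[noise] = assign_noise(scores[noise], centers)
    return labels, noise, centers


@dataclass(frozen=True, eq=False)
class ClusterLevel:
    """One level of the nested analysis, over one row subset."""

    row_indices: np.ndarray        # indices into the full matrix
    labels: np.ndarray             # final labels (noise reassigned)
    noise_mask: np.ndarray | None  # pre-reassignment noise flags (None: K-means)
    centers: np.ndarray            # geometric centers in this level's PCA space
    pca: PCAModel
    scores: np.ndarray
    method: str                    # "hdbscan" | "kmeans"
    chosen_k: int | None = None
    silhouette_by_k: dict | None = None

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


@dataclass(frozen=True, eq=False)
class ClusterTree:
    """Three-level nested cluster assignment.

    ``assignments`` has one row per model with columns ``level1``,
    ``level2``, ``level3`` (-1 where a model is outside the recursed
    branch) and a ``final`` leaf label covering 100% of models.
    """

    levels: list            # [ClusterLevel, ...] (1 to 3 entries)
    assignments: pd.DataFrame


def _largest_cluster(labels: np.ndarray) -> int:
    ids, counts = np.unique(labels, return_counts=True)
    return int(ids[np.argmax(counts)])


def run_nested_clustering(
    matrix,
    variance_threshold: float = 0.95,
    min_cluster_size: int = 10,
    k_range=range(2, 11),
    seed: int = 0,
    recurse_into: int | None = None,
) -> ClusterTree:
    """The full nested analysis over a prepared feature matrix.

    Level 1: PCA + HDBSCAN over all models.  Level 2: PCA refit on the
    largest level-1 cluster (or ``recurse_into`` when given), HDBSCAN
    again.  Level 3: PCA refit on the largest level-2 cluster, K-means
    with silhouette-selected k.  Recursion stops early at any level that
    yields fewer than two clusters or a subset too small to cluster.
    """
    x = np.asarray(matrix, float)
    n = x.shape[0]
    index = (
        matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(n)
    )
    levels: list[ClusterLevel] = []
    assign = pd.DataFrame(
        {"level1": -1, "level2": -1, "level3": -1}, index=index
    )

    # ----- level 1
    pca1, scores1 = pca_reduce(x, variance_threshold)
    labels1, noise1, centers1 = _density_level(scores1, min_cluster_size)
    rows1 = np.arange(n)
    levels.append(
        ClusterLevel(rows1, labels1, noise1, centers1, pca1, scores1, "hdbscan")
    )
    assign["level1"] = labels1

    def _final(depth: int) -> pd.DataFrame:
        parts = []
        cols = ["level1", "level2", "level3"][:depth]
        for _, row in assign[cols].iterrows():
            path = [str(v) for v in row if v >= 0]
            parts.append("L" + str(len(path)) + ":" + ".".join(path))
        assign["final"] = parts
        return assign

    target1 = (
        recurse_into if recurse_into is not None else _largest_cluster(labels1)
    )
    subset2 = np.flatnonzero(labels1 == target1)
    if levels[0].n_clusters < 2 or subset2.size <= min_cluster_size:
        return ClusterTree(levels, _final(1))

    # ----- level 2: PCA refit within the subset
    pca2, scores2 = pca_reduce(x[subset2], variance_threshold)
    labels2, noise2, centers2 = _density_level(scores2, min_cluster_size)
    levels.append(
        ClusterLevel(subset2, labels2, noise2, centers2, pca2, scores2, "hdbscan")
    )
    assign.iloc[subset2, assign.columns.get_loc("level2")] = labels2

    target2 = _largest_cluster(labels2)
    subset3 = subset2[labels2 == target2]
    if levels[1].n_clusters < 2 or subset3.size <= max(min_cluster_size, max(k_range)):
        return ClusterTree(levels, _final(2))

    # ----- level 3: K-means with silhouette-selected k
    pca3, scores3 = pca_reduce(x[subset3], variance_threshold)
    try:
        labels3, best_k, sil = cluster_kmeans_silhouette(scores3, k_range, seed)
    except ValueError:
        return ClusterTree(levels, _final(2))
    centers3 = _cluster_centers(scores3, labels3)
    levels.append(
        ClusterLevel(
            subset3, labels3, None, centers3, pca3, scores3, "kmeans",
            chosen_k=best_k, silhouette_by_k=sil,
        )
    )
    assign.iloc[subset3, assign.columns.get_loc("level3")] = labels3
    return ClusterTree(levels, _final(3))


def correlate_within_cluster(
    data: pd.DataFrame, feature_a: str, feature_b: str
) -> tuple[float, float]:
    """Pearson r and two-sided p between two features of one cluster's
    members."""
    a = data[feature_a].to_numpy(float)
    b = data[feature_b].to_numpy(float)
    if a.size < 3:
        raise ValueError("need at least 3 cluster members")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the features")
    r, p = pearsonr(a, b)
    return float(r), float(p)
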