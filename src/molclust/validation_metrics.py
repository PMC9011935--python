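"""Internal (ground-truth-free) clustering validation indices.

Three standard indices, implemented directly from their definitions:

* Silhouette  s = (b - a) / max(a, b), averaged over points, where a is the
  mean distance to the point's own cluster and b the mean distance to the
  next nearest cluster.  Bounded in [-1, 1]; higher is better.
* Calinski–Harabasz  S = (tr(B_k) / tr(W_k)) * ((n - k) / (k - 1)) with the
  between- and within-cluster dispersion matrices B_k, W_k.  Higher is
  better.
* Davies–Bouldin  DB = (1/k) sum_u max_{v!=u} (s_u + s_v) / d_uv with s_w
  the mean point-to-centroid distance of cluster w and d_uv the centroid
  distance.  Lower is better.

All three are invariant to label permutation and to rigid translation of
the data; the test suite checks each against a brute-force oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "InternalIndices",
    "silhouette_index",
    "calinski_harabasz",
    "davies_bouldin",
    "evaluate_all",
]


@dataclass(frozen=True)
class InternalIndices:
    silhouette: float
    calinski_harabasz: float
    davies_bouldin: float


def _check(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or labels.shape != (X.shape[0],):
        raise ValueError("X must be 2-D with one label per row")
    uniq, dense = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("at least two clusters are required")
    return X, dense, uniq


def silhouette_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean Silhouette coefficient under Euclidean distance.

    Points in singleton clusters contribute s = 0 (the within-cluster mean
    distance is undefined for them).
    """
    X, labels, uniq = _check(X, labels)
    n, k = X.shape[0], uniq.size
    D = cdist(X, X)
    # cluster_sums[i, q] = sum of distances from point i to cluster q
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    cluster_sums = D @ onehot
    sizes = onehot.sum(axis=0)

    own = labels
    own_size = sizes[own]
    s = np.zeros(n)
    non_singleton = own_size > 1
    a = np.zeros(n)
    a[non_singleton] = (
        cluster_sums[non_singleton, own[non_singleton]] / (own_size[non_singleton] - 1)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_other = cluster_sums / sizes  # mean distance to each cluster
    mean_other[np.arange(n), own] = np.inf
    b = mean_other.min(axis=1)
    denom = np.maximum(a, b)
    safe = non_singleton & (denom > 0)  # coincident a=b=0 points score 0
    s[safe] = (b[safe] - a[safe]) / denom[safe]
    return float(s.mean())


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Between/within dispersion ratio scaled by (n - k)/(k - 1)."""
    X, labels, uniq = _check(X, labels)
    n, k = X.shape[0], uniq.size
    if n <= k:
        raise ValueError("Calinski-Harabasz needs more points than clusters")
    global_center = X.mean(axis=0)
    tr_b = 0.0
    tr_w = 0.0
    for q in range(k):
        pts = X[labels == q]
        center = pts.mean(axis=0)
        tr_b += pts.shape[0] * float(np.sum((center - global_center) ** 2))
        tr_w += float(np.sum((pts - center) ** 2))
    if tr_w == 0.0:
        warnings.warn("zero within-cluster dispersion; index is infinite", stacklevel=2)
        return float("inf")
    return (tr_b / tr_w) * ((n - k) / (k - 1))


def davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of the worst (s_u + s_v)/d_uv similarity ratio."""
    X, labels, uniq = _check(X, labels)
    k = uniq.size
    centroids = np.stack([X[labels == q].mean(axis=0) for q in range(k)])
    spread = np.array(
        [float(np.mean(np.linalg.norm(X[labels == q] - centroids[q], axis=1)))
         for q in range(k)]
    )
    dists = cdist(centroids, centroids)
    close = (dists < 1e-12) & ~np.eye(k, dtype=bool)
    if np.any(close):
        u, v = np.argwhere(close)[0]
        raise ValueError(f"coincident centroids for clusters {u} and {v}")
    ratios = (spread[:, None] + spread[None, :]) / np.where(dists > 0, dists, np.inf)
    np.fill_diagonal(ratios, -np.inf)
    return float(np.mean(ratios.max(axis=1)))


def evaluate_all(X: np.ndarray, labels: np.ndarray) -> InternalIndices:
    """All three indices for one clustering, computed exactly (no subsampling)."""
    return InternalIndices(
        silhouette=silhouette_index(X, labels),
        calinski_harabasz=calinski_harabasz(X, labels),
        davies_bouldin=davies_bouldin(X, labels),
    )
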