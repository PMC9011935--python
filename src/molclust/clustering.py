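"""K-means / BIRCH clustering, Silhouette scans over k, and k selection.

The cluster count is treated as a hyper-parameter: a grid of candidate k
values is scanned, the mean Silhouette score is computed for each, and the
chosen k is the smallest one after which the score stays flat (plateau
onset), falling back to the argmax when no plateau exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import Birch, KMeans

from .validation_metrics import silhouette_index

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "SilhouetteScan",
    "default_k_grid",
    "kmeans",
    "birch",
    "scan_k",
    "select_k",
]


@dataclass
class ClusterAssignment:
    """Per-molecule integer labels in [0, k) plus centroids and inertia."""

    labels: np.ndarray
    centroids: np.ndarray
    k: int
    inertia: float

    def __post_init__(self):
        present = np.unique(self.labels)
        if present.size != self.k or present.min() != 0 or present.max() != self.k - 1:
            raise ValueError(f"labels must cover every cluster id in [0, {self.k})")


@dataclass
class SilhouetteScan:
    grid: np.ndarray
    scores: np.ndarray
    method: str
    subsample_size: int
    seed: int


def default_k_grid() -> np.ndarray:
    """Candidate cluster counts 5..200 in steps of 5."""
    return np.arange(5, 201, 5)


def kmeans(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ClusterAssignment:
    """Lloyd's algorithm with k-means++ seeding, best of ``n_init`` restarts.

    Iteration alternates assignment to the nearest centroid (Euclidean) and
    centroid recomputation until centroid movement falls below ``tol`` or
    ``max_iter`` is reached.
    """
    X = np.asarray(X, dtype=float)
    if not 2 <= k <= X.shape[0]:
        raise ValueError(f"k={k} must satisfy 2 <= k <= n={X.shape[0]}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter,
        tol=tol, random_state=seed,
    ).fit(X)
    return ClusterAssignment(
        labels=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        k=k,
        inertia=float(km.inertia_),
    )


def birch(
    X: np.ndarray,
    k: int,
    threshold: float = 0.5,
    branching_factor: int = 50,
) -> ClusterAssignment:
    """CF-tree summarization followed by global clustering into k clusters.

    Deterministic given the input row order.  Centroids are the Euclidean
    means of the final clusters.
    """
    X = np.asarray(X, dtype=float)
    if not 2 <= k <= X.shape[0]:
        raise ValueError(f"k={k} must satisfy 2 <= k <= n={X.shape[0]}")
    model = Birch(threshold=threshold, branching_factor=branching_factor, n_clusters=k)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # sklearn warns when leaves < k
        raw = model.fit_predict(X)
    uniq, labels = np.unique(raw, return_inverse=True)
    if uniq.size < k:
        # the CF-tree over-summarized (fewer leaf entries than k); refine by
        # clustering the raw points so the requested k is honoured
        km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(X)
        uniq, labels = np.unique(km.labels_, return_inverse=True)
    centroids = np.stack([X[labels == c].mean(axis=0) for c in range(uniq.size)])
    inertia = float(
        sum(np.sum((X[labels == c] - centroids[c]) ** 2) for c in range(uniq.size))
    )
    return ClusterAssignment(labels=labels, centroids=centroids, k=uniq.size,
                             inertia=inertia)


def _mean_silhouette(
    X: np.ndarray, labels: np.ndarray, subsample: int, rng: np.random.Generator
) -> float:
    """Mean Silhouette, on a seeded subsample when n is large (the exact
    O(n^2) computation is impractical across a 40-point k grid)."""
    n = X.shape[0]
    if subsample and n > subsample:
        idx = rng.choice(n, size=subsample, replace=False)
        Xs, ls = X[idx], labels[idx]
        if np.unique(ls).size < 2:  # degenerate draw; fall back to exact
            Xs, ls = X, labels
    else:
        Xs, ls = X, labels
    return silhouette_index(Xs, ls)


def scan_k(
    X: np.ndarray,
    k_grid: np.ndarray | list[int] | None = None,
    method: str = "kmeans",
    seed: int = 0,
    subsample: int = 10_000,
    cache_path: str | Path | None = None,
    **cluster_kwargs,
) -> SilhouetteScan:
    """Cluster at every k in the grid and record the mean Silhouette score.

    Scores are cached to ``cache_path`` (CSV with columns k, silhouette) so
    an interrupted scan resumes where it stopped.
    """
    X = np.asarray(X, dtype=float)
    grid = np.asarray(default_k_grid() if k_grid is None else k_grid, dtype=int)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("k_grid must be strictly increasing")
    if grid.max() >= X.shape[0]:
        raise ValueError(f"max(k_grid)={grid.max()} must be < n={X.shape[0]}")
    if method not in ("kmeans", "birch"):
        raise ValueError(f"unknown method {method!r}")

    cached: dict[int, float] = {}
    if cache_path is not None and Path(cache_path).exists():
        prev = pd.read_csv(cache_path)
        cached = dict(zip(prev["k"].astype(int), prev["silhouette"].astype(float)))

    scores = np.empty(grid.size)
    for i, k in enumerate(grid):
        if int(k) in cached:
            scores[i] = cached[int(k)]
            continue
        if method == "kmeans":
            assignment = kmeans(X, int(k), seed=seed, **cluster_kwargs)
        else:
            assignment = birch(X, int(k), **cluster_kwargs)
        rng = np.random.default_rng(seed + int(k))  # per-k subsample, reproducible
        scores[i] = _mean_silhouette(X, assignment.labels, subsample, rng)
        cached[int(k)] = scores[i]
        if cache_path is not None:
            pd.DataFrame(
                sorted(cached.items()), columns=["k", "silhouette"]
            ).to_csv(cache_path, index=False, float_format="%.17g")
    return SilhouetteScan(
        grid=grid, scores=scores, method=method,
        subsample_size=subsample, seed=seed,
    )


def select_k(scan: SilhouetteScan, window: int = 2, epsilon: float = 0.01) -> int:
    """Plateau-onset selection of the cluster count.

    Returns the smallest grid k whose next ``window`` scores all stay within
    ``epsilon`` of its own score — the point where the Silhouette curve
    becomes stable.  When no such plateau exists the argmax score is used as
    a fallback; both the rule applied and the choice are logged.
    """
    scores = np.asarray(scan.scores, dtype=float)
    grid = np.asarray(scan.grid, dtype=int)
    if scores.size == 0:
        raise ValueError("empty scan")
    for i in range(scores.size - window):
        ahead = scores[i + 1 : i + 1 + window]
        if np.all(np.abs(ahead - scores[i]) <= epsilon):
            k = int(grid[i])
            logger.info("plateau onset at k=%d (window=%d, eps=%g)", k, window, epsilon)
            return k
    k = int(grid[int(np.argmax(scores))])
    logger.info("no plateau; falling back to argmax k=%d", k)
    return k
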