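"""Small vectorized Lloyd k-means used in the hot replication loops.

The prediction-strength procedure clusters thousands of random data halves
(and permutation-null copies) per run, so the clustering engine must accept
counter-derived child generators and have negligible per-call overhead.
Results are cross-checked against scikit-learn's KMeans in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lloyd_kmeans", "assign_nearest"]


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]), dtype=float)
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0.0:  # all points identical to chosen centers
            centers[j:] = X[rng.integers(n, size=k - j)]
            break
        probs = d2 / total
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def _lloyd_once(X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float):
    k = centers.shape[0]
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        new_centers = centers.copy()
        for j in range(k):
            mask = labels == j
            if mask.any():
                new_centers[j] = X[mask].mean(axis=0)
        shift = ((new_centers - centers) ** 2).sum()
        centers = new_centers
        if shift <= tol:
            break
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = d2[np.arange(X.shape[0]), labels].sum()
    return centers, labels, inertia


def lloyd_kmeans(
    X: np.ndarray,
    k: int = 2,
    *,
    rng: np.random.Generator,
    n_init: int = 10,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    """k-means with k-means++ seeding and ``n_init`` restarts.

    Returns ``(centers, labels, inertia)`` of the restart with the lowest
    within-cluster sum of squares.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < k:
        raise ValueError("need a 2-D matrix with at least k rows")
    best = None
    for _ in range(n_init):
        centers0 = _kmeanspp_init(X, k, rng)
        centers, labels, inertia = _lloyd_once(X, centers0, max_iter, tol)
        if best is None or inertia < best[2]:
            best = (centers, labels, inertia)
    return best


def assign_nearest(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Label each row of ``X`` by its nearest centroid (ties -> lower index)."""
    d2 = ((np.asarray(X, dtype=float)[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)
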