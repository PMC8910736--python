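"""Time-series primitives for QC stability analysis.

Peak-area trajectories of each derivative across the QC injections are
min-max scaled to [-2, 2] and grouped by shape with k-means under one of
three metrics: plain Euclidean distance, dynamic time warping (DTW), or
DTW with barycenter-averaged centroids (DBA).  DTW is the classic
dynamic program with squared local cost; the returned distance is the
square root of the accumulated cost along the optimal monotone warping
path.  QC series share one injection grid, so all series have equal
length and warping only absorbs small shape shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "rsd_percent",
    "minmax_scale",
    "dtw_distance",
    "dtw_path",
    "dba_barycenter",
    "cluster_qc_series",
    "KMeansResult",
]


def rsd_percent(values) -> float:
    """Relative standard deviation: sample SD / mean x 100.

    The stability criterion of QC series; <= 10 % is treated as stable.
    Undefined (NaN) for a zero mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least two values")
    mean = v.mean()
    if mean == 0:
        return float("nan")
    return float(v.std(ddof=1) / mean * 100.0)


def minmax_scale(values, lo: float = -2.0, hi: float = 2.0) -> np.ndarray:
    """Affine map of a series onto [lo, hi]; constant series map to 0.

    The min of a non-constant series lands exactly on ``lo`` and the max
    on ``hi``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("scaling needs at least two values")
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.zeros_like(v)
    return lo + (hi - lo) * (v - vmin) / (vmax - vmin)


def _dtw_matrix(a: np.ndarray, b: np.ndarray, window: int | None) -> np.ndarray:
    n, m = len(a), len(b)
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        j_lo, j_hi = 1, m
        if window is not None:
            j_lo = max(1, i - window)
            j_hi = min(m, i + window)
        for j in range(j_lo, j_hi + 1):
            cost = (a[i - 1] - b[j - 1]) ** 2
            acc[i, j] = cost + min(acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1])
    return acc


def dtw_distance(a, b, window: int | None = None) -> float:
    """DTW distance with squared local cost; sqrt of accumulated cost.

    ``window`` is an optional Sakoe-Chiba band half-width restricting
    |i - j| along the warping path.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("series must be non-empty")
    acc = _dtw_matrix(a, b, window)
    d2 = acc[len(a), len(b)]
    if not np.isfinite(d2):
        raise ValueError("window too narrow for the series lengths")
    return float(np.sqrt(d2))


def dtw_path(a, b, window: int | None = None) -> list[tuple[int, int]]:
    """Optimal warping path as (index into a, index into b) pairs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    acc = _dtw_matrix(a, b, window)
    i, j = len(a), len(b)
    path = [(i - 1, j - 1)]
    while (i, j) != (1, 1):
        steps = [
            (acc[i - 1, j - 1], (i - 1, j - 1)),
            (acc[i - 1, j], (i - 1, j)),
            (acc[i, j - 1], (i, j - 1)),
        ]
        _, (i, j) = min(steps, key=lambda t: t[0])
        path.append((i - 1, j - 1))
    path.reverse()
    return path


def dba_barycenter(
    series_set, n_iter: int = 10, seed: int | None = None, init=None
) -> np.ndarray:
    """DTW barycenter averaging over equal-length series.

    Starting from an initial centroid (default: the element-wise mean),
    each iteration DTW-aligns every series to the centroid and replaces
    each centroid coordinate by the mean of all series values mapped to
    it.  The summed squared DTW distance to the centroid is
    non-increasing over iterations.
    """
    X = np.asarray(series_set, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need at least one series of equal length")
    centroid = np.asarray(init, dtype=float) if init is not None else X.mean(axis=0)
    for _ in range(n_iter):
        sums = np.zeros_like(centroid)
        counts = np.zeros_like(centroid)
        for s in X:
            for ci, si in dtw_path(centroid, s):
                sums[ci] += s[si]
                counts[ci] += 1
        new = np.where(counts > 0, sums / np.maximum(counts, 1), centroid)
        if np.allclose(new, centroid):
            break
        centroid = new
    return centroid


@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    metric: str


def _distances_to(centroid: np.ndarray, X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return np.sqrt(((X - centroid) ** 2).sum(axis=1))
    return np.array([dtw_distance(centroid, s) for s in X])


def cluster_qc_series(
    series_set,
    k: int,
    metric: str = "dba",
    seed: int | None = 0,
    n_init: int = 10,
    max_iter: int = 50,
) -> KMeansResult:
    """k-means over scaled QC series under euclidean, dtw or dba metrics.

    Assignment is by the chosen distance; the centroid update is the
    arithmetic mean for ``euclidean`` and ``dtw``, and DTW barycenter
    averaging for ``dba``.  Runs ``n_init`` seeded restarts and keeps
    the solution with the lowest within-cluster sum of squared
    distances; deterministic for a fixed seed.
    """
    X = np.asarray(series_set, dtype=float)
    if metric not in ("euclidean", "dtw", "dba"):
        raise ValueError(f"unknown metric {metric!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k={k} exceeds number of series ({len(X)})")
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for _ in range(max(1, n_init)):
        idx = rng.choice(len(X), size=k, replace=False)
        centroids = X[idx].copy()
        labels = np.full(len(X), -1)
        for _ in range(max_iter):
            dist = np.stack([_distances_to(c, X, metric) for c in centroids])
            new_labels = dist.argmin(axis=0)
            # re-seed empty clusters with the worst-fit series
            for c in range(k):
                if not (new_labels == c).any():
                    far = dist[new_labels, np.arange(len(X))].argmax()
                    new_labels[far] = c
            if (new_labels == labels).all():
                break
            labels = new_labels
            for c in range(k):
                members = X[labels == c]
                if metric == "dba":
                    centroids[c] = dba_barycenter(
                        members, n_iter=5, init=members.mean(axis=0)
                    )
                else:
                    centroids[c] = members.mean(axis=0)
        dist = np.stack([_distances_to(c, X, metric) for c in centroids])
        inertia = float((dist[labels, np.arange(len(X))] ** 2).sum())
        if best is None or inertia < best.inertia:
            best = KMeansResult(labels.copy(), centroids.copy(), inertia, metric)
    assert best is not None
    return best
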