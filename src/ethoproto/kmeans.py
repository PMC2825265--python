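"""Restarted Lloyd k-means in squared-Euclidean feature space.

Lloyd's iteration alternates nearest-centroid assignment (Voronoi
partitioning) with centroid-mean updates, monotonically decreasing the
within-cluster variance objective until the centroids stop moving.  The
result is a local minimum that depends on the random start, so the
clustering is restarted from several random draws of k data rows and the
run with the lowest objective wins.

An optional k-d-tree assignment path accelerates large data sets; it is
label-identical to the naive argmin and the naive path stays the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import CentroidSet, FeatureMatrix

__all__ = ["lloyd", "restarted_kmeans", "assign", "KMeansRun"]

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000
DEFAULT_RESTARTS = 12


def _data(fm) -> np.ndarray:
    return fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)


def assign(fm, centroids, accelerated: bool = False) -> np.ndarray:
    """Nearest-centroid label per row (squared Euclidean, ties -> lowest index).

    With ``accelerated=True`` the lookup goes through a k-d tree; labels are
    identical to the naive computation.
    """
    X = _data(fm)
    C = centroids.centroids if isinstance(centroids, CentroidSet) else np.asarray(centroids, float)
    if X.shape[1] != C.shape[1]:
        raise ValueError(f"dimension mismatch: data F={X.shape[1]}, centroids F={C.shape[1]}")
    if accelerated:
        return cKDTree(C).query(X)[1]
    return _nearest(X, C)[0]


def _nearest(X: np.ndarray, C: np.ndarray):
    """Labels and squared distances to the nearest centroid (naive argmin)."""
    # ||x-c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; argmin over c
    d2 = (
        np.einsum("ij,ij->i", X, X)[:, None]
        - 2.0 * X @ C.T
        + np.einsum("ij,ij->i", C, C)[None, :]
    )
    labels = np.argmin(d2, axis=1)
    best = d2[np.arange(len(X)), labels]
    return labels, np.maximum(best, 0.0)


@dataclass(frozen=True)
class KMeansRun:
    """One converged Lloyd run: centroid set, objective and iteration count.

    ``objective_history`` holds the objective after every assignment step;
    Lloyd guarantees it is non-increasing.
    """

    centroids: CentroidSet
    objective: float
    n_iter: int
    seed: int
    labels: np.ndarray
    objective_history: tuple = ()


def _repaired_assignment(X: np.ndarray, C: np.ndarray, k: int):
    """Nearest-centroid labels with deterministic empty-cluster repair.

    Each empty cluster is re-seeded at the point currently farthest from
    its nearest centroid (that point is relabelled, so the next mean
    update moves the centroid onto it).
    """
    labels, d2 = _nearest(X, C)
    for _ in range(k):  # moving a singleton's only point can re-empty a cluster
        empty = np.flatnonzero(np.bincount(labels, minlength=k) == 0)
        if not empty.size:
            break
        for j in empty:
            far = int(np.argmax(d2))
            labels[far] = j
            d2[far] = 0.0
    return labels, d2


def _summarize(X: np.ndarray, C: np.ndarray, labels: np.ndarray, norm, names, units) -> CentroidSet:
    k = C.shape[0]
    shares = np.bincount(labels, minlength=k) / len(X)
    within = np.zeros(k)
    fsd = np.zeros_like(C)
    for j in range(k):
        members = X[labels == j]
        if len(members):
            within[j] = np.mean(np.sum((members - C[j]) ** 2, axis=1))
            fsd[j] = members.std(axis=0)
    return CentroidSet(C, shares, within, fsd, norm, names, units)


def lloyd(
    fm,
    k: int,
    seed: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> KMeansRun:
    """One Lloyd run started from k distinct data rows drawn with ``seed``.

    Iterates until the largest centroid displacement drops below ``tol``
    (normalized units) or ``max_iter`` is reached.  A cluster emptied
    during iteration is re-seeded at the point farthest from its nearest
    centroid, so the returned set never has an empty cluster.
    """
    X = _data(fm)
    n = len(X)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of data points {n}")
    rng = np.random.default_rng(seed)
    C = X[rng.choice(n, size=k, replace=False)].copy()
    history = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        labels, d2 = _repaired_assignment(X, C, k)
        history.append(float(d2.sum()))
        sums = np.zeros_like(C)
        np.add.at(sums, labels, X)
        counts = np.bincount(labels, minlength=k)
        newC = sums / counts[:, None]
        shift = np.max(np.sqrt(np.sum((newC - C) ** 2, axis=1)))
        C = newC
        if shift < tol:
            break
    labels, d2 = _repaired_assignment(X, C, k)
    history.append(float(d2.sum()))
    objective = float(d2.sum())
    norm = fm.norm if isinstance(fm, FeatureMatrix) else None
    names = fm.names if isinstance(fm, FeatureMatrix) else ()
    units = fm.units if isinstance(fm, FeatureMatrix) else ()
    cs = _summarize(X, C, labels, norm, names, units)
    return KMeansRun(cs, objective, n_iter, seed, labels, tuple(history))


def restarted_kmeans(fm, k: int, n_restarts: int = DEFAULT_RESTARTS, base_seed: int = 0, **kw) -> KMeansRun:
    """Best of ``n_restarts`` Lloyd runs seeded base_seed..base_seed+n-1.

    The run with the minimal objective wins; ties go to the lowest seed.
    """
    if n_restarts < 1:
        raise ValueError("need at least one restart")
    best = None
    for seed in range(base_seed, base_seed + n_restarts):
        run = lloyd(fm, k, seed=seed, **kw)
        if best is None or run.objective < best.objective:
            best = run
    return best
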