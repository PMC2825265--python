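"""Ward agglomerative pre-scan for constraining the number of clusters.

Agglomerative clustering under Ward's criterion merges, at every step, the
two clusters whose fusion minimally increases the total within-cluster
variance.  The increase for merging clusters of sizes n1, n2 with
centroids c1, c2 is

    cost = n1 * n2 / (n1 + n2) * ||c1 - c2||^2            (squared Euclidean)

and the merged cluster's variance is V1 + V2 + cost, so the joining costs
telescope to the total variance of the data.  Plotting the joining cost
against the remaining number of clusters shows a sharp rise once distinct
groups are forced to merge; the position of that rise bounds the range of
cluster counts worth scanning with k-means.  The scan is exploratory and
noise-sensitive, so it is run on modest subsequences, never the full data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage

from .io import FeatureMatrix

__all__ = ["Dendrogram", "ward_cluster", "cost_curve", "CostCurve", "suggest_k_range"]

DEFAULT_SIZE_CAP = 20000
FALLBACK_RANGE = (2, 50)


@dataclass(frozen=True)
class Dendrogram:
    """Merge history: (cluster_a, cluster_b, joining_cost, new_size) per step.

    Cluster indices follow the scipy convention: 0..N-1 are the original
    points, N+i is the cluster created by merge i.
    """

    merges: tuple
    n_points: int

    def __post_init__(self):
        object.__setattr__(self, "merges", tuple(tuple(m) for m in self.merges))
        if len(self.merges) != self.n_points - 1:
            raise ValueError("a dendrogram of N points has N-1 merges")
        sizes = {i: 1 for i in range(self.n_points)}
        for step, (a, b, cost, size) in enumerate(self.merges):
            if cost < -1e-12:
                raise ValueError(f"negative joining cost at merge {step}")
            if sizes.pop(int(a)) + sizes.pop(int(b)) != size:
                raise ValueError(f"size bookkeeping broken at merge {step}")
            sizes[self.n_points + step] = size
        (last,) = sizes.values()
        if last != self.n_points:
            raise ValueError("final cluster does not contain all points")

    @property
    def joining_costs(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])


def ward_cluster(fm: FeatureMatrix | np.ndarray, size_cap: int = DEFAULT_SIZE_CAP) -> Dendrogram:
    """Full Ward agglomeration of the rows of ``fm``.

    Uses the Lance-Williams recurrence internally; merge costs are reported
    as variance increases (squared-Euclidean units).
    """
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if n > size_cap:
        raise ValueError(
            f"{n} points exceed the agglomeration cap of {size_cap}; "
            "subsample the sequence (the pre-scan is meant for small subsets)"
        )
    Z = linkage(X, method="ward")
    # scipy's Ward 'distance' is sqrt(2 * n1*n2/(n1+n2)) * ||c1-c2||;
    # the variance increase is therefore height^2 / 2.
    merges = tuple(
        (int(a), int(b), h * h / 2.0, int(size)) for a, b, h, size in Z
    )
    return Dendrogram(merges, n)


@dataclass(frozen=True)
class CostCurve:
    """Joining cost of the merge that reduces m clusters to m-1.

    ``num_clusters[i]`` = m, ``cost[i]`` = cost of the m -> m-1 merge,
    ordered by decreasing m (chronological merge order).  ``differential``
    is the successive difference of costs; costs are not guaranteed
    monotone in m.
    """

    num_clusters: np.ndarray
    cost: np.ndarray

    @property
    def differential(self) -> np.ndarray:
        return np.diff(self.cost)


def cost_curve(d: Dendrogram) -> CostCurve:
    costs = d.joining_costs
    m = np.arange(d.n_points, 1, -1)  # merge i goes from m=N-i clusters to m-1
    return CostCurve(m, costs)


def suggest_k_range(curve: CostCurve, window: int = 5, factor: float = 2.0, margin: int = 3):
    """Bound the k range for the k-means scan from a joining-cost curve.

    Joining costs grow smoothly as merges deplete the data even when no
    cluster structure exists, so a jump only counts if it beats the *local
    trend*: for each m the cost of the m -> m-1 merge is compared against
    ``factor`` times the cost extrapolated from the ``window`` preceding
    (larger-m, cheaper) merges via their median successive ratio.  The
    elbow is the largest m whose cost breaks the trend; the suggested
    range is [2, elbow + margin].  If no merge stands out — as for
    unstructured, noisy data, where no distinct cluster number exists —
    the full fallback range [2, 50] is returned with a warning.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if len(curve.cost) < window + 1:
        raise ValueError("cost curve shorter than the comparison window")
    order = np.argsort(curve.num_clusters)
    m_sorted = curve.num_clusters[order]  # ascending m
    cost_sorted = curve.cost[order]
    elbow = None
    # scan m descending; first trend-breaking jump is the elbow
    for i in range(len(m_sorted) - window - 1, -1, -1):
        ahead = cost_sorted[i + 1 : i + 1 + window]  # the window cheaper merges
        if (ahead <= 0).any():
            continue
        ratios = ahead[:-1] / ahead[1:]
        predicted = np.median(ratios) * ahead[0]
        if predicted > 0 and cost_sorted[i] > factor * predicted:
            elbow = int(m_sorted[i])
            break
    if elbow is None:
        warnings.warn(
            "no distinct joining-cost increase found; falling back to the "
            f"full range {FALLBACK_RANGE}",
            stacklevel=2,
        )
        return FALLBACK_RANGE
    return (2, elbow + margin)
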