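"""Stability/quality validation of k-means clusterings and choice of k.

A centroid configuration is only worth interpreting as a set of
behavioural prototypes if it is (a) *stable* — reproducible across random
starts and across systematic variations of the data base — and (b) of
high *quality* — its clusters are compact and well separated.

Stability is measured directly between centroid sets rather than between
data partitions: two equal-cardinality sets are matched one-to-one by the
Hungarian algorithm minimizing the summed squared Euclidean centroid
distances, and the matched sum, normalized by the number of centroids and
of features, is the configuration distance.  Among several runs, the
*mean set* is the one with the smallest mean distance to all the others,
and that minimal mean distance is the instability of the collection.

Data-base variation is systematic rather than random: contiguous blocks
of 10%, 20% or 50% of the sequence are left out at 50 equidistant cut
positions, mimicking shorter recordings of fewer individuals while
keeping every sample involved in many constellations.

Quality of one cluster j is the squared separation/compactness index

    Q_j = min_{i != j} ||c_j - c_i||^2  /  sigma_j^2

with sigma_j^2 the mean squared distance of cluster members to their
centroid; the mean over clusters scores the whole clustering.  Stability
is a prerequisite: among the stable cluster counts, the one with the best
mean-set quality is selected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .io import CentroidSet, FeatureMatrix
from .kmeans import DEFAULT_RESTARTS, lloyd, restarted_kmeans, assign

__all__ = [
    "LeaveOutPlan",
    "leave_out_plan",
    "match_distance",
    "StabilityReport",
    "mean_set",
    "QualityReport",
    "cluster_quality",
    "ValidationReport",
    "validation_scan",
    "select_k",
    "FULL_DATA",
    "DEFAULT_FRACTIONS",
]

FULL_DATA = "full"
DEFAULT_FRACTIONS = (0.1, 0.2, 0.5)
DEFAULT_N_POSITIONS = 50
DEFAULT_FULL_RUNS = 10


# ---------------------------------------------------------------------------
# systematic leave-out resampling


@dataclass(frozen=True)
class LeaveOutPlan:
    """Kept-index masks for systematic contiguous leave-out."""

    fraction: float
    n_positions: int
    masks: tuple  # of int arrays (kept indices, original order)

    def __post_init__(self):
        object.__setattr__(
            self, "masks", tuple(np.asarray(m, dtype=np.intp) for m in self.masks)
        )


def leave_out_plan(N: int, fraction: float, n_positions: int = DEFAULT_N_POSITIONS) -> LeaveOutPlan:
    """Plan removing a contiguous block of ``round(N*fraction)`` samples at
    ``n_positions`` equidistant start positions (wrapping at the end).

    Kept indices stay in original order; every index is kept by at least
    one mask.
    """
    if not 0 < fraction < 1:
        raise ValueError("leave-out fraction must be in (0, 1)")
    if N * fraction < 1 or n_positions < 1:
        raise ValueError("N*fraction must be >= 1 and n_positions >= 1")
    block = int(round(N * fraction))
    masks = []
    all_idx = np.arange(N)
    for p in range(n_positions):
        start = int(round(p * N / n_positions))
        removed = (start + np.arange(block)) % N
        keep = np.ones(N, dtype=bool)
        keep[removed] = False
        masks.append(all_idx[keep])
    return LeaveOutPlan(fraction, n_positions, tuple(masks))


# ---------------------------------------------------------------------------
# configuration distance between centroid sets


def match_distance(A: CentroidSet, B: CentroidSet):
    """Optimal centroid matching and normalized configuration distance.

    Returns ``(matching, distance)`` where ``matching[i]`` is the index in
    B matched to centroid i of A, and distance is the Hungarian-minimal
    sum of squared Euclidean centroid distances divided by k*F.
    """
    if A.k != B.k:
        raise ValueError(f"centroid sets differ in cardinality: {A.k} vs {B.k}")
    if A.n_features != B.n_features:
        raise ValueError("centroid sets differ in feature dimension")
    cost = cdist(A.centroids, B.centroids, metric="sqeuclidean")
    rows, cols = linear_sum_assignment(cost)
    matching = np.empty(A.k, dtype=int)
    matching[rows] = cols
    total = cost[rows, cols].sum()
    return matching, float(total / (A.k * A.n_features))


@dataclass(frozen=True)
class StabilityReport:
    """Pairwise configuration distances within a collection of centroid sets.

    ``mean_set_index`` marks the set with the smallest mean distance to the
    others; ``instability`` is that minimal mean distance and
    ``mean_error`` the standard deviation of the mean set's distances to
    the others divided by the number of sets.
    """

    pairwise: np.ndarray
    mean_set_index: int
    instability: float
    mean_error: float

    def __post_init__(self):
        object.__setattr__(self, "pairwise", np.asarray(self.pairwise, float))


def mean_set(sets) -> StabilityReport:
    """Mean set of centroids and instability of a collection of >= 2 sets."""
    sets = list(sets)
    m = len(sets)
    if m < 2:
        raise ValueError("need at least two centroid sets")
    pairwise = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            _, d = match_distance(sets[i], sets[j])
            pairwise[i, j] = pairwise[j, i] = d
    row_means = pairwise.sum(axis=1) / (m - 1)
    idx = int(np.argmin(row_means))
    others = np.delete(pairwise[idx], idx)
    mean_error = float(others.std(ddof=1) / m) if m > 2 else 0.0
    return StabilityReport(pairwise, idx, float(row_means[idx]), mean_error)


# ---------------------------------------------------------------------------
# quality


@dataclass(frozen=True)
class QualityReport:
    """Per-cluster squared separation/compactness indices Q_j and their mean.

    Clusters with zero within-cluster variance get Q_j = inf and are
    excluded from the mean (with a warning at computation time).
    """

    per_cluster_q: np.ndarray
    inner: np.ndarray
    outer: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "per_cluster_q", np.asarray(self.per_cluster_q, float))
        object.__setattr__(self, "inner", np.asarray(self.inner, float))
        object.__setattr__(self, "outer", np.asarray(self.outer, float))

    @property
    def mean_q(self) -> float:
        finite = self.per_cluster_q[np.isfinite(self.per_cluster_q)]
        return float(finite.mean())


def cluster_quality(fm, cs: CentroidSet, labels: np.ndarray | None = None) -> QualityReport:
    """Quality of a centroid set on a data set.

    ``labels`` defaults to the nearest-centroid assignment of ``fm`` to
    ``cs`` (so a mean set obtained on reduced data can be scored on the
    full data).  inner_j is the mean squared member distance to c_j,
    outer_j the squared distance to the nearest other centroid,
    Q_j = outer_j / inner_j.
    """
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    if labels is None:
        labels = assign(X, cs)
    k = cs.k
    counts = np.bincount(labels, minlength=k)
    if (counts == 0).any():
        raise ValueError(f"empty cluster(s): {np.flatnonzero(counts == 0).tolist()}")
    inner = np.empty(k)
    for j in range(k):
        inner[j] = np.mean(np.sum((X[labels == j] - cs.centroids[j]) ** 2, axis=1))
    cc = cdist(cs.centroids, cs.centroids, metric="sqeuclidean")
    np.fill_diagonal(cc, np.inf)
    outer = cc.min(axis=1)
    with np.errstate(divide="ignore"):
        q = np.where(inner > 0, outer / np.where(inner > 0, inner, 1.0), np.inf)
    if (inner == 0).any():
        warnings.warn(
            "cluster(s) with zero within-cluster variance: quality reported "
            "as inf and excluded from the mean",
            stacklevel=2,
        )
    return QualityReport(q, inner, outer)


# ---------------------------------------------------------------------------
# full scan over k and data-set conditions


@dataclass
class ConditionResult:
    """Stability of one (k, condition) cell plus its mean centroid set."""

    stability: StabilityReport
    mean_centroids: CentroidSet
    quality: QualityReport  # of the mean set, on the full data


@dataclass
class ValidationReport:
    """Everything the model-selection rule needs, per k and condition."""

    k_values: tuple
    conditions: tuple  # FULL_DATA and/or leave-out fractions (as str)
    cells: dict  # (k, condition) -> ConditionResult
    between: dict  # k -> StabilityReport across condition mean sets
    settings: dict = field(default_factory=dict)
    selected_k: int | None = None

    def instability(self, condition) -> np.ndarray:
        return np.array([self.cells[(k, str(condition))].stability.instability for k in self.k_values])

    def between_instability(self) -> np.ndarray:
        return np.array([self.between[k].instability for k in self.k_values])

    def mean_quality(self) -> np.ndarray:
        """Per k: mean over conditions of the mean-set mean quality."""
        return np.array(
            [
                np.mean([self.cells[(k, c)].quality.mean_q for c in self.conditions])
                for k in self.k_values
            ]
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        def _cs(cs: CentroidSet) -> dict:
            return {
                "centroids": cs.centroids.tolist(),
                "shares": cs.shares.tolist(),
                "within_var": cs.within_var.tolist(),
                "feature_sd": cs.feature_sd.tolist(),
                "norm": cs.norm.to_dict() if cs.norm else None,
                "names": list(cs.names),
                "units": list(cs.units),
            }

        doc = {
            "k_values": list(self.k_values),
            "conditions": list(self.conditions),
            "selected_k": self.selected_k,
            "settings": self.settings,
            "cells": [
                {
                    "k": k,
                    "condition": c,
                    "stability": {
                        "pairwise": r.stability.pairwise.tolist(),
                        "mean_set_index": r.stability.mean_set_index,
                        "instability": r.stability.instability,
                        "mean_error": r.stability.mean_error,
                    },
                    "mean_centroids": _cs(r.mean_centroids),
                    "quality": {
                        "per_cluster_q": r.quality.per_cluster_q.tolist(),
                        "inner": r.quality.inner.tolist(),
                        "outer": r.quality.outer.tolist(),
                    },
                }
                for (k, c), r in self.cells.items()
            ],
            "between": {
                str(k): {
                    "pairwise": r.pairwise.tolist(),
                    "mean_set_index": r.mean_set_index,
                    "instability": r.instability,
                    "mean_error": r.mean_error,
                }
                for k, r in self.between.items()
            },
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "ValidationReport":
        from .io import NormalizationParams

        doc = json.loads(Path(path).read_text())

        def _cs(d):
            norm = NormalizationParams.from_dict(d["norm"]) if d.get("norm") else None
            return CentroidSet(
                np.asarray(d["centroids"], float),
                np.asarray(d["shares"], float),
                np.asarray(d["within_var"], float),
                np.asarray(d["feature_sd"], float),
                norm,
                tuple(d.get("names", ())),
                tuple(d.get("units", ())),
            )

        def _stab(d):
            return StabilityReport(
                np.asarray(d["pairwise"], float),
                int(d["mean_set_index"]),
                float(d["instability"]),
                float(d["mean_error"]),
            )

        cells = {}
        for cell in doc["cells"]:
            q = cell["quality"]
            cells[(int(cell["k"]), cell["condition"])] = ConditionResult(
                _stab(cell["stability"]),
                _cs(cell["mean_centroids"]),
                QualityReport(
                    np.asarray(q["per_cluster_q"], float),
                    np.asarray(q["inner"], float),
                    np.asarray(q["outer"], float),
                ),
            )
        between = {int(k): _stab(d) for k, d in doc["between"].items()}
        return cls(
            tuple(doc["k_values"]),
            tuple(doc["conditions"]),
            cells,
            between,
            doc.get("settings", {}),
            doc.get("selected_k"),
        )


def validation_scan(
    fm: FeatureMatrix,
    k_range,
    fractions=DEFAULT_FRACTIONS,
    n_positions: int = DEFAULT_N_POSITIONS,
    n_full_runs: int = DEFAULT_FULL_RUNS,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    select: bool = True,
    stability_factor: float = 2.0,
) -> ValidationReport:
    """Scan cluster counts and data-set conditions; fully seeded.

    Per k: the full data is clustered ``n_full_runs`` times, each run a
    restarted k-means with a different block of start seeds
    (start-position stability); each leave-out condition is likewise
    clustered once per mask.  Per (k, condition) the mean set, instability
    and the mean set's quality on the full data are recorded; per k the
    between-condition instability of the condition mean sets.
    """
    k_range = tuple(int(k) for k in k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    N = fm.n_samples
    plans = {f: leave_out_plan(N, f, n_positions) for f in fractions}
    conditions = (FULL_DATA, *[str(f) for f in fractions])
    cells = {}
    between = {}
    for ki, k in enumerate(k_range):
        base = seed + 100_000 * ki  # disjoint seed blocks per k
        per_condition_sets = {}
        # full data, varying random starts
        full_sets = [
            restarted_kmeans(
                fm, k, n_restarts=restarts, base_seed=base + r * restarts,
                max_iter=max_iter, tol=tol,
            ).centroids
            for r in range(n_full_runs)
        ]
        per_condition_sets[FULL_DATA] = full_sets
        # leave-out conditions, one restarted clustering per mask
        offset = n_full_runs * restarts
        for f in fractions:
            sets = []
            for mask in plans[f].masks:
                run = restarted_kmeans(
                    fm.take(mask), k, n_restarts=restarts,
                    base_seed=base + offset, max_iter=max_iter, tol=tol,
                )
                offset += restarts
                sets.append(run.centroids)
            per_condition_sets[str(f)] = sets
        mean_sets = {}
        for cond, sets in per_condition_sets.items():
            stab = mean_set(sets)
            mcs = sets[stab.mean_set_index]
            quality = cluster_quality(fm, mcs)
            cells[(k, cond)] = ConditionResult(stab, mcs, quality)
            mean_sets[cond] = mcs
        between[k] = mean_set([mean_sets[c] for c in conditions])
    report = ValidationReport(
        k_range,
        conditions,
        cells,
        between,
        settings={
            "fractions": list(fractions),
            "n_positions": n_positions,
            "n_full_runs": n_full_runs,
            "restarts": restarts,
            "seed": seed,
            "stability_factor": stability_factor,
        },
    )
    if select:
        report.selected_k = select_k(report, stability_factor=stability_factor)
    return report


DEFAULT_STABILITY_FLOOR = 0.01


def select_k(
    report: ValidationReport,
    stability_factor: float = 2.0,
    stability_floor: float = DEFAULT_STABILITY_FLOOR,
    instability_cap: float | None = None,
) -> int:
    """Stability-gated quality maximization.

    Admissible k have between-condition instability at most
    ``stability_factor`` times the minimum over the scanned range.  Because
    that relative rule degenerates when the minimum is essentially zero
    (any instability at the numerical-noise level is stable in practice),
    instabilities up to ``stability_floor`` are always admissible; an
    optional hard ``instability_cap`` bounds the threshold from above.
    Among the admissible k, the one with the best mean quality of the
    condition mean sets wins, ties going to the smaller k.
    """
    inst = report.between_instability()
    threshold = max(stability_factor * inst.min(), stability_floor)
    if instability_cap is not None:
        threshold = min(threshold, instability_cap)
    admissible = [
        (k, q)
        for k, i, q in zip(report.k_values, inst, report.mean_quality())
        if i <= threshold
    ]
    if not admissible:
        raise ValueError(
            "no admissible cluster count; between-condition instabilities: "
            + ", ".join(f"k={k}: {i:.4g}" for k, i in zip(report.k_values, inst))
        )
    best_q = max(q for _, q in admissible)
    return min(k for k, q in admissible if q == best_q)
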