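"""Model/Results front end over the prototype-discovery pipeline.

``PrototypeModel`` is built from data (a feature matrix, or a trajectory
via :meth:`PrototypeModel.from_trajectory`); ``fit`` runs the validated
clustering — optional Ward pre-scan to bound k, a stability/quality scan
over that range, selection of k, and a final restarted k-means at the
selected k — and returns a ``PrototypeResults`` carrying the prototypes,
their uncertainties and diagnostics, with ``summary()``, segmentation and
plotting attached.  All heavy lifting lives in the functional modules;
this layer only orchestrates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import features as feat
from . import hcluster, kmeans, segment as seg, validate, viz
from .io import CentroidSet, FeatureMatrix, SegmentList, Trajectory6D

__all__ = ["PrototypeModel", "PrototypeResults"]


class PrototypeModel:
    """Prototypical-movement model of a behavioural feature time series.

    Parameters
    ----------
    fm :
        Feature matrix (rows = time steps).  Normalized on construction
        unless it already carries normalization parameters.
    """

    def __init__(self, fm: FeatureMatrix):
        if fm.norm is None:
            fm = feat.znormalize(fm)
        self.data = fm

    @classmethod
    def from_trajectory(
        cls, traj: Trajectory6D, smooth: bool = True, order: int = 2, rel_cutoff: float = 0.1
    ) -> "PrototypeModel":
        """Build from a 6-DOF trajectory: smooth, differentiate, normalize."""
        if smooth:
            traj = feat.smooth_trajectory(traj, order=order, rel_cutoff=rel_cutoff)
        return cls(feat.body_frame_velocities(traj))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, units=None) -> "PrototypeModel":
        """Build from a DataFrame of feature columns."""
        units = tuple(units) if units is not None else tuple("" for _ in df.columns)
        return cls(FeatureMatrix(df.to_numpy(float), tuple(df.columns), units))

    def suggest_k_range(self, subseq_len: int = 5000, n_subseq: int = 3, seed: int = 0):
        """Ward pre-scan on random subsequences; union of suggested ranges."""
        rng = np.random.default_rng(seed)
        n = self.data.n_samples
        L = min(subseq_len, n)
        lo, hi = None, None
        for _ in range(n_subseq):
            start = int(rng.integers(0, max(n - L, 0) + 1))
            sub = self.data.take(np.arange(start, start + L))
            curve = hcluster.cost_curve(hcluster.ward_cluster(sub))
            a, b = hcluster.suggest_k_range(curve)
            lo = a if lo is None else min(lo, a)
            hi = b if hi is None else max(hi, b)
        return lo, hi

    def fit(
        self,
        k: int | None = None,
        k_range=None,
        fractions=validate.DEFAULT_FRACTIONS,
        n_positions: int = validate.DEFAULT_N_POSITIONS,
        restarts: int = kmeans.DEFAULT_RESTARTS,
        seed: int = 0,
        **scan_kw,
    ) -> "PrototypeResults":
        """Fit the model.

        With ``k`` given, the validation scan is skipped and a single
        restarted k-means is run at that k (the scan report is None).
        Otherwise ``k_range`` (default 2..12) is scanned and k selected by
        the stability-gated quality rule.
        """
        report = None
        if k is None:
            if k_range is None:
                k_range = range(2, 13)
            report = validate.validation_scan(
                self.data,
                k_range,
                fractions=fractions,
                n_positions=n_positions,
                restarts=restarts,
                seed=seed,
                **scan_kw,
            )
            k = report.selected_k
        run = kmeans.restarted_kmeans(self.data, k, n_restarts=restarts, base_seed=seed)
        return PrototypeResults(self, run, report)


@dataclass
class PrototypeResults:
    """Fitted prototypes plus validation diagnostics."""

    model: PrototypeModel
    run: kmeans.KMeansRun
    report: validate.ValidationReport | None = None

    @property
    def k(self) -> int:
        return self.run.centroids.k

    @property
    def centroids(self) -> CentroidSet:
        """Centroid set in normalized feature space."""
        return self.run.centroids

    @property
    def prototypes(self) -> CentroidSet:
        """Centroid set re-expressed in physical units."""
        return feat.renormalize_centroids(self.run.centroids)

    @property
    def labels(self) -> np.ndarray:
        return self.run.labels

    def quality(self) -> validate.QualityReport:
        return validate.cluster_quality(self.model.data, self.run.centroids, self.run.labels)

    def group_map(self, factor: float = 1.0) -> dict:
        """Rotational/translational classification of the prototypes."""
        return seg.classify_prototypes(self.run.centroids, factor=factor)

    def segments(self, min_duration: float = 0.0) -> SegmentList:
        dt = 1.0
        t0 = 0.0
        if self.model.data.t is not None:
            t = self.model.data.t
            dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
            t0 = float(t[0])
        sl = seg.segment_labels(self.labels, dt, t0)
        if min_duration > 0:
            sl = seg.merge_short_segments(sl, min_duration, dt)
        return sl

    def duration_stats(self, threshold: float = 20.0, factor: float = 1.0) -> pd.DataFrame:
        return seg.duration_stats(self.segments(), self.group_map(factor), threshold)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        q = self.quality()
        cs = self.prototypes
        lines = []
        lines.append("Prototypical movement model")
        lines.append("=" * 66)
        lines.append(f"samples: {self.model.data.n_samples}   features: "
                     f"{', '.join(self.model.data.names)}")
        lines.append(f"clusters (k): {self.k}   objective: {self.run.objective:.4f}   "
                     f"mean quality: {q.mean_q:.3f}")
        if self.report is not None:
            inst = dict(zip(self.report.k_values, self.report.between_instability()))
            lines.append(
                f"selected k: {self.report.selected_k} from "
                f"{list(self.report.k_values)} "
                f"(between-condition instability at k: {inst[self.k]:.4g})"
            )
        lines.append("-" * 66)
        header = f"{'j':>2} {'share%':>7} {'Q_j':>8}  " + " ".join(
            f"{n:>9}" for n in (cs.names or tuple(f"f{i}" for i in range(cs.n_features)))
        )
        lines.append(header)
        for j in range(self.k):
            vals = " ".join(f"{v:9.3f}" for v in cs.centroids[j])
            qj = q.per_cluster_q[j]
            qs = f"{qj:8.2f}" if np.isfinite(qj) else "     inf"
            lines.append(f"{j:>2} {cs.shares[j] * 100:7.2f} {qs}  {vals}")
        if cs.units:
            lines.append("units: " + " ".join(f"{u:>9}" for u in cs.units))
        return "\n".join(lines)

    def plot_prototypes(self, out, physical: bool = True) -> None:
        viz.star_plot(self.prototypes if physical else self.centroids, out)

    def plot_report(self, out_dir) -> list:
        if self.report is None:
            raise ValueError("fit was run with fixed k; no validation report")
        return viz.report_plots(self.report, out_dir)
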