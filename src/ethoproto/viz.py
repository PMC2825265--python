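"""Diagnostic plots: star plots of prototypes, validation curves, segments.

The star plot shows one high-dimensional centroid as rays at equi-angular
directions spanning the upper half-plane, one per feature; the marker
sits at a radius proportional to the feature value (negative values on
the opposite orientation of the same ray), with an error bar for the
per-cluster feature standard deviation.  Centre-to-tip connecting lines
are deliberately omitted so the error bars stay legible.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .io import CentroidSet, SegmentList
from .validate import FULL_DATA, ValidationReport

__all__ = ["star_plot", "report_plots", "cost_curve_plot", "segment_ribbon"]


def _ray_angles(F: int) -> np.ndarray:
    """Ray direction for feature f: 180 deg * (f + 0.5) / F from the +x axis."""
    return np.pi * (np.arange(F) + 0.5) / F


def star_plot(cs: CentroidSet, out, ncols: int = 3, titles=None) -> None:
    """One panel per centroid; writes a figure to ``out`` (format by suffix)."""
    F = cs.n_features
    angles = _ray_angles(F)
    colors = plt.cm.tab10(np.arange(F) % 10)
    k = cs.k
    ncols = min(ncols, k)
    nrows = math.ceil(k / ncols)
    rmax = float(max(np.abs(cs.centroids).max() + cs.feature_sd.max(), 1e-12)) * 1.15
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 3.2 * nrows), squeeze=False
    )
    names = cs.names if cs.names else tuple(f"f{i}" for i in range(F))
    for j in range(nrows * ncols):
        ax = axes[j // ncols][j % ncols]
        if j >= k:
            ax.axis("off")
            continue
        for f in range(F):
            v = cs.centroids[j, f]
            theta = angles[f] if v >= 0 else angles[f] + np.pi
            r = abs(v)
            x, y = r * np.cos(theta), r * np.sin(theta)
            # sd error bar along the ray direction
            dx, dy = np.cos(theta), np.sin(theta)
            sd = cs.feature_sd[j, f]
            ax.plot(
                [x - sd * dx, x + sd * dx],
                [y - sd * dy, y + sd * dy],
                color=colors[f],
                lw=1.2,
            )
            ax.plot([x], [y], "o", color=colors[f], ms=6, label=names[f])
        ax.axhline(0, color="0.8", lw=0.5, zorder=0)
        ax.set_xlim(-rmax, rmax)
        ax.set_ylim(-rmax, rmax)
        ax.set_aspect("equal")
        title = titles[j] if titles else f"prototype {j} ({cs.shares[j] * 100:.1f}%)"
        ax.set_title(title, fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
    handles, labels = axes[0][0].get_legend_handles_labels()
    fig.legend(handles, labels, loc="lower center", ncol=min(F, 6), fontsize=8)
    fig.tight_layout(rect=(0, 0.06, 1, 1))
    fig.savefig(out, dpi=120)
    plt.close(fig)


def cost_curve_plot(curve, out, max_clusters: int | None = None) -> None:
    """Joining cost and differential cost against the number of clusters."""
    m = curve.num_clusters
    cost = curve.cost
    if max_clusters is not None:
        keep = m <= max_clusters
        m, cost = m[keep], cost[keep]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
    ax1.plot(m, cost, ".-")
    ax1.set_xlabel("number of clusters")
    ax1.set_ylabel("joining cost")
    ax1.invert_xaxis()
    dm = m[:-1]
    ax2.plot(dm, np.abs(np.diff(cost)), ".-")
    ax2.set_xlabel("number of clusters")
    ax2.set_ylabel("differential joining cost")
    ax2.invert_xaxis()
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def report_plots(report: ValidationReport, out_dir) -> list:
    """Instability and quality curves of a validation scan.

    Writes four files into ``out_dir`` (created if needed) and returns
    their paths: within-condition instability vs k, between-condition
    instability vs k, mean quality vs k, and the per-cluster quality bar
    chart for the selected (or best-quality) k.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ks = np.array(report.k_values)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for cond in report.conditions:
        label = "full data" if cond == FULL_DATA else f"leave out {float(cond) * 100:.0f}%"
        ax.errorbar(
            ks,
            report.instability(cond),
            yerr=[report.cells[(k, cond)].stability.mean_error for k in ks],
            marker="o",
            ms=3,
            label=label,
        )
    ax.set_xlabel("number of clusters")
    ax.set_ylabel("instability")
    ax.set_xticks(ks)
    ax.set_xlim(ks.min() - 0.5, ks.max() + 0.5)
    ax.legend(fontsize=8)
    p = out_dir / "instability_within.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ks, report.between_instability(), "o-")
    ax.set_xlabel("number of clusters")
    ax.set_ylabel("between-condition instability")
    ax.set_xticks(ks)
    ax.set_xlim(ks.min() - 0.5, ks.max() + 0.5)
    p = out_dir / "instability_between.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for cond in report.conditions:
        label = "full data" if cond == FULL_DATA else f"leave out {float(cond) * 100:.0f}%"
        ax.plot(ks, [report.cells[(k, cond)].quality.mean_q for k in ks], "o-", ms=3, label=label)
    ax.plot(ks, report.mean_quality(), "k--", label="condition mean")
    ax.set_xlabel("number of clusters")
    ax.set_ylabel("mean quality of mean set")
    ax.set_xticks(ks)
    ax.set_xlim(ks.min() - 0.5, ks.max() + 0.5)
    ax.legend(fontsize=8)
    p = out_dir / "quality.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    k_sel = report.selected_k or int(ks[np.argmax(report.mean_quality())])
    q = report.cells[(k_sel, FULL_DATA)].quality if (k_sel, FULL_DATA) in report.cells else None
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if q is not None:
        vals = np.where(np.isfinite(q.per_cluster_q), q.per_cluster_q, 0.0)
        ax.bar(np.arange(len(vals)), vals)
        ax.axhline(q.mean_q, color="r", ls="--", label=f"mean {q.mean_q:.2f}")
        ax.legend(fontsize=8)
    ax.set_xlabel(f"cluster (k = {k_sel})")
    ax.set_ylabel("quality Q")
    p = out_dir / "quality_per_cluster.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths


def segment_ribbon(sl: SegmentList, out, group_map: dict | None = None) -> None:
    """Horizontal ribbon of the segmentation (one colour per prototype)."""
    labels = sorted(set(int(s[0]) for s in sl.segments))
    cmap = plt.cm.tab10
    fig, ax = plt.subplots(figsize=(8, 1.8))
    for label, start, end, _ in sl.segments:
        ax.axvspan(start, end, color=cmap(labels.index(int(label)) % 10), lw=0)
    ax.set_xlabel("time (ms)")
    ax.set_yticks([])
    if group_map:
        from matplotlib.patches import Patch

        handles = [
            Patch(color=cmap(labels.index(l) % 10), label=f"{l} ({group_map[l]})")
            for l in labels
        ]
        ax.legend(handles=handles, fontsize=7, ncol=min(len(labels), 5), loc="upper right")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
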