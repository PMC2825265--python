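"""Segmentation of label sequences into prototypical movements.

Assigning every time step to its nearest prototype turns a trajectory
into a label sequence; maximal runs of a constant label are the
prototypical movements, and the run length is the movement's duration.
No smoothing or minimum-duration suppression is applied by default: very
short segments are reported as such, since they reflect classification
uncertainty rather than noise to be hidden (an optional post-filter
exists as an extension).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CentroidSet, SegmentList, VELOCITY_FEATURES

__all__ = ["segment_labels", "merge_short_segments", "duration_stats", "classify_prototypes",
           "ROTATIONAL", "TRANSLATIONAL"]

ROTATIONAL = "rotational"
TRANSLATIONAL = "translational"


def segment_labels(labels, dt: float, t0: float = 0.0) -> SegmentList:
    """Maximal constant-label runs; duration = run length * dt (ms).

    Segment i covers [start_ms, end_ms) with end_ms exclusive, so the
    segments tile the sequence exactly.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    segs = tuple(
        (int(labels[s]), t0 + s * dt, t0 + e * dt, (e - s) * dt)
        for s, e in zip(starts, ends)
    )
    return SegmentList(segs, len(labels))


def merge_short_segments(sl: SegmentList, min_duration: float, dt: float) -> SegmentList:
    """Optional post-filter: absorb runs shorter than ``min_duration`` into
    the preceding segment (the first segment is never absorbed).

    Off by default in every pipeline; an extension, not part of the core
    procedure.
    """
    if min_duration <= 0:
        return sl
    kept = []
    for seg in sl.segments:
        label, start, end, dur = seg
        if kept and dur < min_duration:
            kept[-1][2] = end
            kept[-1][3] += dur
        else:
            kept.append(list(seg))
    # re-merge adjacent equal labels created by absorption
    merged = [kept[0]]
    for seg in kept[1:]:
        if seg[0] == merged[-1][0]:
            merged[-1][2] = seg[2]
            merged[-1][3] += seg[3]
        else:
            merged.append(seg)
    return SegmentList(tuple(tuple(s) for s in merged), sl.source_length)


def duration_stats(sl: SegmentList, group_map: dict, threshold: float = 20.0) -> pd.DataFrame:
    """Per-group duration summaries of the segments.

    ``group_map`` maps every prototype label to a group name (e.g.
    rotational/translational).  Returns a DataFrame indexed by group with
    columns n, mean_ms, median_ms, sd_ms and frac_gt_threshold (the
    fraction of segments longer than ``threshold`` ms, default 20 ms —
    the canonical saccade/intersaccade duration boundary).
    """
    rows = {}
    labels = sl.labels()
    unmapped = sorted(set(labels.tolist()) - set(group_map))
    if unmapped:
        raise ValueError(f"labels without a group: {unmapped}")
    durations = sl.durations()
    groups = np.array([group_map[l] for l in labels])
    for g in sorted(set(groups.tolist())):
        d = durations[groups == g]
        rows[g] = {
            "n": len(d),
            "mean_ms": float(d.mean()),
            "median_ms": float(np.median(d)),
            "sd_ms": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
            "frac_gt_threshold": float((d > threshold).mean()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_prototypes(cs: CentroidSet, factor: float = 1.0, norm=None) -> dict:
    """Label each prototype rotational or translational.

    Works on normalized centroid components (rotational deg/ms and
    translational m/s are otherwise incommensurable): a prototype is
    *rotational* when its largest absolute normalized rotational component
    exceeds ``factor`` times its largest absolute normalized translational
    component, else *translational*.  ``cs`` may be in normalized space
    (norm attached) or physical units with ``norm`` supplied.

    Only defined for the canonical six-velocity feature set.
    """
    if tuple(cs.names) != tuple(VELOCITY_FEATURES):
        raise ValueError(
            "prototype classification is defined for the six-velocity feature "
            f"set {VELOCITY_FEATURES}; got {cs.names} — supply a custom rule"
        )
    params = cs.norm if cs.norm is not None else norm
    if params is not None and cs.norm is None:
        # physical units -> normalized space
        centroids = (cs.centroids - params.mean) / params.sd
    else:
        centroids = cs.centroids
    trans = np.abs(centroids[:, :3]).max(axis=1)
    rot = np.abs(centroids[:, 3:]).max(axis=1)
    return {
        j: (ROTATIONAL if rot[j] > factor * trans[j] else TRANSLATIONAL)
        for j in range(cs.k)
    }
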