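"""On-disk and in-memory representations of trajectories, features and centroids.

Unit conventions, fixed package-wide:

* time in milliseconds, positions in metres, angles in degrees;
* translational velocities in m/s, rotational velocities in deg/ms;
* orientation as Tait-Bryan yaw/pitch/roll, intrinsic Z-Y'-X'' order,
  right-handed body frame with x forward, y leftward, z up.  Positive yaw
  is a left turn, positive pitch is head-down, positive roll is clockwise
  seen from behind.

All readers validate invariants and reject broken files rather than
repairing them silently; every writer/reader pair round-trips losslessly
to within 1e-12.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory6D",
    "FeatureMatrix",
    "NormalizationParams",
    "CentroidSet",
    "SegmentList",
    "FormatError",
    "SamplingError",
    "read_trajectory",
    "write_trajectory",
    "read_features",
    "write_features",
    "read_centroids",
    "write_centroids",
    "read_segments",
    "write_segments",
    "TRAJECTORY_COLUMNS",
    "VELOCITY_FEATURES",
    "VELOCITY_UNITS",
]

TRAJECTORY_COLUMNS = ("t", "x", "y", "z", "yaw", "pitch", "roll")

#: canonical six-velocity feature set produced by the features module
VELOCITY_FEATURES = ("forward", "sideward", "upward", "yaw", "pitch", "roll")
VELOCITY_UNITS = ("m/s", "m/s", "m/s", "deg/ms", "deg/ms", "deg/ms")

_DT_RTOL = 1e-9


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class SamplingError(ValueError):
    """Time stamps are not uniformly sampled."""


def _as_2d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Trajectory6D:
    """Uniformly sampled 6-DOF head/body trajectory.

    ``t`` in ms (strictly increasing, constant step), ``pos`` (T, 3) in
    metres (world frame), ``ori`` (T, 3) yaw/pitch/roll in degrees.
    """

    t: np.ndarray
    pos: np.ndarray
    ori: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        pos = _as_2d(self.pos, "pos")
        ori = _as_2d(self.ori, "ori")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "pos", pos)
        object.__setattr__(self, "ori", ori)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if pos.shape != (len(t), 3) or ori.shape != (len(t), 3):
            raise ValueError("t, pos, ori lengths disagree")
        if not (np.isfinite(t).all() and np.isfinite(pos).all() and np.isfinite(ori).all()):
            raise ValueError("trajectory contains non-finite values")
        steps = np.diff(t)
        if (steps <= 0).any():
            idx = int(np.argmax(steps <= 0))
            raise SamplingError(f"time stamps not strictly increasing at index {idx + 1}")
        dt = steps[0]
        bad = np.abs(steps - dt) > _DT_RTOL * max(abs(dt), 1.0)
        if bad.any():
            idx = int(np.argmax(bad))
            raise SamplingError(
                f"non-uniform sampling at index {idx + 1}: step {steps[idx]} != {dt}"
            )

    @property
    def dt(self) -> float:
        """Sampling step in ms."""
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature mean/sd used for z-normalization (sd strictly positive)."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        if mean.shape != sd.shape or mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D and equally long")
        if (sd <= 0).any():
            raise ValueError("normalization sd must be strictly positive")

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormalizationParams":
        return cls(np.asarray(d["mean"], float), np.asarray(d["sd"], float))


@dataclass(frozen=True)
class FeatureMatrix:
    """T x F matrix of per-time-step feature values.

    ``norm`` is present when the columns are z-normalized; it holds the
    parameters needed to map back to physical units.  ``t`` (optional)
    carries the time stamp of each row in ms.
    """

    values: np.ndarray
    names: tuple
    units: tuple
    norm: NormalizationParams | None = None
    t: np.ndarray | None = None

    def __post_init__(self):
        values = _as_2d(self.values, "values")
        names = tuple(self.names)
        units = tuple(self.units)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "units", units)
        if len(names) != values.shape[1] or len(units) != values.shape[1]:
            raise ValueError("names/units length must equal number of columns")
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if not np.isfinite(values).all():
            raise ValueError("feature matrix contains NaN/Inf")
        if self.t is not None:
            t = np.asarray(self.t, float)
            object.__setattr__(self, "t", t)
            if t.shape != (values.shape[0],):
                raise ValueError("t length must equal number of rows")
        if self.norm is not None:
            if len(self.norm.mean) != values.shape[1]:
                raise ValueError("normalization parameter length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take(self, index: np.ndarray) -> "FeatureMatrix":
        """Row subset (keeps names/units/norm; drops or subsets t)."""
        t = self.t[index] if self.t is not None else None
        return FeatureMatrix(self.values[index], self.names, self.units, self.norm, t)


@dataclass(frozen=True)
class CentroidSet:
    """k cluster centroids in (normalized) feature space.

    ``shares`` is the fraction of the data assigned to each centroid,
    ``within_var`` the mean squared Euclidean distance of members to their
    centroid, ``feature_sd`` the per-cluster, per-feature member standard
    deviation (drawn as error bars in star plots).  ``norm`` records the
    z-normalization under which the centroids live so they can be mapped
    back to physical units.
    """

    centroids: np.ndarray
    shares: np.ndarray
    within_var: np.ndarray
    feature_sd: np.ndarray
    norm: NormalizationParams | None = None
    names: tuple = ()
    units: tuple = ()

    def __post_init__(self):
        c = _as_2d(self.centroids, "centroids")
        shares = np.asarray(self.shares, float)
        wv = np.asarray(self.within_var, float)
        fsd = _as_2d(self.feature_sd, "feature_sd")
        object.__setattr__(self, "centroids", c)
        object.__setattr__(self, "shares", shares)
        object.__setattr__(self, "within_var", wv)
        object.__setattr__(self, "feature_sd", fsd)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "units", tuple(self.units))
        k = c.shape[0]
        if k < 1:
            raise ValueError("need at least one centroid")
        if shares.shape != (k,) or wv.shape != (k,) or fsd.shape != c.shape:
            raise ValueError("centroid set field shapes disagree")
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError(f"shares must sum to 1, got {shares.sum()}")
        if (wv < 0).any():
            raise ValueError("within-cluster variances must be >= 0")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_features(self) -> int:
        return self.centroids.shape[1]


@dataclass(frozen=True)
class SegmentList:
    """Maximal runs of constant prototype label tiling a label sequence."""

    segments: tuple  # of (label, start_ms, end_ms, duration_ms)
    source_length: int

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(tuple(s) for s in self.segments))

    def labels(self) -> np.ndarray:
        return np.array([s[0] for s in self.segments])

    def durations(self) -> np.ndarray:
        return np.array([s[3] for s in self.segments], dtype=float)

    def __len__(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------------------
# trajectory CSV


def read_trajectory(path, dialect: Mapping[str, str] | None = None) -> Trajectory6D:
    """Read a trajectory CSV (header row; default columns t,x,y,z,yaw,pitch,roll).

    ``dialect`` maps canonical column names to the file's column names,
    e.g. ``{"t": "time_ms"}``.  Units must already be ms/m/deg.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    colmap = {c: c for c in TRAJECTORY_COLUMNS}
    if dialect:
        colmap.update({k: v for k, v in dialect.items() if k in colmap})
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df[colmap["t"]].to_numpy(float)
    pos = df[[colmap["x"], colmap["y"], colmap["z"]]].to_numpy(float)
    ori = df[[colmap["yaw"], colmap["pitch"], colmap["roll"]]].to_numpy(float)
    return Trajectory6D(t, pos, ori)


def write_trajectory(traj: Trajectory6D, path) -> None:
    df = pd.DataFrame(
        np.column_stack([traj.t, traj.pos, traj.ori]), columns=list(TRAJECTORY_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# feature TSV (+ sidecar JSON for units / normalization / time stamps)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_features(fm: FeatureMatrix, path) -> None:
    path = Path(path)
    pd.DataFrame(fm.values, columns=list(fm.names)).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    meta = {
        "units": list(fm.units),
        "norm": fm.norm.to_dict() if fm.norm is not None else None,
        "t": fm.t.tolist() if fm.t is not None else None,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_features(path) -> FeatureMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = _sidecar(path)
    units = ["" for _ in df.columns]
    norm = None
    t = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        units = meta.get("units") or units
        if meta.get("norm") is not None:
            norm = NormalizationParams.from_dict(meta["norm"])
        if meta.get("t") is not None:
            t = np.asarray(meta["t"], float)
    return FeatureMatrix(df.to_numpy(float), tuple(df.columns), tuple(units), norm, t)


# ---------------------------------------------------------------------------
# centroid JSON


def write_centroids(cs: CentroidSet, path) -> None:
    doc = {
        "format": "ethoproto-centroids-v1",
        "centroids": cs.centroids.tolist(),
        "shares": cs.shares.tolist(),
        "within_var": cs.within_var.tolist(),
        "feature_sd": cs.feature_sd.tolist(),
        "norm": cs.norm.to_dict() if cs.norm is not None else None,
        "names": list(cs.names),
        "units": list(cs.units),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_centroids(path) -> CentroidSet:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    try:
        norm = (
            NormalizationParams.from_dict(doc["norm"]) if doc.get("norm") is not None else None
        )
        return CentroidSet(
            np.asarray(doc["centroids"], float),
            np.asarray(doc["shares"], float),
            np.asarray(doc["within_var"], float),
            np.asarray(doc["feature_sd"], float),
            norm,
            tuple(doc.get("names", ())),
            tuple(doc.get("units", ())),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing field {exc}") from exc


# ---------------------------------------------------------------------------
# segment TSV


def write_segments(sl: SegmentList, path) -> None:
    df = pd.DataFrame(
        list(sl.segments), columns=["label", "start_ms", "end_ms", "duration_ms"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_segments(path, source_length: int | None = None) -> SegmentList:
    df = pd.read_csv(path, sep="\t")
    required = {"label", "start_ms", "end_ms", "duration_ms"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: segment table needs columns {sorted(required)}")
    segs = [
        (int(r.label), float(r.start_ms), float(r.end_ms), float(r.duration_ms))
        for r in df.itertuples()
    ]
    return SegmentList(tuple(segs), source_length if source_length is not None else len(segs))
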