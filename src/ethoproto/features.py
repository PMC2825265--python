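"""Velocity feature extraction from 6-DOF trajectories.

The discriminative features for prototypical-movement discovery are the
three translational (forward, sideward, upward; m/s) and three rotational
(yaw, pitch, roll; deg/ms) velocities of the head, measured in the
head-centred coordinate system.  Expressing velocities in the body frame
makes them independent of where in the arena the animal is and which way
it faces, so the same manoeuvre always produces the same feature vector.

Per time step i the world displacement ``pos[i+1] - pos[i]`` is rotated
into the body frame at time i; the orientation change is the relative
rotation R_i^-1 R_{i+1} expressed as a rotation vector (axis-angle) on the
body axes, which for the sub-2 deg/ms rates of fly flight at 1 ms sampling
equals the per-axis angular rates to well below 0.1%.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .io import (
    CentroidSet,
    FeatureMatrix,
    NormalizationParams,
    Trajectory6D,
    VELOCITY_FEATURES,
    VELOCITY_UNITS,
)

__all__ = [
    "smooth_trajectory",
    "body_frame_velocities",
    "znormalize",
    "renormalize",
    "renormalize_centroids",
    "pca_diagnostic",
    "PcaDiagnostic",
    "rotations_from_euler",
]


def rotations_from_euler(ori_deg: np.ndarray) -> Rotation:
    """Body->world rotations from yaw/pitch/roll (deg), intrinsic Z-Y'-X''."""
    return Rotation.from_euler("ZYX", ori_deg, degrees=True)


def smooth_trajectory(traj: Trajectory6D, order: int = 2, rel_cutoff: float = 0.1) -> Trajectory6D:
    """Zero-phase Butterworth smoothing of all six trajectory channels.

    The filter is applied forward and backward (``filtfilt``), i.e. twice,
    which doubles the attenuation and cancels the phase shift, so features
    extracted afterwards are not displaced in time.  ``rel_cutoff`` is the
    border frequency relative to the Nyquist frequency.
    """
    if not 0 < rel_cutoff < 1:
        raise ValueError("rel_cutoff must be in (0, 1)")
    if len(traj) <= 3 * order:
        raise ValueError(f"trajectory too short to filter: {len(traj)} samples")
    b, a = butter(order, rel_cutoff)
    pos = filtfilt(b, a, traj.pos, axis=0)
    ori = filtfilt(b, a, traj.ori, axis=0)
    return Trajectory6D(traj.t, pos, ori)


def body_frame_velocities(traj: Trajectory6D) -> FeatureMatrix:
    """Six body-frame velocities per time step (T-1 rows, stamped at t[i]).

    Translational columns are in m/s, rotational in deg/ms.  Forward is the
    body x axis, sideward the body y axis (positive left), upward the body
    z axis.  Positive yaw = left turn, positive pitch = head down, positive
    roll = clockwise viewed from behind.
    """
    dt_ms = traj.dt
    rot = rotations_from_euler(traj.ori[:-1])
    disp = traj.pos[1:] - traj.pos[:-1]
    v_body = rot.apply(disp, inverse=True) / dt_ms * 1000.0  # m/ms -> m/s

    rot_next = rotations_from_euler(traj.ori[1:])
    rel = rot.inv() * rot_next
    rotvec_deg = rel.as_rotvec(degrees=True)  # body-frame axis-angle, deg
    omega = rotvec_deg / dt_ms  # deg/ms, columns = (roll, pitch, yaw) about x,y,z
    values = np.column_stack([v_body, omega[:, 2], omega[:, 1], omega[:, 0]])
    return FeatureMatrix(values, VELOCITY_FEATURES, VELOCITY_UNITS, t=traj.t[:-1])


def znormalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Normalize each feature column to zero mean, unit standard deviation.

    The parameters are attached so centroids can later be mapped back to
    physical units, and so reduced data sets can be normalized on the same
    scale as the full set (required to compare centroids across data-set
    conditions).
    """
    mean = fm.values.mean(axis=0)
    sd = fm.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"constant (degenerate) feature column(s): {[fm.names[i] for i in dead]}")
    values = (fm.values - mean) / sd
    return FeatureMatrix(values, fm.names, fm.units, NormalizationParams(mean, sd), fm.t)


def renormalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Inverse of :func:`znormalize` (restores physical units)."""
    if fm.norm is None:
        raise ValueError("feature matrix carries no normalization parameters")
    values = fm.values * fm.norm.sd + fm.norm.mean
    return FeatureMatrix(values, fm.names, fm.units, None, fm.t)


def renormalize_centroids(cs: CentroidSet) -> CentroidSet:
    """Map a centroid set from normalized space back to physical units.

    The centroids become the feature prototypes with their respective
    physical units; per-cluster feature sds scale by the feature sd.
    Within-cluster variances are left in normalized units (they mix
    features of different units and are only compared between clusterings).
    """
    if cs.norm is None:
        raise ValueError("centroid set carries no normalization parameters")
    centroids = cs.centroids * cs.norm.sd + cs.norm.mean
    feature_sd = cs.feature_sd * cs.norm.sd
    return CentroidSet(centroids, cs.shares, cs.within_var, feature_sd, None, cs.names, cs.units)


class PcaDiagnostic:
    """Variance split over principal components of one feature group."""

    def __init__(self, variance_fraction: np.ndarray, loadings: np.ndarray, names: tuple):
        variance_fraction = np.asarray(variance_fraction, float)
        if abs(variance_fraction.sum() - 1.0) > 1e-9:
            raise ValueError("variance fractions must sum to 1")
        if (np.diff(variance_fraction) > 1e-12).any():
            raise ValueError("variance fractions must be non-increasing")
        self.variance_fraction = variance_fraction
        self.loadings = np.asarray(loadings, float)  # components x features
        self.names = tuple(names)

    def __repr__(self):
        frac = ", ".join(f"{f:.3f}" for f in self.variance_fraction)
        return f"PcaDiagnostic({'/'.join(self.names)}: [{frac}])"


def pca_diagnostic(fm: FeatureMatrix, groups) -> list:
    """PCA within each feature group, as a linear-dependence diagnostic.

    ``groups`` is an iterable of feature-name lists (e.g. the translational
    and the rotational trio analysed independently).  A group whose leading
    components carry nearly all variance signals that the group could be
    reduced in dimension; an even split says every feature carries
    independent information and all should be kept.
    """
    out = []
    for group in groups:
        group = list(group)
        if len(group) < 2:
            raise ValueError(f"PCA group needs >= 2 features, got {group}")
        idx = [fm.names.index(g) for g in group]
        sub = fm.values[:, idx]
        cov = np.cov(sub, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0, None)
        loadings = evecs[:, order].T
        out.append(PcaDiagnostic(evals / evals.sum(), loadings, group))
    return out
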