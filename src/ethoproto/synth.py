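"""Synthetic inputs with known ground truth.

Two generators:

* an axis-aligned Gaussian-mixture benchmark in 2-D feature space — five
  well-separated clouds of unequal weight, the classic test bed for the
  clustering and validation machinery;
* a fly-like saccadic flight simulator producing a 6-DOF head trajectory
  as a semi-Markov alternation of *intersaccades* (sustained body-frame
  translation: forward 0.23-0.64 m/s coupled with downward motion up to
  0.31 m/s and symmetric sideward components up to ~0.15 m/s, negligible
  rotation) and brief *saccades* (fast yaw of ~1.1 deg/ms with coupled
  roll and up/down pitch variants, forward drift ~0.4 m/s).  Within a
  state the body-frame velocity is the state mean plus white Gaussian
  noise; the trajectory is obtained by exact integration of those
  velocities (the inverse of the body-frame differencing used for feature
  extraction), and the generating state of every time step is returned.

The simulator is a statistical fixture, not an aerodynamic model: it has
sharp state switches, white within-state noise and no measurement noise
on positions, which is what makes exact parameter-recovery experiments
possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .io import FeatureMatrix, Trajectory6D, VELOCITY_FEATURES, VELOCITY_UNITS

__all__ = [
    "MixtureSpec",
    "gaussian_mixture",
    "default_artificial_spec",
    "FlightState",
    "FlightSpec",
    "default_flight_spec",
    "simulate_flight",
]


# ---------------------------------------------------------------------------
# Gaussian mixture benchmark


@dataclass(frozen=True)
class MixtureSpec:
    """Axis-aligned Gaussian mixture: k components in F dimensions."""

    means: np.ndarray  # k x F
    sds: np.ndarray  # k x F, > 0
    weights: np.ndarray  # k, sums to 1
    n: int
    seed: int

    def __post_init__(self):
        means = np.atleast_2d(np.asarray(self.means, float))
        sds = np.atleast_2d(np.asarray(self.sds, float))
        weights = np.asarray(self.weights, float)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "weights", weights)
        if sds.shape != means.shape or weights.shape != (means.shape[0],):
            raise ValueError("means/sds/weights shapes disagree")
        if (sds <= 0).any():
            raise ValueError("component sds must be positive")
        if abs(weights.sum() - 1.0) > 1e-9 or (weights < 0).any():
            raise ValueError("weights must be non-negative and sum to 1")
        if self.n < 1:
            raise ValueError("n must be positive")

    @property
    def k(self) -> int:
        return self.means.shape[0]


def gaussian_mixture(spec: MixtureSpec):
    """Sample the mixture; returns (FeatureMatrix, true component labels)."""
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(spec.k, size=spec.n, p=spec.weights)
    values = rng.normal(spec.means[labels], spec.sds[labels])
    names = tuple(f"f{i}" for i in range(spec.means.shape[1]))
    units = tuple("" for _ in names)
    return FeatureMatrix(values, names, units), labels


def default_artificial_spec(n: int = 500, seed: int = 20100222) -> MixtureSpec:
    """Five well-separated 2-D clouds of unequal weight.

    Nearest centroid pair is 8 apart at component sd 0.7 (>= 11x sd), so
    the five-cluster structure is unambiguous — the regime in which the
    joining-cost elbow, the instability minimum and the quality maximum
    all agree on k = 5.
    """
    means = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0], [8.0, 8.0], [4.0, 16.0]])
    sds = np.full((5, 2), 0.7)
    weights = np.array([0.30, 0.25, 0.20, 0.15, 0.10])
    return MixtureSpec(means, sds, weights, n, seed)


# ---------------------------------------------------------------------------
# fly-like saccadic flight simulator


@dataclass(frozen=True)
class FlightState:
    """One semi-Markov state: mean body-frame velocity + dwell-time law.

    ``velocity`` is (forward, sideward, upward, yaw, pitch, roll) in
    m/s and deg/ms; dwell times are gamma(shape, mean/shape) in ms.
    """

    name: str
    velocity: tuple
    dwell_mean: float
    dwell_shape: float
    group: str  # "saccade" or "intersaccade"

    def __post_init__(self):
        if len(self.velocity) != 6:
            raise ValueError("state velocity must have 6 components")
        if self.dwell_mean <= 0 or self.dwell_shape <= 0:
            raise ValueError("dwell mean and shape must be positive")


# yaw/roll are coupled with equal sign (a left turn rolls clockwise);
# pitch-up and pitch-down variants exist for either turning direction
_SACCADE_STATES = (
    FlightState("sacc_L_up", (0.4, 0.0, 0.0, 1.1, -0.25, 0.35), 12.0, 4.0, "saccade"),
    FlightState("sacc_L_down", (0.4, 0.0, 0.0, 1.1, 0.25, 0.35), 12.0, 4.0, "saccade"),
    FlightState("sacc_R_up", (0.4, 0.0, 0.0, -1.1, -0.25, -0.35), 12.0, 4.0, "saccade"),
    FlightState("sacc_R_down", (0.4, 0.0, 0.0, -1.1, 0.25, -0.35), 12.0, 4.0, "saccade"),
)

# forward 0.23-0.64 m/s coupled with downward (negative upward) velocity
# 0.02-0.31 m/s; sideward symmetric up to 0.15 m/s; no rotation
_INTERSACCADE_STATES = (
    FlightState("inter_fast", (0.64, 0.0, -0.31, 0.0, 0.0, 0.0), 40.0, 2.0, "intersaccade"),
    FlightState("inter_slow", (0.23, 0.0, -0.02, 0.0, 0.0, 0.0), 40.0, 2.0, "intersaccade"),
    FlightState("inter_left", (0.40, 0.15, -0.15, 0.0, 0.0, 0.0), 40.0, 2.0, "intersaccade"),
    FlightState("inter_right", (0.40, -0.15, -0.15, 0.0, 0.0, 0.0), 40.0, 2.0, "intersaccade"),
    FlightState("inter_mid", (0.50, 0.0, -0.20, 0.0, 0.0, 0.0), 40.0, 2.0, "intersaccade"),
)


@dataclass(frozen=True)
class FlightSpec:
    """Semi-Markov saccade/intersaccade alternation.

    Every intersaccade is followed by a uniformly drawn saccade state and
    vice versa; within a state the body-frame velocity is the state mean
    plus independent Gaussian noise (``noise_trans`` m/s on the
    translational, ``noise_rot`` deg/ms on the rotational axes).
    """

    dt: float = 1.0  # ms
    duration: float = 60000.0  # ms
    saccade_states: tuple = _SACCADE_STATES
    intersaccade_states: tuple = _INTERSACCADE_STATES
    noise_trans: float = 0.025
    noise_rot: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if not self.saccade_states or not self.intersaccade_states:
            raise ValueError("need at least one state per group")
        sac_mean = max(s.dwell_mean for s in self.saccade_states)
        inter_mean = min(s.dwell_mean for s in self.intersaccade_states)
        if sac_mean >= inter_mean:
            raise ValueError("saccades must dwell shorter than intersaccades")
        if self.dt <= 0 or self.duration < 2 * self.dt:
            raise ValueError("invalid dt/duration")
        if self.noise_trans < 0 or self.noise_rot < 0:
            raise ValueError("noise sds must be >= 0")

    @property
    def states(self) -> tuple:
        return self.saccade_states + self.intersaccade_states

    def state_means(self) -> np.ndarray:
        return np.array([s.velocity for s in self.states])

    def expected_saccade_time_fraction(self) -> float:
        sac = np.mean([s.dwell_mean for s in self.saccade_states])
        inter = np.mean([s.dwell_mean for s in self.intersaccade_states])
        return sac / (sac + inter)


def default_flight_spec(duration: float = 60000.0, seed: int = 0) -> FlightSpec:
    """Default 4-saccade + 5-intersaccade simulator (60 s at 1 ms)."""
    return FlightSpec(duration=duration, seed=seed)


def _state_sequence(spec: FlightSpec, n_steps: int, rng) -> np.ndarray:
    """Ground-truth state index per time step (semi-Markov alternation)."""
    states = spec.states
    n_sac = len(spec.saccade_states)
    seq = np.empty(n_steps, dtype=int)
    pos = 0
    in_saccade = False  # start with an intersaccade
    while pos < n_steps:
        if in_saccade:
            idx = rng.integers(0, n_sac)
        else:
            idx = n_sac + rng.integers(0, len(spec.intersaccade_states))
        st = states[idx]
        dwell_ms = rng.gamma(st.dwell_shape, st.dwell_mean / st.dwell_shape)
        n_dwell = max(1, int(round(dwell_ms / spec.dt)))
        seq[pos : pos + n_dwell] = idx
        pos += n_dwell
        in_saccade = not in_saccade
    return seq


def simulate_flight(spec: FlightSpec):
    """Simulate; returns (Trajectory6D, ground-truth state index per step).

    Velocity row i of the trajectory's body-frame differencing recovers
    exactly the simulated velocity of step i (the integrator is the exact
    inverse of the feature extraction): position advances by the body
    velocity rotated into the world frame, orientation by the body-frame
    rotation vector, both over one ``dt``.
    """
    rng = np.random.default_rng(spec.seed)
    n_steps = int(round(spec.duration / spec.dt))  # velocity steps
    states = _state_sequence(spec, n_steps, rng)
    means = spec.state_means()[states]
    noise = np.column_stack(
        [
            rng.normal(0.0, spec.noise_trans, size=(n_steps, 3)),
            rng.normal(0.0, spec.noise_rot, size=(n_steps, 3)),
        ]
    )
    vel = means + noise  # (fwd, side, up) m/s ; (yaw, pitch, roll) deg/ms

    t = np.arange(n_steps + 1) * spec.dt
    pos = np.zeros((n_steps + 1, 3))
    ori = np.zeros((n_steps + 1, 3))
    R = Rotation.identity()
    rotvecs_deg = np.column_stack([vel[:, 5], vel[:, 4], vel[:, 3]]) * spec.dt  # x,y,z axes
    step_m = vel[:, :3] * spec.dt / 1000.0  # m/s * ms -> m
    import warnings

    with warnings.catch_warnings():
        # long runs can random-walk the pitch through +-90 deg; the Euler
        # triple returned at gimbal lock still composes to the exact
        # rotation, so the decomposition warning is noise here
        warnings.filterwarnings("ignore", message="Gimbal lock")
        for i in range(n_steps):
            pos[i + 1] = pos[i] + R.apply(step_m[i])
            R = R * Rotation.from_rotvec(rotvecs_deg[i], degrees=True)
            ori[i + 1] = R.as_euler("ZYX", degrees=True)
    traj = Trajectory6D(t, pos, ori)
    return traj, states
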