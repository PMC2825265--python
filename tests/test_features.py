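import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import feature_matrix
from ethoproto import (
    Trajectory6D,
    body_frame_velocities,
    pca_diagnostic,
    renormalize_centroids,
    smooth_trajectory,
    znormalize,
)
from ethoproto.features import renormalize
from ethoproto.io import CentroidSet, NormalizationParams


def traj_from(pos=None, ori=None, n=100, dt=1.0):
    t = np.arange(n) * dt
    pos = np.zeros((n, 3)) if pos is None else np.asarray(pos, float)
    ori = np.zeros((n, 3)) if ori is None else np.asarray(ori, float)
    return Trajectory6D(t, pos, ori)


class TestSmoothing:
    def test_dc_passes(self):
        traj = traj_from(pos=np.full((100, 3), 0.25), ori=np.full((100, 3), 12.0))
        out = smooth_trajectory(traj)
        np.testing.assert_allclose(out.pos, traj.pos, atol=1e-9)
        np.testing.assert_allclose(out.ori, traj.ori, atol=1e-9)
        np.testing.assert_array_equal(out.t, traj.t)

    def test_zero_phase_on_symmetric_pulse(self):
        # symmetric input with long quiet tails -> symmetric output
        # (forward+backward filtering cancels the phase shift)
        n = 601
        pos = np.zeros((n, 3))
        pos[250:351, 0] = np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:]])
        out = smooth_trajectory(traj_from(pos=pos, n=n))
        np.testing.assert_allclose(out.pos[:, 0], out.pos[::-1, 0], atol=1e-9)

    def test_sine_attenuation_matches_analytic_squared_response(self):
        # forward+backward pass of an order-2 Butterworth attenuates a sine
        # at relative frequency f by |H(f)|^2 = 1 / (1 + (f/fc)^4)
        n, rel_f, rel_cutoff = 1000, 0.4, 0.1
        phase = np.pi * rel_f * np.arange(n)  # rel. to Nyquist
        pos = np.zeros((n, 3))
        pos[:, 0] = np.sin(phase)
        out = smooth_trajectory(traj_from(pos=pos, n=n), order=2, rel_cutoff=rel_cutoff)
        # order-2 digital Butterworth via bilinear transform: |H|^2 at the
        # prewarped frequency ratio, applied twice by the two passes
        warped = np.tan(np.pi * rel_f / 2) / np.tan(np.pi * rel_cutoff / 2)
        expected = 1.0 / (1.0 + warped**4)
        mid = slice(n // 4, -n // 4)
        y, ph = out.pos[mid, 0], phase[mid]
        # quadrature demodulation: amplitude of the sine in the settled middle
        measured = 2.0 * np.hypot((y * np.sin(ph)).mean(), (y * np.cos(ph)).mean())
        assert measured == pytest.approx(expected, rel=0.02)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            smooth_trajectory(traj_from(n=5), order=2)


class TestBodyFrameVelocities:
    def test_translation_rotates_into_body_frame(self):
        # moving along world +x at 0.5 m/s while facing +y (yaw = 90):
        # the motion is purely sideward in the body frame
        n = 5
        pos = np.column_stack([np.arange(n) * 5e-4, np.zeros(n), np.zeros(n)])
        ori = np.column_stack([np.full(n, 90.0), np.zeros(n), np.zeros(n)])
        fm = body_frame_velocities(traj_from(pos=pos, ori=ori, n=n))
        assert fm.values.shape == (n - 1, 6)
        np.testing.assert_allclose(np.abs(fm.values[:, 1]), 0.5, atol=1e-9)  # sideward
        np.testing.assert_allclose(fm.values[:, 0], 0.0, atol=1e-9)  # forward
        np.testing.assert_allclose(fm.values[:, 2:], 0.0, atol=1e-9)

    def test_pure_yaw_rate(self):
        n = 10
        ori = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
        fm = body_frame_velocities(traj_from(ori=ori, n=n))
        np.testing.assert_allclose(fm.values[:, 3], 1.0, atol=1e-9)  # yaw deg/ms
        mask = np.ones(6, bool)
        mask[3] = False
        np.testing.assert_allclose(fm.values[:, mask], 0.0, atol=1e-9)

    def test_circular_flight_closed_form(self):
        # heading tangent to a circle: constant forward speed v, yaw rate w,
        # sideward ~ 0 (discretization error O(w*dt))
        v, w, dt = 0.5, 1.0, 1.0  # m/s, deg/ms, ms
        n = 200
        radius = v / 1000.0 / np.deg2rad(w)  # m per ms over rad per ms
        theta = np.deg2rad(w) * np.arange(n) * dt
        pos = np.column_stack([radius * np.sin(theta), radius * (1 - np.cos(theta)), np.zeros(n)])
        ori = np.column_stack([np.rad2deg(theta), np.zeros(n), np.zeros(n)])
        fm = body_frame_velocities(Trajectory6D(np.arange(n) * dt, pos, ori))
        # chord-vs-arc error is ~ (w*dt)^2/24, well below 1e-3 relative here
        np.testing.assert_allclose(fm.values[:, 0], v, rtol=1e-3)
        np.testing.assert_allclose(fm.values[:, 1], 0.0, atol=v * np.deg2rad(w) * dt)
        np.testing.assert_allclose(fm.values[:, 3], w, atol=1e-9)

    def test_invariance_under_world_rotation(self, rng):
        # body-frame features must not change when the whole trajectory is
        # rigidly rotated in the world (the reason for the body frame)
        n = 50
        pos = np.cumsum(rng.normal(scale=1e-4, size=(n, 3)), axis=0)
        ori = np.cumsum(rng.normal(scale=0.5, size=(n, 3)), axis=0)
        traj = traj_from(pos=pos, ori=ori, n=n)
        world = Rotation.from_euler("ZYX", [35.0, -20.0, 10.0], degrees=True)
        pos2 = world.apply(pos)
        ori2 = (world * Rotation.from_euler("ZYX", ori, degrees=True)).as_euler(
            "ZYX", degrees=True
        )
        fm1 = body_frame_velocities(traj)
        fm2 = body_frame_velocities(traj_from(pos=pos2, ori=ori2, n=n))
        np.testing.assert_allclose(fm1.values, fm2.values, atol=1e-8)


class TestNormalization:
    def test_column_stats(self):
        fm = znormalize(feature_matrix([[1.0], [2.0], [3.0]]))
        assert abs(fm.values.mean()) < 1e-8
        assert abs(fm.values.std() - 1.0) < 1e-8

    def test_round_trip(self, rng):
        fm = feature_matrix(rng.normal(loc=3.0, scale=2.0, size=(50, 4)))
        back = renormalize(znormalize(fm))
        np.testing.assert_allclose(back.values, fm.values, atol=1e-10)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="f1"):
            znormalize(feature_matrix([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))

    def test_renormalize_centroids_arithmetic(self):
        norm = NormalizationParams(np.array([0.1]), np.array([0.3]))
        cs = CentroidSet(
            np.array([[2.0]]), np.array([1.0]), np.array([0.0]), np.array([[1.0]]), norm
        )
        out = renormalize_centroids(cs)
        assert out.centroids[0, 0] == pytest.approx(0.7, abs=1e-12)
        assert out.feature_sd[0, 0] == pytest.approx(0.3, abs=1e-12)

    def test_renormalize_centroids_identity_and_round_trip(self, rng):
        ident = NormalizationParams(np.zeros(2), np.ones(2))
        c = rng.normal(size=(3, 2))
        cs = CentroidSet(c, np.full(3, 1 / 3), np.zeros(3), np.abs(c), ident)
        np.testing.assert_allclose(renormalize_centroids(cs).centroids, c, atol=1e-10)
        cs2 = CentroidSet(c, np.full(3, 1 / 3), np.zeros(3), np.abs(c),
                          NormalizationParams(np.array([1.0, -2.0]), np.array([0.5, 3.0])))
        phys = renormalize_centroids(cs2)
        back = (phys.centroids - cs2.norm.mean) / cs2.norm.sd
        np.testing.assert_allclose(back, c, atol=1e-10)

    def test_missing_norm_is_error(self):
        cs = CentroidSet(np.ones((1, 1)), np.array([1.0]), np.array([0.0]), np.ones((1, 1)))
        with pytest.raises(ValueError, match="normalization"):
            renormalize_centroids(cs)


class TestPcaDiagnostic:
    def test_line_in_2d(self):
        x = np.linspace(-1, 1, 100)
        fm = feature_matrix(np.column_stack([x, 2 * x]))
        (diag,) = pca_diagnostic(fm, [["f0", "f1"]])
        np.testing.assert_allclose(diag.variance_fraction, [1.0, 0.0], atol=1e-9)

    def test_isotropic_gaussian_splits_evenly(self, rng):
        fm = feature_matrix(rng.normal(size=(10000, 3)))
        (diag,) = pca_diagnostic(fm, [["f0", "f1", "f2"]])
        np.testing.assert_allclose(diag.variance_fraction, 1 / 3, atol=0.02)

    def test_fractions_conserved_and_sorted(self, rng):
        fm = feature_matrix(rng.normal(size=(200, 6)) * [1, 2, 3, 1, 5, 0.1])
        diags = pca_diagnostic(fm, [["f0", "f1", "f2"], ["f3", "f4", "f5"]])
        for d in diags:
            assert d.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
            assert (np.diff(d.variance_fraction) <= 1e-12).all()

    def test_small_group_rejected(self, rng):
        fm = feature_matrix(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            pca_diagnostic(fm, [["f0"]])
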