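"""Rigid-pose fitting, kinematic derivatives, filtering, channel extraction."""

import numpy as np
import pytest

import movescreen as ms
from movescreen.sensors import FilterSpec, fit_segment_pose_series
from movescreen.sensors import rotation_to_euler
from movescreen.sensors import zero_lag_butterworth

from conftest import random_rotation


def horn_quaternion_fit(obs, ref):
    """Independent absolute-orientation oracle (quaternion eigendecomposition)."""
    obs_c = obs - obs.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    M = ref_c.T @ obs_c
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    w, v = np.linalg.eigh(N)
    q = v[:, -1]
    w0, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w0 * z), 2 * (x * z + w0 * y)],
        [2 * (x * y + w0 * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w0 * x)],
        [2 * (x * z - w0 * y), 2 * (y * z + w0 * x), 1 - 2 * (x * x + y * y)],
    ])
    t = obs.mean(axis=0) - R @ ref.mean(axis=0)
    return R, t


class TestFitSegmentPose:
    def test_identity(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0.5, 1.0]])
        R, t = ms.fit_segment_pose(ref, ref)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0.0, atol=1e-12)

    def test_recovers_known_rotation_and_translation(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0.5, 1.0]])
        Rz90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        obs = ref @ Rz90.T + np.array([1.0, 0.0, 0.0])
        R, t = ms.fit_segment_pose(obs, ref)
        assert np.allclose(R, Rz90, atol=1e-12)
        assert np.allclose(t, [1, 0, 0], atol=1e-12)
        assert np.isclose(np.linalg.det(R), 1.0)

    def test_noisy_fit_matches_quaternion_oracle(self):
        rng = np.random.default_rng(42)
        ref = rng.normal(size=(4, 3))
        R_true = random_rotation(rng)
        obs = ref @ R_true.T + rng.normal(0, 1e-3, size=(4, 3)) + [0.3, -0.2, 0.9]
        R, t = ms.fit_segment_pose(obs, ref)
        Rq, tq = horn_quaternion_fit(obs, ref)
        rss = np.sum((ref @ R.T + t - obs) ** 2)
        rss_q = np.sum((ref @ Rq.T + tq - obs) ** 2)
        assert abs(rss - rss_q) < 1e-10

    def test_collinear_reference_rejected(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            ms.fit_segment_pose(ref, ref)

    def test_too_few_markers_rejected(self):
        ref = np.array([[0, 0, 0], [1, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="3 markers"):
            ms.fit_segment_pose(ref, ref)

    def test_noise_free_synthetic_residuals(self, body_model, noise_free_trial):
        seg = body_model.segments["shank_L"]
        obs = noise_free_trial.coords[:, body_model.marker_indices("shank_L")]
        R, t = fit_segment_pose_series(obs, seg.marker_local)
        recon = np.einsum("fij,mj->fmi", R, seg.marker_local) + t[:, None, :]
        assert np.abs(recon - obs).max() < 1e-10


class TestEulerAngles:
    def test_identity_gives_zero(self):
        ang, gimbal = rotation_to_euler(np.eye(3))
        assert np.allclose(ang, 0.0)
        assert not gimbal

    def test_single_axis_rotation(self):
        a = np.pi / 6
        Rx = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
        ang, _ = rotation_to_euler(Rx)
        assert np.allclose(ang, [a, 0, 0], atol=1e-12)

    def test_roundtrip_and_scipy_agreement(self):
        from scipy.spatial.transform import Rotation
        from movescreen.sensors import euler_to_rotation
        rng = np.random.default_rng(0)
        for _ in range(50):
            R = random_rotation(rng)
            ang, gimbal = rotation_to_euler(R)
            assert not gimbal
            assert np.abs(euler_to_rotation(ang) - R).max() < 1e-9
            ref = Rotation.from_matrix(R).as_euler("xyz")
            assert np.allclose(ang, ref, atol=1e-9)

    def test_gimbal_lock_flagged_and_third_angle_zeroed(self):
        from movescreen.sensors import euler_to_rotation
        R = euler_to_rotation(np.array([0.3, np.pi / 2, 0.0]))
        ang, gimbal = rotation_to_euler(R)
        assert gimbal
        assert ang[2] == 0.0
        assert np.abs(euler_to_rotation(ang) - R).max() < 1e-7


class TestAngularVelocity:
    def test_constant_spin_norm(self):
        fs, w = 120.0, 2.0
        t = np.arange(240) / fs
        c, s = np.cos(w * t), np.sin(w * t)
        R = np.zeros((240, 3, 3))
        R[:, 0, 0], R[:, 0, 1] = c, -s
        R[:, 1, 0], R[:, 1, 1] = s, c
        R[:, 2, 2] = 1.0
        omega = ms.angular_velocity_series(R, fs)
        norms = np.linalg.norm(omega[1:-1], axis=1)
        assert np.abs(norms - w).max() < 1e-4

    def test_static_series_is_zero(self):
        R = np.tile(np.eye(3), (10, 1, 1))
        assert np.abs(ms.angular_velocity_series(R, 120.0)).max() == 0.0

    def test_varying_rate_matches_analytic_derivative(self):
        # R(t) = Rz(sin t)  =>  omega_z(t) = cos t; second-order FD error
        # is bounded by max|alpha'''| * dt^2 / 6 plus the skew-extraction bias.
        fs = 120.0
        t = np.arange(360) / fs
        alpha = np.sin(t)
        c, s = np.cos(alpha), np.sin(alpha)
        R = np.zeros((360, 3, 3))
        R[:, 0, 0], R[:, 0, 1] = c, -s
        R[:, 1, 0], R[:, 1, 1] = s, c
        R[:, 2, 2] = 1.0
        omega = ms.angular_velocity_series(R, fs)
        dt = 1.0 / fs
        bound = dt**2 / 6 + dt**2  # derivative truncation + sin() linearization
        assert np.abs(omega[1:-1, 2] - np.cos(t[1:-1])).max() < bound

    def test_requires_three_frames(self):
        with pytest.raises(ValueError):
            ms.angular_velocity_series(np.tile(np.eye(3), (2, 1, 1)), 120.0)


class TestComAcceleration:
    def test_linear_path_has_zero_acceleration(self):
        t = np.arange(100) / 120.0
        com = np.stack([0.1 * t, -0.5 * t, 2.0 * t], axis=1)
        a = ms.com_acceleration_series(com, 120.0)
        assert np.abs(a[1:-1]).max() < 1e-9

    def test_constant_curvature_gravity(self):
        t = np.arange(100) / 120.0
        com = np.stack([np.zeros_like(t), np.zeros_like(t), -4.905 * t**2], axis=1)
        a = ms.com_acceleration_series(com, 120.0)
        assert np.abs(np.linalg.norm(a, axis=1) - 9.81).max() < 1e-6

    def test_sinusoid_peak_matches_analytic(self):
        fs, A, f = 120.0, 0.05, 3.0
        t = np.arange(600) / fs
        com = np.stack([A * np.sin(2 * np.pi * f * t),
                        np.zeros_like(t), np.zeros_like(t)], axis=1)
        a = ms.com_acceleration_series(com, fs)
        peak = np.abs(a[1:-1, 0]).max()
        expected = A * (2 * np.pi * f) ** 2
        # central second difference underestimates by sinc^2(pi f / fs)
        assert abs(peak - expected) / expected < (np.pi * f / fs) ** 2 / 2


class TestZeroLagButterworth:
    def test_dc_gain_unity(self):
        x = np.full(500, 3.7)
        y = zero_lag_butterworth(x, FilterSpec(), 120.0)
        assert np.abs(y - x).max() < 1e-10

    def test_cutoff_amplitude_is_half(self):
        fs = 120.0
        t = np.arange(4800) / fs
        x = np.sin(2 * np.pi * 15.0 * t)
        y = zero_lag_butterworth(x, FilterSpec(cutoff_hz=15.0), fs)
        amp = np.abs(y[1200:-1200]).max()
        assert abs(amp - 0.5) / 0.5 < 0.02

    def test_zero_phase_impulse_symmetry(self):
        x = np.zeros(801)
        x[400] = 1.0
        y = zero_lag_butterworth(x, FilterSpec(), 120.0)
        assert np.abs(y - y[::-1]).max() < 1e-9

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            zero_lag_butterworth(np.zeros(100), FilterSpec(cutoff_hz=70.0), 120.0)


class TestExtractChannels:
    def test_full_body_has_65_channels(self, body_model, noise_free_trial):
        s = ms.extract_simu_channels(noise_free_trial, body_model)
        assert s.data.shape[1] == 65
        assert len(s.channel_names) == 65
        assert np.array_equal(s.frame_labels, noise_free_trial.frame_labels)

    def test_torso_only_has_5_channels(self, body_model, noise_free_trial):
        s = ms.extract_simu_channels(noise_free_trial, body_model,
                                     segments=("torso",))
        assert s.data.shape[1] == 5

    def test_norm_channels_nonnegative(self, body_model, noise_free_trial):
        s = ms.extract_simu_channels(noise_free_trial, body_model)
        norms = s.data[:, np.array([3, 4] * 13) + np.repeat(np.arange(13) * 5, 2)]
        assert norms.min() >= -1e-12

    def test_static_trial_norms_vanish(self, body_model):
        t = ms.MovementTemplate(label="SDR", duration_s=1.0, side="right")
        trial = ms.synthesize_trial(t, noise_sd=0.0)
        s = ms.extract_simu_channels(trial, body_model)
        for i in range(13):
            assert np.abs(s.data[:, 5 * i + 3]).max() < 1e-6
            assert np.abs(s.data[:, 5 * i + 4]).max() < 1e-6

    def test_norms_invariant_to_global_rotation(self, body_model, noise_free_trial):
        rng = np.random.default_rng(3)
        Q = random_rotation(rng)
        rotated = ms.MarkerTrial(
            athlete_id="rot",
            coords=noise_free_trial.coords @ Q.T,
            fs=noise_free_trial.fs,
            frame_labels=noise_free_trial.frame_labels,
            marker_names=noise_free_trial.marker_names)
        s0 = ms.extract_simu_channels(noise_free_trial, body_model)
        s1 = ms.extract_simu_channels(rotated, body_model)
        norm_cols = np.array([3, 4] * 13) + np.repeat(np.arange(13) * 5, 2)
        assert np.abs(s0.data[:, norm_cols] - s1.data[:, norm_cols]).max() < 1e-8

    def test_missing_marker_error_names_marker_and_segment(self, body_model,
                                                           noise_free_trial):
        broken = ms.MarkerTrial(
            athlete_id="x",
            coords=noise_free_trial.coords[:, :-1],
            fs=120.0,
            frame_labels=noise_free_trial.frame_labels,
            marker_names=noise_free_trial.marker_names[:-1])
        with pytest.raises(ValueError, match="FOOT_R_4.*foot_R"):
            ms.extract_simu_channels(broken, body_model)


class TestSelectSensorConfig:
    def test_simu3l_selects_torso_and_shanks(self, body_model, noise_free_trial):
        s = ms.extract_simu_channels(noise_free_trial, body_model)
        sub = ms.select_sensor_config(s, "sIMU3L")
        assert sub.segments == ("torso", "shank_L", "shank_R")
        assert sub.data.shape[1] == 15

    def test_simu13_keeps_everything(self, body_model, noise_free_trial):
        s = ms.extract_simu_channels(noise_free_trial, body_model)
        sub = ms.select_sensor_config(s, "sIMU13")
        assert len(sub.segments) == 13
        assert sub.data.shape[1] == 65

    def test_unknown_code_lists_valid_codes(self, body_model, noise_free_trial):
        s = ms.extract_simu_channels(noise_free_trial, body_model)
        with pytest.raises(ValueError, match="sIMU13"):
            ms.select_sensor_config(s, "sIMU99")

    def test_all_table_codes_have_expected_sizes(self, body_model, noise_free_trial):
        s = ms.extract_simu_channels(noise_free_trial, body_model)
        sizes = {"sIMU1": 1, "sIMU2": 2, "sIMU3L": 3, "sIMU3U": 3, "sIMU4": 4,
                 "sIMU4D": 4, "sIMU4P": 4, "sIMU5": 5, "sIMU13": 13}
        for code, n in sizes.items():
            sub = ms.select_sensor_config(s, code)
            assert len(sub.segments) == n
            assert sub.data.shape[1] == 5 * n
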