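"""Simulated inertial-sensor channels from optical marker trajectories.

For each body segment, a least-squares rigid transform is fitted from the
model's reference marker cluster to the observed markers at every frame.
From the resulting pose series, five channels per segment are derived:

* 3 global orientation Euler angles (extrinsic X-Y-Z Cardan sequence, rad),
* the Euclidean norm of the segment angular velocity (rad/s),
* the Euclidean norm of the segment COM linear acceleration (m/s^2),

with the two norm channels low-pass filtered by a zero-lag (forward-
backward) second-order Butterworth filter, 15 Hz cutoff by default.  Norms
are used instead of vector components so the channels are invariant to any
fixed rotation of the global frame — the same rationale that makes real
IMU norms robust to sensor alignment.  The segment COM is approximated by
the centroid of the segment's markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .body import SEGMENT_ORDER, BodyModel
from .synthetic import MarkerTrial

__all__ = [
    "FilterSpec",
    "SimulatedIMUSeries",
    "SENSOR_CONFIGS",
    "fit_segment_pose",
    "fit_segment_pose_series",
    "rotation_to_euler",
    "angular_velocity_series",
    "com_acceleration_series",
    "zero_lag_butterworth",
    "extract_simu_channels",
    "select_sensor_config",
]

#: Body-segment membership of each sensor-set code (bilateral entries expanded).
SENSOR_CONFIGS: dict[str, tuple[str, ...]] = {
    "sIMU1": ("torso",),
    "sIMU2": ("torso", "pelvis"),
    "sIMU3L": ("torso", "shank_L", "shank_R"),
    "sIMU3U": ("torso", "upper_arm_L", "upper_arm_R"),
    "sIMU4": ("torso", "pelvis", "thigh_L", "thigh_R"),
    "sIMU4D": ("forearm_L", "forearm_R", "shank_L", "shank_R"),
    "sIMU4P": ("upper_arm_L", "upper_arm_R", "thigh_L", "thigh_R"),
    "sIMU5": ("torso", "forearm_L", "forearm_R", "shank_L", "shank_R"),
    "sIMU13": tuple(SEGMENT_ORDER),
}

CHANNELS_PER_SEGMENT = 5
_CHANNEL_SUFFIXES = ("euler_x", "euler_y", "euler_z", "gyro_norm", "accel_norm")


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter parameters for the norm channels."""

    cutoff_hz: float = 15.0
    order: int = 2
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass
class SimulatedIMUSeries:
    """Per-segment 5-channel feature streams with per-frame labels."""

    data: np.ndarray                  # (frames, 5 * n_segments)
    channel_names: list[str]
    segments: tuple[str, ...]
    frame_labels: np.ndarray
    fs: float
    gimbal_flags: np.ndarray | None = field(default=None)   # (frames, n_segments) bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[1] != CHANNELS_PER_SEGMENT * len(self.segments):
            raise ValueError("channel count must be 5 x number of segments")
        if len(self.frame_labels) != self.data.shape[0]:
            raise ValueError("frame_labels length mismatch")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel_matrix(self) -> np.ndarray:
        return self.data


def fit_segment_pose(observed: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (Kabsch) mapping reference -> observed.

    Returns ``(R, t)`` minimizing ``sum ||R @ ref_i + t - obs_i||^2`` with
    ``det(R) = +1``.

    Raises
    ------
    ValueError
        If fewer than 3 markers are given or the reference cloud is
        (near-)collinear, which leaves the rotation underdetermined.
    """
    obs = np.asarray(observed, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if obs.shape != ref.shape or obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("observed and reference must both be (n, 3)")
    if obs.shape[0] < 3:
        raise ValueError("at least 3 markers are required for a pose fit")
    R, t = _kabsch_batch(obs[None], ref[None], check_degenerate=True)
    return R[0], t[0]


def _kabsch_batch(obs: np.ndarray, ref: np.ndarray, check_degenerate: bool = False
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Kabsch over a stack of (F, n, 3) point clouds."""
    obs_c = obs.mean(axis=1)
    ref_c = ref.mean(axis=1)
    A = obs - obs_c[:, None, :]
    B = ref - ref_c[:, None, :]
    H = np.einsum("fni,fnj->fij", B, A)           # ref x obs covariance
    U, S, Vt = np.linalg.svd(H)
    if check_degenerate:
        # Collinear reference: second singular value of the centered cloud
        # covariance vanishes.
        scale = S[:, 0]
        if np.any(S[:, 1] <= 1e-10 * np.maximum(scale, 1e-30)) or np.any(scale <= 0):
            raise ValueError("degenerate (collinear) reference marker cloud")
    V = np.swapaxes(Vt, 1, 2)
    det = np.linalg.det(V @ np.swapaxes(U, 1, 2))
    D = np.zeros_like(H)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = det
    R = V @ D @ np.swapaxes(U, 1, 2)
    t = obs_c - np.einsum("fij,fj->fi", R, ref_c)
    return R, t


def fit_segment_pose_series(observed: np.ndarray, reference: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame rigid fits for an (F, n, 3) observed marker series."""
    obs = np.asarray(observed, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if obs.ndim != 3 or obs.shape[2] != 3:
        raise ValueError("observed must be (frames, n, 3)")
    if obs.shape[1] < 3:
        raise ValueError("at least 3 markers are required for a pose fit")
    ref_b = np.broadcast_to(ref, obs.shape)
    # Degeneracy of the reference cloud is frame-independent; check once.
    fit_segment_pose(ref, ref)
    return _kabsch_batch(obs, ref_b)


def rotation_to_euler(R: np.ndarray, sequence: str = "xyz"
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Decompose rotation matrices into extrinsic Cardan angles.

    Only the default extrinsic ``"xyz"`` sequence is implemented:
    ``R = Rz(c) @ Ry(b) @ Rx(a)`` with ``b`` in [-pi/2, pi/2].  Returns
    ``(angles, gimbal)`` where ``angles`` has shape (..., 3) and ``gimbal``
    flags frames within ~1e-7 of the |b| = pi/2 singularity; at those
    frames the convention sets the third angle ``c`` to zero and folds the
    remaining freedom into ``a``.
    """
    if sequence != "xyz":
        raise NotImplementedError("only the extrinsic 'xyz' sequence is supported")
    R = np.asarray(R, dtype=float)
    sy = -R[..., 2, 0]
    sy_cl = np.clip(sy, -1.0, 1.0)
    b = np.arcsin(sy_cl)
    gimbal = np.abs(np.abs(sy_cl) - 1.0) < 1e-7
    a = np.arctan2(R[..., 2, 1], R[..., 2, 2])
    c = np.arctan2(R[..., 1, 0], R[..., 0, 0])
    if np.any(gimbal):
        # cos(b) ~ 0: only a -+ c is determined; put it all in a, zero c.
        a_lock = np.arctan2(-R[..., 1, 2], R[..., 1, 1])
        a = np.where(gimbal, a_lock, a)
        c = np.where(gimbal, 0.0, c)
    return np.stack([a, b, c], axis=-1), gimbal


def euler_to_rotation(angles: np.ndarray) -> np.ndarray:
    """Recompose extrinsic-xyz Cardan angles into rotation matrices."""
    from scipy.spatial.transform import Rotation

    angles = np.asarray(angles, dtype=float)
    return Rotation.from_euler("xyz", angles.reshape(-1, 3)).as_matrix().reshape(
        angles.shape[:-1] + (3, 3))


def angular_velocity_series(rotations: np.ndarray, fs: float) -> np.ndarray:
    """Global-frame angular velocity from a rotation series.

    Central differences of R give ``Rdot``; the angular velocity is the
    axial vector of the skew-symmetric part of ``Rdot @ R.T``.  Endpoints
    use one-sided differences.
    """
    R = np.asarray(rotations, dtype=float)
    if R.ndim != 3 or R.shape[1:] != (3, 3):
        raise ValueError("rotations must be (frames, 3, 3)")
    n = R.shape[0]
    if n < 3:
        raise ValueError("at least 3 frames are required")
    Rdot = np.empty_like(R)
    Rdot[1:-1] = (R[2:] - R[:-2]) * (fs / 2.0)
    Rdot[0] = (R[1] - R[0]) * fs
    Rdot[-1] = (R[-1] - R[-2]) * fs
    S = Rdot @ np.swapaxes(R, 1, 2)
    omega = np.empty((n, 3))
    omega[:, 0] = (S[:, 2, 1] - S[:, 1, 2]) / 2.0
    omega[:, 1] = (S[:, 0, 2] - S[:, 2, 0]) / 2.0
    omega[:, 2] = (S[:, 1, 0] - S[:, 0, 1]) / 2.0
    return omega


def com_acceleration_series(com: np.ndarray, fs: float) -> np.ndarray:
    """Linear acceleration of a COM path by second central differences.

    Interior frames use ``(x[i+1] - 2 x[i] + x[i-1]) * fs^2``; the endpoint
    values are mirrored from their interior neighbors.
    """
    x = np.asarray(com, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("com must be (frames, 3)")
    n = x.shape[0]
    if n < 3:
        raise ValueError("at least 3 frames are required")
    a = np.empty_like(x)
    a[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) * fs**2
    a[0] = a[1]
    a[-1] = a[-2]
    return a


def zero_lag_butterworth(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Forward-backward Butterworth low-pass along the first axis.

    The two passes square the magnitude response (amplitude at the cutoff
    is 0.5 instead of the single-pass 1/sqrt(2)) and cancel the phase, so
    the output has zero lag.  Edges are handled by odd-reflection padding
    of length ``3 * (order + 1)`` samples (the scipy ``filtfilt`` default);
    series must exceed that length.
    """
    if spec.cutoff_hz >= fs / 2.0:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz must be below Nyquist ({fs / 2} Hz)")
    b, a = butter(spec.order, spec.cutoff_hz, btype="low", fs=fs)
    if not spec.zero_lag:
        from scipy.signal import lfilter
        return lfilter(b, a, x, axis=0)
    return filtfilt(b, a, x, axis=0)


def extract_simu_channels(
    trial: MarkerTrial,
    model: BodyModel,
    spec: FilterSpec = FilterSpec(),
    segments: tuple[str, ...] | None = None,
) -> SimulatedIMUSeries:
    """Derive the 5-channels-per-segment simulated-IMU series for one trial.

    Euler angles are reported unfiltered; angular velocity and COM
    acceleration are low-pass filtered component-wise per ``spec`` before
    their Euclidean norms are taken.  Channels are computed
    per trial (never across concatenation seams) and frame labels are
    carried through unchanged.
    """
    if segments is None:
        segments = tuple(SEGMENT_ORDER)
    name_to_col = {m: i for i, m in enumerate(trial.marker_names)}
    n_frames = trial.n_frames
    data = np.empty((n_frames, CHANNELS_PER_SEGMENT * len(segments)))
    names: list[str] = []
    flags = np.zeros((n_frames, len(segments)), dtype=bool)

    for s, seg_id in enumerate(segments):
        seg = model.segments[seg_id]
        try:
            cols = [name_to_col[m] for m in seg.marker_names]
        except KeyError as exc:
            raise ValueError(
                f"marker {exc.args[0]!r} of segment {seg_id!r} missing from trial"
            ) from None
        obs = trial.coords[:, cols, :]
        R, _ = fit_segment_pose_series(obs, seg.marker_local)
        euler, gimbal = rotation_to_euler(R)
        omega = angular_velocity_series(R, trial.fs)
        com = obs.mean(axis=1)
        acc = com_acceleration_series(com, trial.fs)
        # Filter the vector components, then take norms: keeps the channels
        # nonnegative (filtering a norm directly undershoots at transients)
        # and leaves them invariant to fixed global rotations.
        gyro_norm = np.linalg.norm(
            zero_lag_butterworth(omega, spec, trial.fs), axis=1)
        accel_norm = np.linalg.norm(
            zero_lag_butterworth(acc, spec, trial.fs), axis=1)

        base = CHANNELS_PER_SEGMENT * s
        data[:, base:base + 3] = euler
        data[:, base + 3] = gyro_norm
        data[:, base + 4] = accel_norm
        flags[:, s] = gimbal
        names.extend(f"{seg_id}:{suf}" for suf in _CHANNEL_SUFFIXES)

    return SimulatedIMUSeries(
        data=data, channel_names=names, segments=tuple(segments),
        frame_labels=trial.frame_labels.copy(), fs=trial.fs, gimbal_flags=flags,
    )


def select_sensor_config(series: SimulatedIMUSeries, config_name: str) -> SimulatedIMUSeries:
    """Restrict a full simulated-IMU series to one sensor-set code."""
    if config_name not in SENSOR_CONFIGS:
        raise ValueError(
            f"unknown sensor config {config_name!r}; valid: {sorted(SENSOR_CONFIGS)}")
    wanted = SENSOR_CONFIGS[config_name]
    missing = [s for s in wanted if s not in series.segments]
    if missing:
        raise ValueError(f"series lacks segments {missing} needed by {config_name}")
    cols: list[int] = []
    names: list[str] = []
    flag_cols: list[int] = []
    for seg_id in wanted:
        s = series.segments.index(seg_id)
        base = CHANNELS_PER_SEGMENT * s
        cols.extend(range(base, base + CHANNELS_PER_SEGMENT))
        names.extend(series.channel_names[base:base + CHANNELS_PER_SEGMENT])
        flag_cols.append(s)
    return SimulatedIMUSeries(
        data=series.data[:, cols].copy(),
        channel_names=names,
        segments=wanted,
        frame_labels=series.frame_labels.copy(),
        fs=series.fs,
        gimbal_flags=None if series.gimbal_flags is None
        else series.gimbal_flags[:, flag_cols].copy(),
    )
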