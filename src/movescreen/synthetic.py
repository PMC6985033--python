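"""Synthetic labeled motion-capture cohorts.

Generates multi-athlete marker-trajectory datasets with the structure the
downstream analysis assumes: a 13-segment / 45-marker articulated body,
trials sampled at 120 Hz, movements that come in left/right mirror pairs
plus bilateral tasks, null (quiet standing) lead-in/lead-out periods, and
athlete-to-athlete amplitude/timing variability with optical marker noise.

Movement templates are smooth by construction: every joint-angle and
root-translation profile is a sum of Gaussian pulses of phase, so positions
are infinitely differentiable and angular velocities / accelerations are
well defined.  A template is mirrored by swapping left/right joints,
negating rotations about the anterior (Y) and vertical (Z) axes, keeping
rotations about the lateral (X) axis, and negating lateral root translation
— the exact sagittal-plane reflection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .body import SEGMENT_ORDER, BodyModel, build_default_segment_model

__all__ = [
    "Pulse",
    "MovementTemplate",
    "MarkerTrial",
    "AthleteParams",
    "NULL_LABEL",
    "SCREEN_TASK_CODES",
    "MIRROR_CODE",
    "default_templates",
    "mirror_template",
    "synthesize_trial",
    "assemble_cohort",
]

NULL_LABEL = "Null"

#: The 13 standard movement-screen task codes.
SCREEN_TASK_CODES = (
    "HDR", "HDL", "BDR", "BDL", "DJ", "TBR", "TBL",
    "SDR", "SDL", "LHR", "LHL", "LR", "LL",
)

#: Left/right partner for every sided code (synthetic codes may be added).
MIRROR_CODE = {
    "HDR": "HDL", "HDL": "HDR",
    "BDR": "BDL", "BDL": "BDR",
    "TBR": "TBL", "TBL": "TBR",
    "SDR": "SDL", "SDL": "SDR",
    "LHR": "LHL", "LHL": "LHR",
    "LR": "LL", "LL": "LR",
}


@dataclass(frozen=True)
class Pulse:
    """One Gaussian pulse contributing ``A * exp(-((p-c)/w)^2 / 2)`` to a
    profile, where ``p`` is movement phase in [0, 1].

    ``axis`` selects the rotation axis (0=X lateral, 1=Y anterior, 2=Z up)
    for joint profiles, or the translation axis for root profiles.
    """

    axis: int
    amplitude: float
    center: float
    width: float

    def __call__(self, phase: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((phase - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class MovementTemplate:
    """A parametric movement: per-joint angle profiles and root translation.

    ``joint_profiles`` maps a segment id to the pulses driving the rotation
    at that segment's proximal joint (the pelvis entry drives the root
    orientation).  ``side`` is ``"left"``/``"right"`` for mirror-pair tasks
    and ``"bilateral"`` for symmetric ones.
    """

    label: str
    duration_s: float
    side: str
    joint_profiles: dict[str, tuple[Pulse, ...]] = field(default_factory=dict)
    root_translation: tuple[Pulse, ...] = ()

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "bilateral"):
            raise ValueError(f"invalid side {self.side!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


def _mirror_pulses(pulses: tuple[Pulse, ...], rotational: bool) -> tuple[Pulse, ...]:
    # Reflection about the sagittal (Y-Z) plane: rotations about in-plane
    # axes (Y, Z) flip sign, rotation about the plane normal (X) is kept;
    # translations flip only the lateral X component.
    out = []
    for p in pulses:
        if rotational:
            amp = p.amplitude if p.axis == 0 else -p.amplitude
        else:
            amp = -p.amplitude if p.axis == 0 else p.amplitude
        out.append(replace(p, amplitude=amp))
    return tuple(out)


def _mirror_joint_name(joint: str) -> str:
    if joint.endswith("_L"):
        return joint[:-2] + "_R"
    if joint.endswith("_R"):
        return joint[:-2] + "_L"
    return joint


def mirror_template(t: MovementTemplate) -> MovementTemplate:
    """Return the sagittal-plane mirror of a sided movement template.

    Raises
    ------
    ValueError
        If the template is bilateral (no mirror partner is defined).
    """
    if t.side == "bilateral":
        raise ValueError(f"template {t.label!r} is bilateral; no mirror is defined")
    label = MIRROR_CODE.get(t.label)
    if label is None:
        # Synthetic codes: swap a trailing R/L.
        if t.label.endswith("R"):
            label = t.label[:-1] + "L"
        elif t.label.endswith("L"):
            label = t.label[:-1] + "R"
        else:
            raise ValueError(f"cannot derive mirrored label for {t.label!r}")
    profiles = {
        _mirror_joint_name(j): _mirror_pulses(p, rotational=True)
        for j, p in t.joint_profiles.items()
    }
    return MovementTemplate(
        label=label,
        duration_s=t.duration_s,
        side="left" if t.side == "right" else "right",
        joint_profiles=profiles,
        root_translation=_mirror_pulses(t.root_translation, rotational=False),
    )


@dataclass
class MarkerTrial:
    """One labeled trial: 45-marker trajectories for one movement of one athlete."""

    athlete_id: str
    coords: np.ndarray           # (frames, n_markers, 3), meters
    fs: float                    # Hz
    frame_labels: np.ndarray     # (frames,) of str codes incl. "Null"
    marker_names: tuple[str, ...]
    movement_label: str = NULL_LABEL

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.frame_labels = np.asarray(self.frame_labels)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (frames, markers, 3)")
        if len(self.frame_labels) != self.coords.shape[0]:
            raise ValueError("frame_labels length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def channel_matrix(self) -> np.ndarray:
        """Flattened (frames, 3*n_markers) coordinate channels (OPT input)."""
        return self.coords.reshape(self.n_frames, -1)

    def channel_names(self) -> list[str]:
        return [f"{m}:{ax}" for m in self.marker_names for ax in "xyz"]


@dataclass(frozen=True)
class AthleteParams:
    """Per-athlete variability factors applied to every trial."""

    amplitude_scale: float = 1.0
    time_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.amplitude_scale) and math.isfinite(self.time_scale)):
            raise ValueError("athlete jitter parameters must be finite")
        if self.amplitude_scale <= 0 or self.time_scale <= 0:
            raise ValueError("athlete jitter parameters must be positive")


def _forward_kinematics(model: BodyModel, joint_angles: dict[str, np.ndarray],
                        root_pos: np.ndarray) -> np.ndarray:
    """Pose the model for F frames.

    joint_angles maps segment id -> (F, 3) extrinsic-XYZ angles of the
    rotation at its proximal joint; missing segments stay unrotated.
    Returns (F, n_markers, 3) global marker positions.
    """
    n_frames = root_pos.shape[0]
    eye = np.broadcast_to(np.eye(3), (n_frames, 3, 3))
    rot: dict[str, np.ndarray] = {}
    org: dict[str, np.ndarray] = {}

    def joint_rot(seg_id: str) -> np.ndarray:
        ang = joint_angles.get(seg_id)
        if ang is None:
            return eye
        return Rotation.from_euler("xyz", ang).as_matrix()

    # topological traversal: parents before children
    order: list[str] = []
    pending = list(SEGMENT_ORDER)
    while pending:
        for seg_id in list(pending):
            parent = model.segments[seg_id].parent
            if parent is None or parent in order:
                order.append(seg_id)
                pending.remove(seg_id)

    for seg_id in order:
        seg = model.segments[seg_id]
        if seg.parent is None:
            rot[seg_id] = joint_rot(seg_id)
            org[seg_id] = root_pos + seg.joint_offset
        else:
            rp, ro = rot[seg.parent], org[seg.parent]
            rot[seg_id] = rp @ joint_rot(seg_id)
            org[seg_id] = ro + np.einsum("fij,j->fi", rp, seg.joint_offset)

    out = np.empty((n_frames, model.n_markers, 3))
    col = 0
    for seg_id in SEGMENT_ORDER:
        seg = model.segments[seg_id]
        k = len(seg.marker_names)
        out[:, col:col + k, :] = (org[seg_id][:, None, :]
                                  + np.einsum("fij,mj->fmi", rot[seg_id], seg.marker_local))
        col += k
    return out


def _evaluate_profiles(pulses: tuple[Pulse, ...], phase: np.ndarray) -> np.ndarray:
    """Sum pulses into an (F, 3) per-axis profile."""
    out = np.zeros((phase.shape[0], 3))
    for p in pulses:
        out[:, p.axis] += p(phase)
    return out


def synthesize_trial(
    template: MovementTemplate,
    athlete: AthleteParams = AthleteParams(),
    noise_sd: float = 0.0,
    fs: float = 120.0,
    seed: int = 0,
    null_lead_s: float = 0.5,
    null_trail_s: float = 0.5,
    sway_amplitude: float = 0.0,
    model: BodyModel | None = None,
    athlete_id: str = "athlete",
) -> MarkerTrial:
    """Forward-kinematics synthesis of one labeled marker trial.

    The movement phase occupies ``round(duration_s * time_scale * fs)``
    frames, padded by null (quiet standing) lead-in and lead-out.  Postural
    sway — a slow, seeded sinusoidal drift of the root — can be enabled with
    ``sway_amplitude`` (meters); isotropic Gaussian marker noise of standard
    deviation ``noise_sd`` (meters) is added last.  Identical arguments give
    bit-identical output.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if model is None:
        model = build_default_segment_model()
    rng = np.random.default_rng(seed)

    n_move = int(round(template.duration_s * athlete.time_scale * fs))
    n_lead = int(round(null_lead_s * fs))
    n_trail = int(round(null_trail_s * fs))
    n_frames = n_lead + n_move + n_trail

    # Movement phase: 0 during null, ramps 0->1 across the movement frames.
    phase = np.zeros(n_frames)
    if n_move > 0:
        phase[n_lead:n_lead + n_move] = (np.arange(n_move) + 0.5) / n_move
    active = np.zeros(n_frames, dtype=bool)
    active[n_lead:n_lead + n_move] = True

    joint_angles: dict[str, np.ndarray] = {}
    for joint, pulses in template.joint_profiles.items():
        ang = np.zeros((n_frames, 3))
        ang[active] = athlete.amplitude_scale * _evaluate_profiles(pulses, phase[active])
        joint_angles[joint] = ang

    root = np.zeros((n_frames, 3))
    if template.root_translation:
        root[active] = athlete.amplitude_scale * _evaluate_profiles(
            template.root_translation, phase[active])

    # Quiet-standing sway: slow sinusoids in the horizontal plane, seeded.
    if sway_amplitude > 0:
        t = np.arange(n_frames) / fs
        for ax in (0, 1):
            amp = sway_amplitude * rng.uniform(0.5, 1.0)
            f_hz = rng.uniform(0.2, 0.45)
            ph = rng.uniform(0, 2 * np.pi)
            root[:, ax] += amp * np.sin(2 * np.pi * f_hz * t + ph)

    coords = _forward_kinematics(model, joint_angles, root)
    if noise_sd > 0:
        coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)

    labels = np.full(n_frames, NULL_LABEL, dtype="U8")
    labels[active] = template.label
    return MarkerTrial(
        athlete_id=athlete_id,
        coords=coords,
        fs=fs,
        frame_labels=labels,
        marker_names=model.marker_names,
        movement_label=template.label,
    )


def _p(axis: int, amplitude: float, center: float, width: float) -> Pulse:
    return Pulse(axis, amplitude, center, width)


def default_templates() -> list[MovementTemplate]:
    """The default synthetic movement library: 3 mirror pairs + 2 bilateral.

    The tasks are stylized versions of screen movements: step-down (SDR/SDL),
    lunge (LR/LL) and T-balance (TBR/TBL) as sided pairs, plus a drop jump
    (DJ) and a bodyweight squat (SQ, synthetic code) as bilateral tasks.
    Torso and arm motion is deliberately purely sagittal and bilaterally
    symmetric for the sided tasks, so a torso-mounted (or arm-mounted)
    sensor alone carries no left/right information — the lateral content
    lives entirely in the legs, as in real single-leg screen tasks.
    """
    deg = np.pi / 180.0
    templates: list[MovementTemplate] = []

    # Step-down right: stand on the left leg, right hip/knee flex to lower.
    sdr = MovementTemplate(
        label="SDR", duration_s=2.0, side="right",
        joint_profiles={
            "thigh_R": (_p(0, -55 * deg, 0.5, 0.16),),
            "shank_R": (_p(0, 75 * deg, 0.5, 0.16),),
            "foot_R": (_p(0, -20 * deg, 0.5, 0.18),),
            "torso": (_p(0, -12 * deg, 0.5, 0.20),),
        },
        root_translation=(_p(2, -0.16, 0.5, 0.18),),
    )
    templates += [sdr, mirror_template(sdr)]

    # Lunge right: right hip/knee flexion with a forward + downward root
    # excursion and symmetric sagittal arm swing.
    lr = MovementTemplate(
        label="LR", duration_s=2.0, side="right",
        joint_profiles={
            "thigh_R": (_p(0, -70 * deg, 0.55, 0.14),),
            "shank_R": (_p(0, 95 * deg, 0.55, 0.14),),
            "thigh_L": (_p(0, 30 * deg, 0.55, 0.16),),
            "shank_L": (_p(0, 45 * deg, 0.55, 0.16),),
            "upper_arm_R": (_p(0, 35 * deg, 0.5, 0.2),),
            "upper_arm_L": (_p(0, 35 * deg, 0.5, 0.2),),
            "torso": (_p(0, -8 * deg, 0.55, 0.2),),
        },
        root_translation=(_p(1, 0.35, 0.55, 0.16), _p(2, -0.22, 0.55, 0.14)),
    )
    templates += [lr, mirror_template(lr)]

    # T-balance right: stand on the right leg, left leg extends backward as
    # the torso pitches toward horizontal; arms abducted symmetrically.
    tbr = MovementTemplate(
        label="TBR", duration_s=2.4, side="right",
        joint_profiles={
            "thigh_L": (_p(0, 80 * deg, 0.5, 0.18),),
            "torso": (_p(0, -65 * deg, 0.5, 0.18),),
            "upper_arm_R": (_p(0, 20 * deg, 0.5, 0.2),),
            "upper_arm_L": (_p(0, 20 * deg, 0.5, 0.2),),
            "shank_R": (_p(0, 12 * deg, 0.5, 0.2),),
        },
        root_translation=(_p(2, -0.06, 0.5, 0.2), _p(1, 0.05, 0.5, 0.2)),
    )
    templates += [tbr, mirror_template(tbr)]

    # Drop jump: fast bilateral countermovement with a flight-phase rise.
    dj = MovementTemplate(
        label="DJ", duration_s=1.6, side="bilateral",
        joint_profiles={
            "thigh_R": (_p(0, -60 * deg, 0.3, 0.10), _p(0, -50 * deg, 0.8, 0.09)),
            "thigh_L": (_p(0, -60 * deg, 0.3, 0.10), _p(0, -50 * deg, 0.8, 0.09)),
            "shank_R": (_p(0, 80 * deg, 0.3, 0.10), _p(0, 65 * deg, 0.8, 0.09)),
            "shank_L": (_p(0, 80 * deg, 0.3, 0.10), _p(0, 65 * deg, 0.8, 0.09)),
            "upper_arm_R": (_p(0, -50 * deg, 0.45, 0.12),),
            "upper_arm_L": (_p(0, -50 * deg, 0.45, 0.12),),
        },
        root_translation=(_p(2, -0.25, 0.3, 0.09), _p(2, 0.35, 0.55, 0.08),
                          _p(2, -0.20, 0.8, 0.08)),
    )
    templates.append(dj)

    # Squat: slow symmetric descent, arms raised forward for balance.
    sq = MovementTemplate(
        label="SQ", duration_s=2.8, side="bilateral",
        joint_profiles={
            "thigh_R": (_p(0, -85 * deg, 0.5, 0.2),),
            "thigh_L": (_p(0, -85 * deg, 0.5, 0.2),),
            "shank_R": (_p(0, 95 * deg, 0.5, 0.2),),
            "shank_L": (_p(0, 95 * deg, 0.5, 0.2),),
            "upper_arm_R": (_p(0, 80 * deg, 0.5, 0.22),),
            "upper_arm_L": (_p(0, 80 * deg, 0.5, 0.22),),
            "torso": (_p(0, -18 * deg, 0.5, 0.22),),
        },
        root_translation=(_p(2, -0.35, 0.5, 0.2),),
    )
    templates.append(sq)
    return templates


def assemble_cohort(
    n_athletes: int,
    templates: list[MovementTemplate] | None = None,
    seed: int = 0,
    noise_sd: float = 0.002,
    amplitude_jitter_sd: float = 0.10,
    time_jitter_sd: float = 0.08,
    sway_amplitude: float = 0.004,
    fs: float = 120.0,
    null_lead_s: float = 0.5,
    null_trail_s: float = 0.5,
    model: BodyModel | None = None,
) -> dict[str, list[MarkerTrial]]:
    """Generate a cohort: one trial per template per athlete.

    Each athlete draws amplitude and timing scale factors from seeded
    log-normal-like distributions (1 + N(0, sd), clipped to [0.7, 1.3]) and
    performs every template once.  Marker noise defaults to 2 mm, a typical
    optical residual; sway to 4 mm quiet standing.  Deterministic in
    ``seed``.
    """
    if n_athletes < 1:
        raise ValueError("n_athletes must be >= 1")
    if templates is None:
        templates = default_templates()
    if not templates:
        raise ValueError("templates must be non-empty")
    if model is None:
        model = build_default_segment_model()

    master = np.random.default_rng(seed)
    cohort: dict[str, list[MarkerTrial]] = {}
    for i in range(n_athletes):
        athlete_id = f"ath{i:03d}"
        amp = float(np.clip(1.0 + master.normal(0.0, amplitude_jitter_sd), 0.7, 1.3))
        tsc = float(np.clip(1.0 + master.normal(0.0, time_jitter_sd), 0.7, 1.3))
        params = AthleteParams(amplitude_scale=amp, time_scale=tsc)
        trials = []
        for template in templates:
            trial_seed = int(master.integers(0, 2**31 - 1))
            trials.append(synthesize_trial(
                template, params, noise_sd=noise_sd, fs=fs, seed=trial_seed,
                null_lead_s=null_lead_s, null_trail_s=null_trail_s,
                sway_amplitude=sway_amplitude, model=model, athlete_id=athlete_id,
            ))
        cohort[athlete_id] = trials
    return cohort
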