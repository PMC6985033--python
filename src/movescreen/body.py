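"""Articulated 13-segment body model carrying 45 labeled markers.

Coordinate convention (global and all neutral-pose segment frames):
``X`` lateral (pointing to the subject's left), ``Y`` anterior, ``Z`` up.
Mirror-image movements are reflections about the sagittal Y-Z plane
(``x -> -x``).

The model is a kinematic tree rooted at the pelvis.  Each segment stores the
position of its proximal joint in the parent frame and a small cluster of
marker positions in its own frame.  Marker clusters are rigid, contain at
least three non-collinear markers, and are laterally symmetric: markers on
midline segments (head, torso, pelvis) either lie in the sagittal plane
("_S" names) or come in left/right pairs, while paired limb segments carry
mirror-image clusters with "_L"/"_R" names.  This symmetry is what makes the
exact mirror-pair property of synthesized trials hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentModel",
    "BodyModel",
    "SEGMENT_ORDER",
    "build_default_segment_model",
    "mirror_marker_name",
]

#: Fixed segment ordering used for channel layout everywhere downstream.
SEGMENT_ORDER: tuple[str, ...] = (
    "head",
    "torso",
    "pelvis",
    "upper_arm_L",
    "upper_arm_R",
    "forearm_L",
    "forearm_R",
    "thigh_L",
    "thigh_R",
    "shank_L",
    "shank_R",
    "foot_L",
    "foot_R",
)


@dataclass(frozen=True)
class SegmentModel:
    """One rigid segment of the kinematic tree.

    Parameters
    ----------
    segment_id : str
        One of :data:`SEGMENT_ORDER`.
    parent : str or None
        Parent segment id; ``None`` for the pelvis root.
    joint_offset : (3,) ndarray
        Position of this segment's proximal joint expressed in the parent
        segment frame (meters).  For the root it is the neutral global
        position of the pelvis origin.
    marker_names : tuple of str
        Names of the markers rigidly attached to this segment.
    marker_local : (n, 3) ndarray
        Marker positions in the segment frame (meters).
    """

    segment_id: str
    parent: str | None
    joint_offset: np.ndarray
    marker_names: tuple[str, ...]
    marker_local: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "joint_offset", np.asarray(self.joint_offset, dtype=float))
        object.__setattr__(self, "marker_local", np.asarray(self.marker_local, dtype=float))
        if self.marker_local.shape != (len(self.marker_names), 3):
            raise ValueError(
                f"segment {self.segment_id}: marker_local shape "
                f"{self.marker_local.shape} does not match {len(self.marker_names)} names"
            )


@dataclass(frozen=True)
class BodyModel:
    """The full 13-segment, 45-marker model with a fixed marker ordering."""

    segments: dict[str, SegmentModel]
    marker_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        names: list[str] = []
        for seg_id in SEGMENT_ORDER:
            names.extend(self.segments[seg_id].marker_names)
        object.__setattr__(self, "marker_names", tuple(names))

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def marker_indices(self, segment_id: str) -> np.ndarray:
        """Column indices of a segment's markers in the trial coordinate array."""
        idx = [self.marker_names.index(m) for m in self.segments[segment_id].marker_names]
        return np.asarray(idx, dtype=int)


def mirror_marker_name(name: str) -> str:
    """Swap the lateral side token of a marker name ("_L_"/"_R_" or trailing)."""
    parts = name.split("_")
    swapped = ["L" if p == "R" else "R" if p == "L" else p for p in parts]
    return "_".join(swapped)


def _mirror_cluster(names: tuple[str, ...], local: np.ndarray) -> tuple[tuple[str, ...], np.ndarray]:
    mirrored = local.copy()
    mirrored[:, 0] *= -1.0
    return tuple(mirror_marker_name(n) for n in names), mirrored


def build_default_segment_model() -> BodyModel:
    """Build the default neutral-pose body model.

    Returns a deterministic 13-segment tree with 45 markers.  Segment frames
    coincide with the global frame in the neutral standing pose; limb lengths
    are those of a ~1.75 m adult.  Left-side limb segments are exact mirror
    images of the right side.
    """
    segs: dict[str, SegmentModel] = {}

    def add(seg_id, parent, joint_offset, names, local):
        segs[seg_id] = SegmentModel(seg_id, parent, np.asarray(joint_offset, float),
                                    tuple(names), np.asarray(local, float))

    # Root: pelvis origin at the mid-hip point, 1.0 m above the floor.
    add("pelvis", None, [0.0, 0.0, 1.00],
        ("PELV_L", "PELV_R", "PELV_S1", "PELV_S2"),
        [[0.12, 0.08, 0.02],     # left ASIS
         [-0.12, 0.08, 0.02],    # right ASIS
         [0.0, -0.10, 0.04],     # sacrum
         [0.0, 0.09, -0.03]])    # pubic

    add("torso", "pelvis", [0.0, 0.0, 0.15],
        ("TORS_S1", "TORS_S2", "TORS_S3", "TORS_L", "TORS_R"),
        [[0.0, 0.09, 0.28],      # sternum
         [0.0, -0.08, 0.40],     # C7
         [0.0, -0.09, 0.15],     # mid-back
         [0.17, 0.0, 0.42],      # left acromion
         [-0.17, 0.0, 0.42]])    # right acromion

    add("head", "torso", [0.0, 0.0, 0.48],
        ("HEAD_S1", "HEAD_S2", "HEAD_L", "HEAD_R"),
        [[0.0, 0.10, 0.08],      # forehead
         [0.0, -0.02, 0.15],     # vertex
         [0.08, 0.02, 0.06],     # left temple
         [-0.08, 0.02, 0.06]])   # right temple

    # Right arm; left mirrored below.  Upper arm hangs down from the shoulder.
    ua_names = ("UARM_R_1", "UARM_R_2", "UARM_R_3")
    ua_local = np.array([[-0.04, 0.02, -0.10],
                         [-0.05, -0.02, -0.16],
                         [-0.02, 0.03, -0.22]])
    add("upper_arm_R", "torso", [-0.19, 0.0, 0.40], ua_names, ua_local)
    n, l = _mirror_cluster(ua_names, ua_local)
    add("upper_arm_L", "torso", [0.19, 0.0, 0.40], n, l)

    fa_names = ("FARM_R_1", "FARM_R_2", "FARM_R_3")
    fa_local = np.array([[-0.03, 0.02, -0.08],
                         [-0.04, -0.02, -0.15],
                         [-0.01, 0.03, -0.21]])
    add("forearm_R", "upper_arm_R", [0.0, 0.0, -0.30], fa_names, fa_local)
    n, l = _mirror_cluster(fa_names, fa_local)
    add("forearm_L", "upper_arm_L", [0.0, 0.0, -0.30], n, l)

    th_names = ("THIGH_R_1", "THIGH_R_2", "THIGH_R_3")
    th_local = np.array([[-0.06, 0.05, -0.15],
                         [-0.07, -0.02, -0.25],
                         [-0.03, 0.06, -0.33]])
    add("thigh_R", "pelvis", [-0.09, 0.0, 0.0], th_names, th_local)
    n, l = _mirror_cluster(th_names, th_local)
    add("thigh_L", "pelvis", [0.09, 0.0, 0.0], n, l)

    sh_names = ("SHANK_R_1", "SHANK_R_2", "SHANK_R_3")
    sh_local = np.array([[-0.05, 0.04, -0.12],
                         [-0.05, -0.03, -0.22],
                         [-0.02, 0.05, -0.32]])
    add("shank_R", "thigh_R", [0.0, 0.0, -0.42], sh_names, sh_local)
    n, l = _mirror_cluster(sh_names, sh_local)
    add("shank_L", "thigh_L", [0.0, 0.0, -0.42], n, l)

    ft_names = ("FOOT_R_1", "FOOT_R_2", "FOOT_R_3", "FOOT_R_4")
    ft_local = np.array([[-0.03, 0.05, -0.03],
                         [-0.04, 0.18, -0.05],
                         [-0.01, 0.16, -0.04],
                         [-0.03, -0.04, -0.04]])
    add("foot_R", "shank_R", [0.0, 0.0, -0.42], ft_names, ft_local)
    n, l = _mirror_cluster(ft_names, ft_local)
    add("foot_L", "shank_L", [0.0, 0.0, -0.42], n, l)

    model = BodyModel(segments=segs)
    assert len(model.segments) == 13
    assert model.n_markers == 45
    return model
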