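"""Skeleton data model and rigid-body geometry.

A :class:`SkeletonFrame` is one time-stamped sample of the 17 reduced
joints.  Frames arrive in a per-camera coordinate system and are
roto-translated into a single room-fixed absolute frame (right-handed,
Z vertical, origin in a room corner) before any feature is computed.

Frames whose tracking failed are *sentinel frames*: every coordinate is
exactly 999.0 and the ``tracked`` flag is false.  Sentinel frames are
absorbing — no geometric operation turns one back into a tracked frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CalibrationError
from .joints import DEFAULT_REDUCTION_MAP, N_JOINTS, SENTINEL, JointId, Kinect25

_ORTHO_TOL = 1e-9


def sentinel_joints() -> np.ndarray:
    return np.full((N_JOINTS, 3), SENTINEL, dtype=float)


@dataclass(frozen=True)
class SkeletonFrame:
    """One tracked (or sentinel) 17-joint skeleton sample.

    Parameters
    ----------
    timestamp : float
        Acquisition time in seconds.
    camera_id : int
        Source camera (1..4); 0 denotes a stream already in room coordinates.
    subject_id : str
        Subject identifier.
    tracked : bool
        False if skeletal tracking failed for this frame.
    joints : (17, 3) ndarray
        X, Y, Z in meters, ordered by :class:`~skelpose.joints.JointId`.
    frame : {"camera", "room"}
        Coordinate system the joints are expressed in.
    """

    timestamp: float
    camera_id: int
    subject_id: str
    tracked: bool
    joints: np.ndarray
    frame: str = "room"

    def __post_init__(self):
        joints = np.asarray(self.joints, dtype=float)
        if joints.shape != (N_JOINTS, 3):
            raise ValueError(f"joints must be ({N_JOINTS}, 3), got {joints.shape}")
        object.__setattr__(self, "joints", joints)
        if not self.tracked:
            if not np.all(joints == SENTINEL):
                raise ValueError("untracked frame must carry sentinel coordinates")
        else:
            if not np.all(np.isfinite(joints)) or np.any(np.abs(joints) >= 100.0):
                raise ValueError("tracked frame has non-finite or implausible coordinates")

    def joint(self, jid: JointId) -> np.ndarray:
        return self.joints[int(jid) - 1]

    def as_untracked(self) -> "SkeletonFrame":
        return replace(self, tracked=False, joints=sentinel_joints())


def untracked_frame(timestamp: float = 0.0, camera_id: int = 0,
                    subject_id: str = "", frame: str = "room") -> SkeletonFrame:
    """Build a sentinel frame (tracking failure)."""
    return SkeletonFrame(timestamp, camera_id, subject_id, False,
                         sentinel_joints(), frame)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid roto-translation: ``p_room = rotation @ p_camera + translation``."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise CalibrationError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise CalibrationError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_TOL):
            raise CalibrationError("rotation matrix is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


def reduce_skeleton(raw, *, timestamp: float = 0.0, camera_id: int = 0,
                    subject_id: str = "", frame: str = "camera",
                    mapping: dict[JointId, Kinect25] | None = None) -> SkeletonFrame:
    """Reduce a 25-joint device skeleton to the 17-joint model.

    Sixteen joints are copied through ``mapping`` (anatomically direct by
    default) and ``Hc`` is added as the arithmetic midpoint of the two hip
    joints.  Any missing/non-finite source joint marks the whole frame as
    untracked (all-sentinel), matching the all-or-nothing sentinel rule.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (25, 3):
        raise ValueError(f"raw skeleton must be (25, 3), got {raw.shape}")
    if mapping is None:
        mapping = DEFAULT_REDUCTION_MAP
    if not np.all(np.isfinite(raw)):
        return untracked_frame(timestamp, camera_id, subject_id, frame)
    joints = np.empty((N_JOINTS, 3), dtype=float)
    for jid, src in mapping.items():
        joints[int(jid) - 1] = raw[int(src)]
    joints[int(JointId.HC) - 1] = 0.5 * (raw[int(Kinect25.HIP_L)] + raw[int(Kinect25.HIP_R)])
    return SkeletonFrame(timestamp, camera_id, subject_id, True, joints, frame)


def to_room_frame(frame: SkeletonFrame, calib: RigidTransform) -> SkeletonFrame:
    """Roto-translate a camera-frame skeleton into the room-fixed frame.

    Sentinel frames pass through unchanged apart from the frame tag.
    """
    if not frame.tracked:
        return replace(frame, frame="room")
    return replace(frame, joints=calib.apply(frame.joints), frame="room")
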