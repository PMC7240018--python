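"""Joint naming and the 25-to-17 joint reduction map.

The pipeline works on a reduced skeleton of 17 named joints: 16 joints
kept from the tracking device's 25-joint output plus ``Hc``, the midpoint
of the two hip joints.  Left/right pairs occupy consecutive (odd, even)
indices so hemi-body symmetry is mechanical to express.
"""

from __future__ import annotations

from enum import IntEnum

SENTINEL = 999.0
"""Value assigned to every field of a frame whose tracking failed."""

N_JOINTS = 17


class JointId(IntEnum):
    """The 17 reduced-skeleton joints, indexed 1..17."""

    HEAD = 1
    C7 = 2          # shoulders segment's mid-point (cervical vertebra C7)
    ACROMION_L = 3
    ACROMION_R = 4
    ELBOW_L = 5
    ELBOW_R = 6
    WRIST_L = 7
    WRIST_R = 8
    ILIAC_L = 9
    ILIAC_R = 10
    KNEE_L = 11
    KNEE_R = 12
    MALLEOLUS_L = 13
    MALLEOLUS_R = 14
    FOOT_L = 15
    FOOT_R = 16
    HC = 17         # hips segment's mid-point


class Kinect25(IntEnum):
    """Source-device joint indices (the standard 25-joint skeletal map)."""

    SPINE_BASE = 0
    SPINE_MID = 1
    NECK = 2
    HEAD = 3
    SHOULDER_L = 4
    ELBOW_L = 5
    WRIST_L = 6
    HAND_L = 7
    SHOULDER_R = 8
    ELBOW_R = 9
    WRIST_R = 10
    HAND_R = 11
    HIP_L = 12
    KNEE_L = 13
    ANKLE_L = 14
    FOOT_L = 15
    HIP_R = 16
    KNEE_R = 17
    ANKLE_R = 18
    FOOT_R = 19
    SPINE_SHOULDER = 20
    HAND_TIP_L = 21
    THUMB_L = 22
    HAND_TIP_R = 23
    THUMB_R = 24


# Anatomically direct source mapping for the 16 copied joints.  Hands,
# thumbs, hand tips and the spine base/mid joints are dropped; C7 is taken
# as the device's shoulder-segment midpoint.  Hc is derived, not copied.
DEFAULT_REDUCTION_MAP: dict[JointId, Kinect25] = {
    JointId.HEAD: Kinect25.HEAD,
    JointId.C7: Kinect25.SPINE_SHOULDER,
    JointId.ACROMION_L: Kinect25.SHOULDER_L,
    JointId.ACROMION_R: Kinect25.SHOULDER_R,
    JointId.ELBOW_L: Kinect25.ELBOW_L,
    JointId.ELBOW_R: Kinect25.ELBOW_R,
    JointId.WRIST_L: Kinect25.WRIST_L,
    JointId.WRIST_R: Kinect25.WRIST_R,
    JointId.ILIAC_L: Kinect25.HIP_L,
    JointId.ILIAC_R: Kinect25.HIP_R,
    JointId.KNEE_L: Kinect25.KNEE_L,
    JointId.KNEE_R: Kinect25.KNEE_R,
    JointId.MALLEOLUS_L: Kinect25.ANKLE_L,
    JointId.MALLEOLUS_R: Kinect25.ANKLE_R,
    JointId.FOOT_L: Kinect25.FOOT_L,
    JointId.FOOT_R: Kinect25.FOOT_R,
}

JOINT_NAMES: tuple[str, ...] = tuple(j.name.lower() for j in JointId)
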