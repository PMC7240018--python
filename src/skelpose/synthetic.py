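"""Synthetic labeled skeleton streams for testing the whole pipeline.

Generates Kinect-like 17-joint skeletons in a room-fixed frame for the
four pose classes — standing (1), sitting (2), lying down (3) and
"dangerous sitting" (4, a seated person slumped forward or fallen
backward) — with anthropometric variation (heights 1.55-1.90 m),
per-class head/trunk pitch signatures, scripted sessions with
transition frames, tracking noise, whole-frame dropouts (sentinel
frames) and multi-camera viewpoints.

The generator emulates the *statistical structure* the classifier
relies on (class-specific angle/height signatures, class 2 vs class 4
confusability through overlapping head-pitch distributions in "hard"
mode), not biomechanically realistic motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError
from .features import (DEFAULT_SELECTION, TRANSITION, UNTRACKED,
                       build_dataset, features_from_frames, split_by_subject)
from .joints import N_JOINTS, JointId
from .skeleton import RigidTransform, SkeletonFrame, to_room_frame, untracked_frame

ROOM_SIZE = (4.0, 4.0)  # meters
HEIGHT_RANGE = (1.55, 1.90)

# Class shares of the final database (standing, sitting, lying,
# dangerous sitting), matching the recorded cohort's printed counts.
DEFAULT_CLASS_MIX = (0.241, 0.388, 0.144, 0.227)


@dataclass(frozen=True)
class Anthropometry:
    """Body proportions as fractions of standing height.

    The vertical-chain ratios (head segment + trunk + thigh + shank +
    ankle height) sum to the head-joint height ratio, ~0.95 of stature.
    """

    height: float
    head_z: float = 0.95       # head-joint height / stature, standing
    c7_z: float = 0.818
    hip_z: float = 0.53
    knee_z: float = 0.285
    ankle_z: float = 0.039
    shoulder_halfwidth: float = 0.129
    pelvis_halfwidth: float = 0.096
    upper_arm: float = 0.186
    forearm: float = 0.146
    foot_length: float = 0.152

    def __post_init__(self):
        if not 1.0 <= self.height <= 2.5:
            raise ValueError(f"implausible height {self.height} m")

    @property
    def trunk_len(self) -> float:
        return (self.c7_z - self.hip_z) * self.height

    @property
    def head_len(self) -> float:
        return (self.head_z - self.c7_z) * self.height

    @property
    def thigh_len(self) -> float:
        return (self.hip_z - self.knee_z) * self.height

    @property
    def shank_len(self) -> float:
        return (self.knee_z - self.ankle_z) * self.height


@dataclass(frozen=True)
class NoiseModel:
    """Tracking-noise parameters.

    ``occlusion_p`` is a per-joint occlusion probability; any occluded
    joint invalidates the whole frame (the sentinel rule is
    all-or-nothing), so together with ``dropout_p`` the frame-loss
    probability is ``1 − (1 − dropout_p)(1 − occlusion_p)^17``.
    """

    sigma: float = 0.01          # isotropic joint position noise, m
    occlusion_p: float = 0.0
    dropout_p: float = 0.0

    def __post_init__(self):
        if self.sigma < 0 or not (0 <= self.occlusion_p <= 1) or not (0 <= self.dropout_p <= 1):
            raise ValueError("invalid noise parameters")

    @property
    def frame_loss_p(self) -> float:
        return 1.0 - (1.0 - self.dropout_p) * (1.0 - self.occlusion_p) ** N_JOINTS


@dataclass(frozen=True)
class ScriptEntry:
    pose: int                    # class 1..4
    duration: float              # seconds
    location: tuple[float, float] = (2.0, 2.0)
    heading: float = 0.0         # degrees, about the vertical axis

    def __post_init__(self):
        if self.pose not in (1, 2, 3, 4):
            raise ValueError(f"unknown pose class {self.pose}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        x, y = self.location
        if not (0 <= x <= ROOM_SIZE[0] and 0 <= y <= ROOM_SIZE[1]):
            raise ValueError(f"location {self.location} outside the room")


@dataclass(frozen=True)
class SessionScript:
    entries: tuple[ScriptEntry, ...]
    transition_duration: float = 1.0

    def __post_init__(self):
        if not self.entries:
            raise ValueError("session script is empty")
        object.__setattr__(self, "entries", tuple(self.entries))


# Per-class sampling ranges (degrees) for trunk/head pitch and roll.
# "hard" narrows the class 2 / class 4 head-pitch gap (class 4 forward
# pitch down to 15 deg, class 2 jitter up to 20 deg) to reproduce the
# sitting vs dangerous-sitting confusability.
_JITTER = {
    "easy": {
        1: {"trunk_pitch": (-5, 5), "head_pitch": (-10, 10)},
        2: {"trunk_pitch": (-5, 5), "head_pitch": (-10, 10)},
        3: {"trunk_pitch": (82, 98), "head_pitch": (-10, 10)},
        4: {"fwd_head_pitch": (30, 60), "fwd_trunk_pitch": (5, 25),
            "bwd_trunk_pitch": (-45, -20), "bwd_head_extra": (-15, 0)},
    },
    "hard": {
        1: {"trunk_pitch": (-8, 8), "head_pitch": (-15, 15)},
        2: {"trunk_pitch": (-10, 10), "head_pitch": (-20, 20)},
        3: {"trunk_pitch": (80, 100), "head_pitch": (-15, 15)},
        4: {"fwd_head_pitch": (15, 60), "fwd_trunk_pitch": (0, 25),
            "bwd_trunk_pitch": (-45, -20), "bwd_head_extra": (-15, 0)},
    },
}
_ROLL_RANGE = (-8.0, 8.0)
_SEAT_Z = 0.30      # seat height / stature when seated
_LYING_Z = {"hc": 0.055, "c7": 0.07, "head": 0.08, "knee": 0.065, "ankle": 0.05}


def _direction(f, m, z, pitch_deg, roll_deg):
    """Unit segment direction with the given signed pitch and roll."""
    p, r = np.radians(pitch_deg), np.radians(roll_deg)
    v = np.sin(p) * f + np.cos(p) * (np.sin(r) * m + np.cos(r) * z)
    return v / np.linalg.norm(v)


def _template_joints(pose: int, anthro: Anthropometry, trunk_pitch, trunk_roll,
                     head_pitch, head_roll, location, heading) -> np.ndarray:
    """Deterministic 17-joint skeleton for one frame, room coordinates."""
    h = anthro.height
    phi = np.radians(heading)
    fwd = np.array([np.cos(phi), np.sin(phi), 0.0])
    left = np.array([-np.sin(phi), np.cos(phi), 0.0])
    z = np.array([0.0, 0.0, 1.0])
    m = -left  # heading axis as read back from acromion_R − acromion_L
    origin = np.array([location[0], location[1], 0.0])

    J = np.zeros((N_JOINTS, 3))

    def setj(jid, p):
        J[int(jid) - 1] = p

    if pose == 1:       # standing
        hc = origin + z * anthro.hip_z * h
        d_thigh, d_shank, d_foot = -z, -z, fwd
    elif pose in (2, 4):  # seated
        hc = origin + z * _SEAT_Z * h
        d_thigh, d_shank, d_foot = fwd, -z, fwd
    elif pose == 3:     # lying supine, head along +fwd
        hc = origin + z * _LYING_Z["hc"] * h
        d_thigh, d_shank, d_foot = -fwd, -fwd, -fwd
    else:
        raise ValueError(f"unknown pose class {pose}")

    v_trunk = _direction(fwd, m, z, trunk_pitch, trunk_roll)
    c7 = hc + anthro.trunk_len * v_trunk
    v_head = _direction(fwd, m, z, head_pitch, head_roll)
    head = c7 + anthro.head_len * v_head
    if pose == 3:
        # recumbent heights are set by the floor, not the standing chain
        hc[2] = _LYING_Z["hc"] * h
        c7 = hc + anthro.trunk_len * v_trunk
        c7[2] = _LYING_Z["c7"] * h
        head = c7 + anthro.head_len * v_head
        head[2] = _LYING_Z["head"] * h

    setj(JointId.HC, hc)
    setj(JointId.C7, c7)
    setj(JointId.HEAD, head)
    setj(JointId.ACROMION_L, c7 + left * anthro.shoulder_halfwidth * h)
    setj(JointId.ACROMION_R, c7 - left * anthro.shoulder_halfwidth * h)
    setj(JointId.ILIAC_L, hc + left * anthro.pelvis_halfwidth * h)
    setj(JointId.ILIAC_R, hc - left * anthro.pelvis_halfwidth * h)

    d_arm = -v_trunk  # arms hang antiparallel to the trunk
    for side, sign in (("L", 1.0), ("R", -1.0)):
        acr = J[int(getattr(JointId, f"ACROMION_{side}")) - 1]
        elbow = acr + anthro.upper_arm * h * d_arm
        wrist = elbow + anthro.forearm * h * d_arm
        setj(getattr(JointId, f"ELBOW_{side}"), elbow)
        setj(getattr(JointId, f"WRIST_{side}"), wrist)

        iliac = J[int(getattr(JointId, f"ILIAC_{side}")) - 1]
        knee = iliac + anthro.thigh_len * d_thigh
        ankle = knee + anthro.shank_len * d_shank
        if pose == 3:
            knee[2] = _LYING_Z["knee"] * h
            ankle[2] = _LYING_Z["ankle"] * h
        foot = ankle + anthro.foot_length * h * d_foot
        setj(getattr(JointId, f"KNEE_{side}"), knee)
        setj(getattr(JointId, f"MALLEOLUS_{side}"), ankle)
        setj(getattr(JointId, f"FOOT_{side}"), foot)
    return J


def sample_pose_angles(pose: int, rng: np.random.Generator,
                       hardness: str = "easy") -> dict[str, float]:
    """Draw the per-frame pitch/roll parameters for one pose class."""
    spec = _JITTER[hardness][pose]
    roll = lambda: rng.uniform(*_ROLL_RANGE)  # noqa: E731
    if pose == 4:
        if rng.random() < 0.5:   # slumped forward
            head_pitch = rng.uniform(*spec["fwd_head_pitch"])
            trunk_pitch = rng.uniform(*spec["fwd_trunk_pitch"])
        else:                    # fallen backward
            trunk_pitch = rng.uniform(*spec["bwd_trunk_pitch"])
            head_pitch = trunk_pitch + rng.uniform(*spec["bwd_head_extra"])
    elif pose == 3:
        # recumbent: the head segment follows the (horizontal) trunk
        trunk_pitch = rng.uniform(*spec["trunk_pitch"])
        head_pitch = trunk_pitch + rng.uniform(*spec["head_pitch"])
    else:
        trunk_pitch = rng.uniform(*spec["trunk_pitch"])
        head_pitch = rng.uniform(*spec["head_pitch"])
    return {"trunk_pitch": trunk_pitch, "trunk_roll": roll(),
            "head_pitch": head_pitch, "head_roll": roll()}


def make_pose_template(pose: int, anthro: Anthropometry, rng_seed=None,
                       hardness: str = "easy", location=(2.0, 2.0),
                       heading: float = 0.0) -> np.ndarray:
    """One sampled 17-joint skeleton (room coordinates) for a pose class."""
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    angles = sample_pose_angles(pose, rng, hardness)
    return _template_joints(pose, anthro, location=location, heading=heading,
                            **angles)


def generate_session(script: SessionScript, anthro: Anthropometry,
                     noise: NoiseModel = NoiseModel(), frame_rate: float = 10.0,
                     subject_id: str = "s01", camera_id: int = 0,
                     seed=None, hardness: str = "easy"):
    """Frames plus ground-truth labels for one scripted session.

    Within-pose jitter is sampled per frame; pose changes are bridged by
    linearly interpolated frames labeled ``TRANSITION`` (0); occlusion
    and dropout are applied last, turning frames into all-sentinel ones
    labeled ``UNTRACKED`` (−1).  Fully reproducible from ``seed``.

    Returns ``(frames, labels)``.
    """
    if not 0 < frame_rate <= 30:
        raise ValueError("frame_rate must be in (0, 30] Hz")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed

    segments = []  # (label, joints array (n, 17, 3))
    for entry in script.entries:
        n = int(round(entry.duration * frame_rate))
        joints = np.empty((n, N_JOINTS, 3))
        for i in range(n):
            angles = sample_pose_angles(entry.pose, rng, hardness)
            joints[i] = _template_joints(entry.pose, anthro,
                                         location=entry.location,
                                         heading=entry.heading, **angles)
        segments.append((entry.pose, joints))

    all_joints, labels = [], []
    n_trans = int(round(script.transition_duration * frame_rate))
    for k, (label, joints) in enumerate(segments):
        if k > 0 and n_trans > 0:
            a = segments[k - 1][1][-1]
            b = joints[0]
            w = (np.arange(1, n_trans + 1) / (n_trans + 1))[:, None, None]
            all_joints.append((1 - w) * a + w * b)
            labels.extend([TRANSITION] * n_trans)
        all_joints.append(joints)
        labels.extend([label] * len(joints))
    all_joints = np.concatenate(all_joints)
    labels = np.asarray(labels)

    all_joints = all_joints + rng.normal(0.0, noise.sigma, size=all_joints.shape)
    lost = rng.random(len(all_joints)) < noise.frame_loss_p

    frames = []
    dt = 1.0 / frame_rate
    for i, joints in enumerate(all_joints):
        t = i * dt
        if lost[i]:
            frames.append(untracked_frame(t, camera_id, subject_id))
            labels[i] = UNTRACKED
        else:
            frames.append(SkeletonFrame(t, camera_id, subject_id, True,
                                        joints, "room"))
    return frames, labels


def apply_camera_views(frames, calibrations: dict[int, RigidTransform]):
    """Re-express room-frame skeletons in each camera's own frame.

    ``calibrations`` maps camera_id to the camera→room transform; each
    returned stream holds the inverse-transformed joints, so
    :func:`~skelpose.skeleton.to_room_frame` recovers the originals.
    Sentinel frames pass through unchanged.
    """
    streams: dict[int, list[SkeletonFrame]] = {}
    for cam_id, calib in calibrations.items():
        if not isinstance(calib, RigidTransform):
            raise CalibrationError(f"camera {cam_id}: not a rigid transform")
        inv = calib.inverse()
        stream = []
        for f in frames:
            if not f.tracked:
                stream.append(SkeletonFrame(f.timestamp, cam_id, f.subject_id,
                                            False, f.joints, "camera"))
            else:
                stream.append(SkeletonFrame(f.timestamp, cam_id, f.subject_id,
                                            True, inv.apply(f.joints), "camera"))
        streams[cam_id] = stream
    return streams


def _allocate(total: int, mix) -> list[int]:
    """Largest-remainder allocation of `total` frames to the class mix."""
    raw = np.asarray(mix, dtype=float) * total / np.sum(mix)
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts.tolist()


@dataclass
class Benchmark:
    """Subject-split train/test matrices from the full feature pipeline."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    train_subjects: tuple
    test_subjects: tuple
    heights: dict = field(default_factory=dict)
    selection: tuple = DEFAULT_SELECTION


def generate_benchmark(n_subjects: int = 12, n_train: int = 10,
                       frames_per_subject: int = 500,
                       class_mix=DEFAULT_CLASS_MIX, hardness: str = "easy",
                       seed: int = 0, frame_rate: float = 10.0,
                       selection=DEFAULT_SELECTION) -> Benchmark:
    """Full synthetic study: sessions → features → subject-wise split.

    Twelve subjects by default, ten for training, with per-subject frame
    budgets allocated to the four classes by ``class_mix``.  "easy" uses
    well-separated pose templates and sigma = 0.01 m tracking noise;
    "hard" overlaps the class 2/4 head-pitch distributions and raises
    sigma to 0.05 m.
    """
    import warnings

    if n_train >= n_subjects:
        raise ValueError("need n_train < n_subjects")
    if frames_per_subject < 100:
        warnings.warn("fewer than 100 frames per subject: metrics will be "
                      "unstable", stacklevel=2)
    noise = NoiseModel(sigma=0.01 if hardness == "easy" else 0.05,
                       dropout_p=0.02)
    rng = np.random.default_rng(seed)

    feats, labels, subjects = [], [], []
    heights = {}
    for s in range(n_subjects):
        sid = f"s{s + 1:02d}"
        heights[sid] = float(rng.uniform(*HEIGHT_RANGE))
        anthro = Anthropometry(height=heights[sid])
        counts = _allocate(frames_per_subject, class_mix)
        entries = []
        for pose, count in zip((1, 2, 3, 4), counts):
            entries.append(ScriptEntry(
                pose=pose, duration=count / frame_rate,
                location=(float(rng.uniform(0.8, ROOM_SIZE[0] - 0.8)),
                          float(rng.uniform(0.8, ROOM_SIZE[1] - 0.8))),
                heading=float(rng.uniform(0.0, 360.0))))
        script = SessionScript(tuple(entries), transition_duration=1.0)
        frames, frame_labels = generate_session(
            script, anthro, noise, frame_rate, subject_id=sid,
            seed=rng, hardness=hardness)
        feats.append(features_from_frames(frames, {sid: heights[sid]}))
        labels.append(frame_labels)
        subjects.extend([sid] * len(frames))

    X, y, subj = build_dataset(np.concatenate(feats), np.concatenate(labels),
                               np.asarray(subjects), spec=selection)
    order = rng.permutation(sorted(heights))
    train_subjects = tuple(sorted(order[:n_train]))
    test_subjects = tuple(sorted(order[n_train:]))
    X_tr, y_tr, X_te, y_te = split_by_subject(X, y, subj, test_subjects)
    return Benchmark(X_tr, y_tr, X_te, y_te, train_subjects, test_subjects,
                     heights, tuple(selection))
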