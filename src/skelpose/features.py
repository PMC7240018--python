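"""Per-frame geometric descriptor: 37 features and the selected 10.

Each tracked frame is described by

* 17 vertical coordinates ``Z_j`` scaled by the subject's height
  (dimensionless),
* 16 relative (articular) angles between consecutive body segments,
  measured in the plane the two segments span and normalized by 180°
  (so each lies in [0, 1]),
* 4 absolute angles — pitch and roll of the trunk (``A_pitch``,
  ``A_roll``) and of the head (``B_pitch``, ``B_roll``) — signed,
  normalized by 180° (so each lies in (−1, 1]).

The field order is fixed: ``Z_1 .. Z_Hc``, then the 16 relative-angle
symbols, then the 4 absolute angles (see :data:`FEATURE_NAMES`).
Untracked frames map to an all-sentinel (999.0) vector.

The default 10-attribute subset kept after ReliefF ranking is
:data:`DEFAULT_SELECTION`.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter

import numpy as np

from .errors import ConfigurationError, DegenerateGeometryError
from .joints import N_JOINTS, SENTINEL, JointId
from .skeleton import SkeletonFrame

logger = logging.getLogger(__name__)

_EPS_SEGMENT = 1e-9     # minimum body-segment length, meters
_EPS_HORIZONTAL = 1e-6  # minimum horizontal heading-axis norm, meters

TRANSITION = 0
UNTRACKED = -1
POSE_CLASSES = (1, 2, 3, 4)

# Z-coordinate feature names follow the joint numbering, with the named
# C7 and Hc joints spelled out (they appear in the selected subset).
Z_NAMES: tuple[str, ...] = tuple(
    {JointId.HEAD: "Z_1", JointId.C7: "Z_C7", JointId.HC: "Z_Hc"}.get(j, f"Z_{int(j)}")
    for j in JointId
)

# (symbol, vertex, endpoint_a, endpoint_b) for the 16 relative angles.
# The enumeration order mirrors the anatomical listing head-to-foot;
# tau2 (right shoulder-axis/trunk) is omitted as redundant with tau1.
RELATIVE_ANGLE_SPECS: tuple[tuple[str, JointId, JointId, JointId], ...] = (
    ("mu1", JointId.C7, JointId.HEAD, JointId.ACROMION_L),
    ("mu2", JointId.C7, JointId.HEAD, JointId.ACROMION_R),
    ("xi", JointId.C7, JointId.HEAD, JointId.HC),
    ("tau1", JointId.C7, JointId.ACROMION_L, JointId.HC),
    ("eta1", JointId.ACROMION_L, JointId.C7, JointId.ELBOW_L),
    ("eta2", JointId.ACROMION_R, JointId.C7, JointId.ELBOW_R),
    ("theta1", JointId.ELBOW_L, JointId.ACROMION_L, JointId.WRIST_L),
    ("theta2", JointId.ELBOW_R, JointId.ACROMION_R, JointId.WRIST_R),
    ("delta1", JointId.HC, JointId.C7, JointId.ILIAC_L),
    ("delta2", JointId.HC, JointId.C7, JointId.ILIAC_R),
    ("gamma1", JointId.ILIAC_L, JointId.HC, JointId.KNEE_L),
    ("gamma2", JointId.ILIAC_R, JointId.HC, JointId.KNEE_R),
    ("beta1", JointId.KNEE_L, JointId.ILIAC_L, JointId.MALLEOLUS_L),
    ("beta2", JointId.KNEE_R, JointId.ILIAC_R, JointId.MALLEOLUS_R),
    ("alpha1", JointId.MALLEOLUS_L, JointId.KNEE_L, JointId.FOOT_L),
    ("alpha2", JointId.MALLEOLUS_R, JointId.KNEE_R, JointId.FOOT_R),
)

RELATIVE_ANGLE_NAMES: tuple[str, ...] = tuple(s[0] for s in RELATIVE_ANGLE_SPECS)
ABSOLUTE_ANGLE_NAMES: tuple[str, ...] = ("A_pitch", "A_roll", "B_pitch", "B_roll")

FEATURE_NAMES: tuple[str, ...] = Z_NAMES + RELATIVE_ANGLE_NAMES + ABSOLUTE_ANGLE_NAMES
N_FEATURES = len(FEATURE_NAMES)  # 37

DEFAULT_SELECTION: tuple[str, ...] = (
    "A_pitch", "A_roll", "B_pitch", "B_roll",
    "xi", "mu2", "delta2", "Z_1", "Z_C7", "Z_Hc",
)

_FEATURE_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}


def relative_angle(a, vertex, b) -> float:
    """Angle in degrees between segments ``a−vertex`` and ``b−vertex``.

    The angle lies in [0, 180] and is measured in the plane spanned by
    the two segments.  Raises :class:`DegenerateGeometryError` if either
    segment is shorter than 1e-9 m.
    """
    u = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(b, dtype=float) - np.asarray(vertex, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu <= _EPS_SEGMENT or nv <= _EPS_SEGMENT:
        raise DegenerateGeometryError("zero-length body segment; angle undefined")
    # atan2 of cross/dot is the arccos of the normalized dot product but
    # stays well-conditioned at 0 and 180 degrees
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)),
                                       np.dot(u, v))))


def compute_relative_angles(frame: SkeletonFrame) -> dict[str, float]:
    """The 16 articular angles (degrees), keyed by symbol.

    Raises :class:`DegenerateGeometryError` on any zero-length segment;
    callers map the whole frame to untracked in that case.
    """
    if not frame.tracked:
        raise ValueError("relative angles are undefined for untracked frames")
    out = {}
    for symbol, vertex, ja, jb in RELATIVE_ANGLE_SPECS:
        out[symbol] = relative_angle(frame.joint(ja), frame.joint(vertex), frame.joint(jb))
    return out


def _heading_frame(frame: SkeletonFrame) -> tuple[np.ndarray, np.ndarray]:
    """Body-heading reference: horizontal unit axis m and forward axis f.

    m is the horizontal projection of the shoulder axis (acromion_R −
    acromion_L); if that is nearly vertical the iliac-crest axis is used,
    then the room X axis as a last resort.  f = z × m points forward for
    a person whose left side is along +m.
    """
    z = np.array([0.0, 0.0, 1.0])
    candidates = (
        ("shoulder axis", frame.joint(JointId.ACROMION_R) - frame.joint(JointId.ACROMION_L)),
        ("iliac-crest axis", frame.joint(JointId.ILIAC_R) - frame.joint(JointId.ILIAC_L)),
        ("room X axis", np.array([1.0, 0.0, 0.0])),
    )
    for name, axis in candidates:
        horizontal = np.array([axis[0], axis[1], 0.0])
        norm = np.linalg.norm(horizontal)
        if norm >= _EPS_HORIZONTAL:
            if name != "shoulder axis":
                logger.info("heading fallback to %s (shoulder axis nearly vertical)", name)
            m = horizontal / norm
            return m, np.cross(z, m)
    raise DegenerateGeometryError("no usable horizontal heading axis")


def segment_pitch_roll(frame: SkeletonFrame, segment: str) -> tuple[float, float]:
    """Signed pitch and roll (degrees) of the trunk or head segment.

    The segment vector is C7−Hc for ``"trunk"`` and head−C7 for
    ``"head"``.  With z the room vertical, m the horizontal body-heading
    axis and f = z × m, pitch = atan2(v·f, v·z) and roll = atan2(v·m,
    v·z), each in (−180, 180].  Positive pitch is a forward lean.
    """
    if not frame.tracked:
        raise ValueError("pitch/roll undefined for untracked frames")
    if segment == "trunk":
        v = frame.joint(JointId.C7) - frame.joint(JointId.HC)
    elif segment == "head":
        v = frame.joint(JointId.HEAD) - frame.joint(JointId.C7)
    else:
        raise ConfigurationError(f"unknown segment {segment!r}")
    if np.linalg.norm(v) <= _EPS_SEGMENT:
        raise DegenerateGeometryError(f"zero-length {segment} segment")
    m, f = _heading_frame(frame)
    z = np.array([0.0, 0.0, 1.0])
    pitch = np.degrees(np.arctan2(np.dot(v, f), np.dot(v, z)))
    roll = np.degrees(np.arctan2(np.dot(v, m), np.dot(v, z)))
    # atan2 returns (−180, 180]; map −180 to +180 for the closed upper end
    pitch = 180.0 if pitch == -180.0 else pitch
    roll = 180.0 if roll == -180.0 else roll
    return float(pitch), float(roll)


def scale_vertical(frame: SkeletonFrame, height: float) -> np.ndarray:
    """The 17 joint Z coordinates divided by the subject's height (m).

    Untracked frames propagate the sentinel unchanged.
    """
    if height <= 0:
        raise ConfigurationError(f"subject height must be positive, got {height}")
    if not frame.tracked:
        return np.full(N_JOINTS, SENTINEL)
    return frame.joints[:, 2] / height


def assemble_features(frame: SkeletonFrame, height: float) -> np.ndarray:
    """The full 37-element descriptor for one frame, in canonical order.

    Relative angles are divided by 180° (→ [0, 1]); pitch/roll by 180°
    (→ (−1, 1]); Z coordinates by the subject height.  Untracked frames
    — and tracked frames with degenerate geometry — yield 37 × 999.0.
    """
    if height <= 0:
        raise ConfigurationError(f"subject height must be positive, got {height}")
    if not frame.tracked:
        return np.full(N_FEATURES, SENTINEL)
    try:
        rel = compute_relative_angles(frame)
        a_pitch, a_roll = segment_pitch_roll(frame, "trunk")
        b_pitch, b_roll = segment_pitch_roll(frame, "head")
    except DegenerateGeometryError as exc:
        logger.warning("frame at t=%.3f mapped to untracked: %s", frame.timestamp, exc)
        return np.full(N_FEATURES, SENTINEL)
    z = scale_vertical(frame, height)
    angles = np.array([rel[s] for s in RELATIVE_ANGLE_NAMES]) / 180.0
    absolute = np.array([a_pitch, a_roll, b_pitch, b_roll]) / 180.0
    return np.concatenate([z, angles, absolute])


def is_sentinel(values: np.ndarray) -> np.ndarray:
    """Boolean mask of sentinel rows (or a scalar for a 1-d vector)."""
    values = np.asarray(values)
    if values.ndim == 1:
        return np.all(values == SENTINEL)
    return np.all(values == SENTINEL, axis=1)


def select_features(values: np.ndarray, spec=DEFAULT_SELECTION) -> np.ndarray:
    """Copy the named fields of 37-feature vectors in spec order.

    Works on a single vector or an (n, 37) matrix.  Sentinel rows
    propagate sentinel values.
    """
    for name in spec:
        if name not in _FEATURE_INDEX:
            raise ConfigurationError(f"unknown feature field {name!r}")
    idx = [_FEATURE_INDEX[name] for name in spec]
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != N_FEATURES:
        raise ConfigurationError(
            f"expected {N_FEATURES}-field vectors, got width {values.shape[-1]}")
    return values[..., idx]


def build_dataset(features: np.ndarray, labels, subject_ids,
                  spec=DEFAULT_SELECTION):
    """Assemble the training matrix from per-frame features and labels.

    Transition (label 0) and untracked (label −1 or sentinel row) frames
    are removed; only pose classes 1–4 are retained.

    Returns ``(X, y, subjects)`` where X is (n, len(spec)).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    subject_ids = np.asarray(subject_ids)
    if not (len(features) == len(labels) == len(subject_ids)):
        raise ValueError("features, labels and subject_ids must align")
    valid = set(POSE_CLASSES) | {TRANSITION, UNTRACKED}
    bad = set(np.unique(labels)) - valid
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}")
    keep = np.isin(labels, POSE_CLASSES) & ~is_sentinel(features)
    n_removed = Counter()
    n_removed["transition"] = int(np.sum(labels == TRANSITION))
    n_removed["untracked"] = int(np.sum((labels == UNTRACKED) | is_sentinel(features)))
    logger.info("dataset filter: kept %d frames, removed %d transition, %d untracked",
                int(keep.sum()), n_removed["transition"], n_removed["untracked"])
    if not np.any(keep):
        warnings.warn("all frames were transition/untracked; dataset is empty",
                      stacklevel=2)
    X = select_features(features[keep], spec)
    return X, labels[keep], subject_ids[keep]


def split_by_subject(X, y, subjects, test_subjects):
    """Partition a dataset by whole subjects (never by frame).

    Returns ``(X_train, y_train, X_test, y_test)``.  Raises if a subject
    would land on both sides.
    """
    subjects = np.asarray(subjects)
    test_subjects = set(test_subjects)
    is_test = np.isin(subjects, sorted(test_subjects))
    train_ids = set(subjects[~is_test])
    overlap = train_ids & test_subjects
    if overlap:
        raise ValueError(f"subjects in both partitions: {sorted(overlap)}")
    return X[~is_test], y[~is_test], X[is_test], y[is_test]


def features_from_frames(frames, heights: dict[str, float]) -> np.ndarray:
    """Stack :func:`assemble_features` over a frame sequence.

    ``heights`` maps subject_id to height in meters.
    """
    rows = []
    for f in frames:
        try:
            h = heights[f.subject_id]
        except KeyError:
            raise ConfigurationError(f"no height for subject {f.subject_id!r}") from None
        rows.append(assemble_features(f, h))
    return np.asarray(rows, dtype=float)


def estimate_height(frames, quantile: float = 97.5) -> float:
    """Fallback height estimate: upper percentile of head Z over a window.

    Off by default — supplied metadata is preferred; this exists for
    streams recorded without per-subject height.
    """
    zs = [f.joint(JointId.HEAD)[2] for f in frames if f.tracked]
    if not zs:
        raise ValueError("no tracked frames to estimate height from")
    return float(np.percentile(zs, quantile))
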