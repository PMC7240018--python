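"""Plain-text file formats for frames, labels, features, models, reports.

All tabular artifacts are comma-separated text with a header row;
lines starting with ``#`` are metadata comments (config hash, seed) and
are ignored on read.  Coordinates round-trip within 1e-9 and the
999.0 sentinel survives exactly.

Frame file columns::

    timestamp,camera_id,subject_id,tracked,j01_x,j01_y,j01_z,...,j17_z

Calibration files are YAML: one entry per camera id with a row-major
3x3 ``rotation`` and a 3-vector ``translation`` (camera → room).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import yaml

from .errors import CalibrationError, FormatError
from .features import FEATURE_NAMES
from .joints import N_JOINTS
from .skeleton import RigidTransform, SkeletonFrame

_FLOAT_FMT = "%.12g"

FRAME_HEADER = ["timestamp", "camera_id", "subject_id", "tracked"] + [
    f"j{j:02d}_{axis}" for j in range(1, N_JOINTS + 1) for axis in "xyz"
]
LABEL_HEADER = ["timestamp", "camera_id", "subject_id", "label"]


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_frames(path, frames, metadata: dict | None = None) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        w = csv.writer(fh)
        w.writerow(FRAME_HEADER)
        for f in frames:
            row = [_fmt(f.timestamp), str(f.camera_id), f.subject_id,
                   "1" if f.tracked else "0"]
            row += [_fmt(v) for v in f.joints.ravel()]
            w.writerow(row)


def read_frames(path, frame: str = "room"):
    """Parse a frame file; malformed rows raise with their line number."""
    path = Path(path)
    frames = []
    with path.open() as fh:
        lineno = 0
        header = None
        for line in fh:
            lineno += 1
            if line.startswith("#") or not line.strip():
                continue
            row = next(csv.reader([line]))
            if header is None:
                header = row
                if header != FRAME_HEADER:
                    raise FormatError(
                        f"{path}:{lineno}: bad header (expected "
                        f"{len(FRAME_HEADER)} documented columns)")
                continue
            if len(row) != len(FRAME_HEADER):
                raise FormatError(f"{path}:{lineno}: expected "
                                  f"{len(FRAME_HEADER)} fields, got {len(row)}")
            try:
                t = float(row[0])
                cam = int(row[1])
                tracked = bool(int(row[3]))
                joints = np.array(row[4:], dtype=float).reshape(N_JOINTS, 3)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            frames.append(SkeletonFrame(t, cam, row[2], tracked, joints, frame))
        if header is None:
            raise FormatError(f"{path}: empty file")
    return frames


def write_labels(path, frames, labels, metadata: dict | None = None) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        w = csv.writer(fh)
        w.writerow(LABEL_HEADER)
        for f, lab in zip(frames, labels):
            w.writerow([_fmt(f.timestamp), str(f.camera_id), f.subject_id,
                        str(int(lab))])


def read_labels(path) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    if list(df.columns) != LABEL_HEADER:
        raise FormatError(f"{path}: bad label header")
    return df["label"].to_numpy(dtype=int)


def write_features(path, features, labels=None, subjects=None,
                   names=FEATURE_NAMES, metadata: dict | None = None) -> None:
    features = np.asarray(features, dtype=float)
    if features.shape[1] != len(names):
        raise FormatError(f"feature width {features.shape[1]} does not match "
                          f"{len(names)} names")
    path = Path(path)
    with path.open("w", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        w = csv.writer(fh)
        header = []
        if subjects is not None:
            header.append("subject_id")
        if labels is not None:
            header.append("label")
        w.writerow(header + list(names))
        for i, row in enumerate(features):
            lead = []
            if subjects is not None:
                lead.append(str(subjects[i]))
            if labels is not None:
                lead.append(str(int(labels[i])))
            w.writerow(lead + [_fmt(v) for v in row])


def read_features(path):
    """Returns ``(X, labels_or_None, subjects_or_None, names)``."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    subjects = df["subject_id"].to_numpy() if "subject_id" in cols else None
    labels = df["label"].to_numpy(dtype=int) if "label" in cols else None
    names = [c for c in cols if c not in ("subject_id", "label")]
    return df[names].to_numpy(dtype=float), labels, subjects, tuple(names)


def read_calibration(path) -> dict[int, RigidTransform]:
    """YAML calibration file → {camera_id: camera→room transform}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CalibrationError(f"{path}: expected a mapping of camera ids")
    out = {}
    for cam_id, entry in raw.items():
        try:
            R = np.asarray(entry["rotation"], dtype=float).reshape(3, 3)
            t = np.asarray(entry["translation"], dtype=float).reshape(3)
        except (KeyError, TypeError, ValueError) as exc:
            raise CalibrationError(f"{path}: camera {cam_id}: {exc}") from None
        out[int(cam_id)] = RigidTransform(R, t)
    return out


def write_calibration(path, calibrations: dict[int, RigidTransform]) -> None:
    data = {int(cid): {"rotation": c.rotation.tolist(),
                       "translation": c.translation.tolist()}
            for cid, c in calibrations.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def save_model(path, clf, metadata: dict | None = None) -> None:
    """Persist a fitted PoseMLPClassifier to JSON."""
    payload = {
        "format": "skelpose-mlp-v1",
        "params": clf.params_.tolist(),
        "hidden": list(clf.hidden),
        "classes": np.asarray(clf.classes_).tolist(),
        "n_features": int(clf.n_features_in_),
        "loss": clf.loss,
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model(path):
    from .mlp import PoseMLPClassifier, _Net

    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "skelpose-mlp-v1":
        raise FormatError(f"{path}: not a skelpose model file")
    clf = PoseMLPClassifier(hidden=tuple(payload["hidden"]), loss=payload["loss"])
    clf.classes_ = np.asarray(payload["classes"])
    clf.n_features_in_ = payload["n_features"]
    clf.params_ = np.asarray(payload["params"], dtype=float)
    clf._net = _Net(clf.n_features_in_, tuple(payload["hidden"]),
                    len(clf.classes_))
    return clf


def format_report(summary: dict, metadata: dict | None = None) -> str:
    """Deterministic plain-text rendering of a summarize() dict."""
    lines = []
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    lines.append(f"n_simulations: {summary['n_simulations']}")
    ta = summary["total_accuracy"]
    mca = summary["mean_class_accuracy"]
    lines.append(f"total_accuracy: {ta[0]:.6f} +/- {ta[1]:.6f}")
    lines.append(f"mean_class_accuracy: {mca[0]:.6f} +/- {mca[1]:.6f}")
    if "shapiro_total_accuracy" in summary:
        w, p = summary["shapiro_total_accuracy"]
        lines.append(f"shapiro_total_accuracy: W={w:.6f} p={p:.6f}")
    lines.append("")
    lines.append("per_class_metrics (mean +/- sd):")
    for c in summary["classes"]:
        parts = [f"class {c}:"]
        for m, (mean, sd) in summary["per_class"][c].items():
            parts.append(f"{m}={mean:.6f}+/-{sd:.6f}")
        lines.append("  " + " ".join(parts))
    if summary.get("auc"):
        lines.append("")
        lines.append("auc_of_mean_roc (x100):")
        for c, a in summary["auc"].items():
            lines.append(f"  class {c}: {100 * a:.1f}")
    lines.append("")
    lines.append("mean_confusion_matrix (rows=predicted, cols=actual):")
    for row in summary["mean_confusion"]:
        lines.append("  " + " ".join(f"{v:12.3f}" for v in row))
    return "\n".join(lines) + "\n"


def write_report(path, summary: dict, metadata: dict | None = None) -> None:
    Path(path).write_text(format_report(summary, metadata))
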