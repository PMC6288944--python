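"""Skeleton recording domain model and I/O.

A walk recording is an ordered sequence of time-stamped poses captured by a
depth camera facing the walking corridor. Each pose carries 25 named joints
with 3-D positions in meters (x lateral, y vertical, z depth from the camera,
right-handed) and a per-joint flag marking positions that the tracking
software *inferred* while the joint was occluded (low-confidence data).

The canonical on-disk dialects are a flat CSV (one row per frame, columns
``timestamp, <joint>_x, <joint>_y, <joint>_z, <joint>_inferred`` in the fixed
joint order below) and a JSON mirror of the same schema. Floats are written
with Python's shortest round-trip ``repr`` so read->write is byte-identical
on canonical files.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

# Fixed 25-joint schema of the skeleton tracker, in canonical column order.
JOINT_NAMES: tuple[str, ...] = (
    "spine_base",
    "spine_mid",
    "neck",
    "head",
    "shoulder_left",
    "elbow_left",
    "wrist_left",
    "hand_left",
    "shoulder_right",
    "elbow_right",
    "wrist_right",
    "hand_right",
    "hip_left",
    "knee_left",
    "ankle_left",
    "foot_left",
    "hip_right",
    "knee_right",
    "ankle_right",
    "foot_right",
    "spine_shoulder",
    "hand_tip_left",
    "thumb_left",
    "hand_tip_right",
    "thumb_right",
)

N_JOINTS = len(JOINT_NAMES)
JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINT_NAMES)}

#: left/right joint pairs, used by the mirrored-skeleton artifact and by
#: limb-symmetry cleaning.
LEFT_RIGHT_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (left, left.replace("_left", "_right"))
    for left in JOINT_NAMES
    if left.endswith("_left")
)

#: bone segments (proximal joint, distal joint) per limb type and side.
LIMB_SEGMENTS: dict[str, tuple[str, str]] = {
    "humerus.L": ("shoulder_left", "elbow_left"),
    "humerus.R": ("shoulder_right", "elbow_right"),
    "forearm.L": ("elbow_left", "wrist_left"),
    "forearm.R": ("elbow_right", "wrist_right"),
    "thigh.L": ("hip_left", "knee_left"),
    "thigh.R": ("hip_right", "knee_right"),
    "shin.L": ("knee_left", "ankle_left"),
    "shin.R": ("knee_right", "ankle_right"),
}

STAGE_LABELS = ("1", "2", "3", "control")


class SchemaError(ValueError):
    """Recording violates the 25-joint schema."""


class RecordingParseError(ValueError):
    """Malformed on-disk recording."""


@dataclass(frozen=True)
class Joint:
    name: str
    x: float
    y: float
    z: float
    inferred: bool = False

    def __post_init__(self) -> None:
        if self.name not in JOINT_INDEX:
            raise SchemaError(f"unknown joint name {self.name!r}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class SkeletonFrame:
    """One time-stamped pose; ``joints`` keyed by canonical joint name."""

    timestamp: float
    joints: dict[str, Joint]

    def __post_init__(self) -> None:
        missing = set(JOINT_NAMES) - set(self.joints)
        extra = set(self.joints) - set(JOINT_NAMES)
        if missing or extra:
            raise SchemaError(
                f"frame at t={self.timestamp}: missing joints {sorted(missing)}, "
                f"unknown joints {sorted(extra)}"
            )


@dataclass
class WalkRecording:
    """An ordered, schema-uniform sequence of skeleton frames.

    Positions are stored vectorized: ``positions[frame, joint, axis]`` in
    meters with the joint axis following :data:`JOINT_NAMES`.
    """

    subject_id: str
    camera_id: str
    timestamps: np.ndarray  # (n,)
    positions: np.ndarray  # (n, 25, 3)
    inferred: np.ndarray  # (n, 25) bool

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.inferred = np.asarray(self.inferred, dtype=bool)
        n = self.timestamps.shape[0]
        if n == 0:
            raise SchemaError("recording must contain at least one frame")
        if self.positions.shape != (n, N_JOINTS, 3):
            raise SchemaError(
                f"positions shape {self.positions.shape} != {(n, N_JOINTS, 3)}"
            )
        if self.inferred.shape != (n, N_JOINTS):
            raise SchemaError(f"inferred shape {self.inferred.shape} != {(n, N_JOINTS)}")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise SchemaError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def joint_positions(self, name: str) -> np.ndarray:
        """(n, 3) trajectory of one named joint."""
        return self.positions[:, JOINT_INDEX[name], :]

    def frame(self, i: int) -> SkeletonFrame:
        joints = {
            name: Joint(
                name,
                float(self.positions[i, j, 0]),
                float(self.positions[i, j, 1]),
                float(self.positions[i, j, 2]),
                bool(self.inferred[i, j]),
            )
            for name, j in JOINT_INDEX.items()
        }
        return SkeletonFrame(float(self.timestamps[i]), joints)

    def select(self, idx: Sequence[int] | np.ndarray) -> "WalkRecording":
        """Sub-recording keeping frames ``idx`` (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        return WalkRecording(
            self.subject_id,
            self.camera_id,
            self.timestamps[idx],
            self.positions[idx],
            self.inferred[idx],
        )

    def copy(self) -> "WalkRecording":
        return WalkRecording(
            self.subject_id,
            self.camera_id,
            self.timestamps.copy(),
            self.positions.copy(),
            self.inferred.copy(),
        )

    @classmethod
    def from_frames(
        cls, subject_id: str, camera_id: str, frames: Iterable[SkeletonFrame]
    ) -> "WalkRecording":
        frames = list(frames)
        if not frames:
            raise SchemaError("recording must contain at least one frame")
        ts = np.array([f.timestamp for f in frames])
        pos = np.zeros((len(frames), N_JOINTS, 3))
        inf = np.zeros((len(frames), N_JOINTS), dtype=bool)
        for i, f in enumerate(frames):
            for name, j in JOINT_INDEX.items():
                joint = f.joints[name]
                pos[i, j] = (joint.x, joint.y, joint.z)
                inf[i, j] = joint.inferred
        return cls(subject_id, camera_id, ts, pos, inf)


@dataclass(frozen=True)
class Subject:
    """Study participant with the clinician-assigned gait-impairment stage."""

    subject_id: str
    stage_label: str
    age: float | None = None
    gender: str | None = None
    disease_years: float | None = None
    first_affected_side: str | None = None

    def __post_init__(self) -> None:
        if str(self.stage_label) not in STAGE_LABELS:
            raise ValueError(
                f"stage_label {self.stage_label!r} not in {STAGE_LABELS}"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS: tuple[str, ...] = ("timestamp",) + tuple(
    f"{name}_{axis}" for name in JOINT_NAMES for axis in ("x", "y", "z", "inferred")
)


def _fmt(v: float) -> str:
    return repr(float(v))


def write_recording(recording: WalkRecording, path: str | Path, format: str = "csv") -> None:
    """Write a recording in the canonical CSV or JSON dialect."""
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(CSV_COLUMNS)
            for i in range(recording.n_frames):
                row = [_fmt(recording.timestamps[i])]
                for j in range(N_JOINTS):
                    row.extend(_fmt(recording.positions[i, j, a]) for a in range(3))
                    row.append(str(int(recording.inferred[i, j])))
                w.writerow(row)
    elif format == "json":
        frames = []
        for i in range(recording.n_frames):
            joints = {
                name: {
                    "x": float(recording.positions[i, j, 0]),
                    "y": float(recording.positions[i, j, 1]),
                    "z": float(recording.positions[i, j, 2]),
                    "inferred": bool(recording.inferred[i, j]),
                }
                for name, j in JOINT_INDEX.items()
            }
            frames.append({"timestamp": float(recording.timestamps[i]), "joints": joints})
        payload = {
            "subject_id": recording.subject_id,
            "camera_id": recording.camera_id,
            "frames": frames,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_recording(
    path: str | Path,
    format: str | None = None,
    subject_id: str | None = None,
    camera_id: str = "cam0",
) -> WalkRecording:
    """Read a canonical-dialect recording; schema is validated at this boundary."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if subject_id is None:
        subject_id = path.stem
    if format == "csv":
        return _read_csv(path, subject_id, camera_id)
    if format == "json":
        return _read_json(path, subject_id, camera_id)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path, subject_id: str, camera_id: str) -> WalkRecording:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RecordingParseError(f"{path}: empty file") from None
        if tuple(header) != CSV_COLUMNS:
            missing = set(CSV_COLUMNS) - set(header)
            raise SchemaError(
                f"{path}: non-canonical header; missing columns {sorted(missing)[:5]}"
            )
        ts, pos, inf = [], [], []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(CSV_COLUMNS):
                raise RecordingParseError(
                    f"{path}: line {lineno}: expected {len(CSV_COLUMNS)} fields, "
                    f"got {len(row)}"
                )
            try:
                ts.append(float(row[0]))
                fp = np.empty((N_JOINTS, 3))
                fi = np.empty(N_JOINTS, dtype=bool)
                for j in range(N_JOINTS):
                    base = 1 + 4 * j
                    fp[j] = (float(row[base]), float(row[base + 1]), float(row[base + 2]))
                    fi[j] = bool(int(row[base + 3]))
            except ValueError as exc:
                raise RecordingParseError(f"{path}: line {lineno}: {exc}") from None
            pos.append(fp)
            inf.append(fi)
    if not ts:
        raise RecordingParseError(f"{path}: no frames")
    return WalkRecording(subject_id, camera_id, np.array(ts), np.array(pos), np.array(inf))


def _read_json(path: Path, subject_id: str, camera_id: str) -> WalkRecording:
    with open(path) as fh:
        payload = json.load(fh)
    frames = payload.get("frames", [])
    if not frames:
        raise RecordingParseError(f"{path}: no frames")
    ts, pos, inf = [], [], []
    for i, frame in enumerate(frames):
        joints = frame.get("joints", {})
        missing = set(JOINT_NAMES) - set(joints)
        if missing:
            raise SchemaError(
                f"{path}: frame {i}: missing joint(s) {sorted(missing)}"
            )
        ts.append(float(frame["timestamp"]))
        fp = np.empty((N_JOINTS, 3))
        fi = np.empty(N_JOINTS, dtype=bool)
        for name, j in JOINT_INDEX.items():
            rec = joints[name]
            fp[j] = (float(rec["x"]), float(rec["y"]), float(rec["z"]))
            fi[j] = bool(rec["inferred"])
        pos.append(fp)
        inf.append(fi)
    return WalkRecording(
        payload.get("subject_id", subject_id),
        payload.get("camera_id", camera_id),
        np.array(ts),
        np.array(pos),
        np.array(inf),
    )


def write_subjects(subjects: Sequence[Subject], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["subject_id", "stage_label", "age", "gender", "disease_years", "first_affected_side"]
        )
        for s in subjects:
            w.writerow(
                [
                    s.subject_id,
                    s.stage_label,
                    "" if s.age is None else s.age,
                    s.gender or "",
                    "" if s.disease_years is None else s.disease_years,
                    s.first_affected_side or "",
                ]
            )


def read_subjects(path: str | Path) -> list[Subject]:
    subjects = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            subjects.append(
                Subject(
                    subject_id=row["subject_id"],
                    stage_label=row["stage_label"],
                    age=float(row["age"]) if row.get("age") else None,
                    gender=row.get("gender") or None,
                    disease_years=float(row["disease_years"])
                    if row.get("disease_years")
                    else None,
                    first_affected_side=row.get("first_affected_side") or None,
                )
            )
    return subjects


def mirror_left_right(positions: np.ndarray, inferred: np.ndarray | None = None):
    """Swap left/right joint labels in place-free copies.

    Reproduces the tracker artifact where a subject walking away from the
    camera is fitted as if facing it, yielding an "impossible" skeleton with
    swapped sides.
    """
    pos = positions.copy()
    inf = inferred.copy() if inferred is not None else None
    for left, right in LEFT_RIGHT_PAIRS:
        li, ri = JOINT_INDEX[left], JOINT_INDEX[right]
        pos[..., li, :], pos[..., ri, :] = (
            positions[..., ri, :].copy(),
            positions[..., li, :].copy(),
        )
        if inf is not None:
            inf[..., li], inf[..., ri] = (
                inferred[..., ri].copy(),
                inferred[..., li].copy(),
            )
    return (pos, inf) if inferred is not None else pos
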