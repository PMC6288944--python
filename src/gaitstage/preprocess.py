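"""Cleaning, gait-step segmentation, and frame labeling.

The six-stage procedure that turns a raw skeleton recording into labeled
frame sets and a spin-step count:

1. *Initial cleaning* — drop frames with many (>= 4) inferred joints.
2. *Step identification* — gait steps are the spans between consecutive
   local maxima of the inter-feet distance series; the spine-base floor
   projection at the two bounding maxima gives each step's displacement
   direction, which classifies it as straight (< 0.1 rad off the corridor
   line), slightly displaced (0.1-0.2 rad) or spin (> 0.2 rad).
3. *Step cleaning* — a step is valid only if exactly one foot moved; frames
   with strongly asymmetric left/right limb lengths are discarded.
4. *Frame labeling* — type ``a``: aligned frames of straight steps toward
   the camera; type ``b``: aligned frames of slight steps toward the camera;
   type ``c``: all frames of such slight steps (``b`` is a subset of ``c``).
   A label needs at least 5 frames within its step to survive.
5. *Final cleaning* — frames of away-from-camera non-spin steps are removed
   (the tracker mirrors skeletons there); spin frames are kept regardless of
   direction.
6. Each step's frames are rotated about the vertical axis so the walking
   direction aligns with the camera axis before any angles are measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .skeleton import JOINT_INDEX, LIMB_SEGMENTS, WalkRecording

STRAIGHT_THRESH = 0.1  # rad
SLIGHT_THRESH = 0.2  # rad
ALIGN_THRESH = 0.1  # rad, frame-alignment test
MAX_INFERRED = 4
MIN_LABEL_FRAMES = 5
MOVED_THRESH = 0.1  # m, "one foot moved" test
LIMB_ASYM_TOL = 0.10  # relative left/right length difference
SMOOTH_WINDOW = 5  # frames
MIN_PROMINENCE = 0.05  # m
MIN_SEPARATION = 5  # frames


@dataclass
class GaitStep:
    """A frame span between two consecutive inter-feet distance maxima."""

    start: int  # index of the bounding maximum frames (inclusive)
    end: int
    direction_angle: float = float("nan")  # folded to the corridor line
    toward_camera: bool = False
    category: str = "invalid"  # straight | slight | spin | invalid
    valid: bool = False


@dataclass
class ProcessedStep:
    step: GaitStep
    frame_idx: np.ndarray  # indices into the cleaned recording
    orig_idx: np.ndarray  # indices into the raw recording
    rotated: np.ndarray  # (m, 25, 3) rotation-aligned positions
    labels: list[set[str]]  # per-frame label subsets of {a, b, c, spin}
    aligned: np.ndarray  # per-frame alignment flags


@dataclass
class PreprocessResult:
    subject_id: str
    camera_id: str
    steps: list[ProcessedStep]
    n_spin_steps: int
    attrition: dict[str, int] = field(default_factory=dict)

    def labeled_frames(self, label: str):
        """Yield (step, rotated positions) runs for one frame type."""
        for ps in self.steps:
            mask = np.array([label in s for s in ps.labels], dtype=bool)
            if mask.any():
                yield ps, ps.rotated[mask]


# ---------------------------------------------------------------------------
# individual cleaning / segmentation operations
# ---------------------------------------------------------------------------

def clean_inferred(recording: WalkRecording, max_inferred: int = MAX_INFERRED):
    """Drop frames with >= ``max_inferred`` inferred joints.

    Returns the surviving sub-recording and the original frame indices, or
    ``(None, empty)`` if nothing survives.
    """
    counts = recording.inferred.sum(axis=1)
    keep = np.flatnonzero(counts < max_inferred)
    if keep.size == 0:
        return None, keep
    return recording.select(keep), keep


def feet_distance(recording: WalkRecording) -> np.ndarray:
    """Per-frame 3-D Euclidean distance between left and right ankles."""
    d = recording.joint_positions("ankle_left") - recording.joint_positions("ankle_right")
    return np.linalg.norm(d, axis=1)


def detect_steps(
    series: np.ndarray,
    smooth_window: int = SMOOTH_WINDOW,
    min_prominence: float = MIN_PROMINENCE,
    min_separation: int = MIN_SEPARATION,
) -> list[GaitStep]:
    """Steps as spans between consecutive retained local maxima.

    The series is moving-average smoothed before peak picking; each smoothed
    peak is then refined to the raw-series argmax in its neighborhood, since
    smoothing can shift an asymmetric cusp by a frame or two. Returns an
    empty list when fewer than two maxima exist.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        return []
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(series, kernel, mode="same")
    else:
        smoothed = series
    peaks, _ = find_peaks(
        smoothed, prominence=min_prominence, distance=max(1, min_separation)
    )
    refined = sorted(
        {
            int(p - smooth_window + np.argmax(series[max(p - smooth_window, 0): p + smooth_window + 1]))
            if p - smooth_window >= 0
            else int(np.argmax(series[: p + smooth_window + 1]))
            for p in peaks
        }
    )
    if len(refined) < 2:
        return []
    return [GaitStep(start=refined[i], end=refined[i + 1]) for i in range(len(refined) - 1)]


def step_direction(step: GaitStep, recording: WalkRecording):
    """Displacement direction of a step from the spine-base floor projection.

    Returns ``(direction_angle, toward_camera, signed_angle)``: the angle is
    measured between the XZ displacement of the spine base across the step
    and the camera (z) axis, folded to the corridor *line* so that walking
    straight away from the camera also reads as 0; ``toward_camera`` keeps
    the sign of the depth motion; ``signed_angle`` is the off-line angle used
    for rotation alignment. A zero-length displacement flags the step invalid.
    """
    sb = recording.joint_positions("spine_base")
    dx = sb[step.end, 0] - sb[step.start, 0]
    dz = sb[step.end, 2] - sb[step.start, 2]
    r = math.hypot(dx, dz)
    if r == 0.0:
        return float("nan"), False, 0.0
    toward = dz < 0
    angle = math.acos(min(1.0, abs(dz) / r))
    signed = math.atan2(dx, -dz)
    if signed > math.pi / 2:
        signed -= math.pi
    elif signed <= -math.pi / 2:
        signed += math.pi
    return angle, toward, signed


def classify_step(
    direction_angle: float,
    straight_thresh: float = STRAIGHT_THRESH,
    slight_thresh: float = SLIGHT_THRESH,
) -> str:
    """Total, monotone partition of [0, pi]: straight / slight / spin."""
    if math.isnan(direction_angle):
        return "invalid"
    if direction_angle < straight_thresh:
        return "straight"
    if direction_angle < slight_thresh:
        return "slight"
    return "spin"


def validate_step(
    step: GaitStep,
    recording: WalkRecording,
    moved_threshold: float = MOVED_THRESH,
) -> bool:
    """A step is valid iff exactly one ankle's XZ displacement exceeds the threshold."""
    moved = 0
    for name in ("ankle_left", "ankle_right"):
        p = recording.joint_positions(name)
        d = math.hypot(
            p[step.end, 0] - p[step.start, 0], p[step.end, 2] - p[step.start, 2]
        )
        if d > moved_threshold:
            moved += 1
    return moved == 1


def limb_symmetry_ok(
    positions: np.ndarray, limb_asym_tol: float = LIMB_ASYM_TOL
) -> np.ndarray:
    """Per-frame flag: True when no limb type has a large left/right length gap.

    ``positions`` is (m, 25, 3); a frame fails when, for any of humerus /
    forearm / thigh / shin, ``|len_L - len_R| / mean > limb_asym_tol``.
    """
    ok = np.ones(positions.shape[0], dtype=bool)
    for limb in ("humerus", "forearm", "thigh", "shin"):
        lp, ld = LIMB_SEGMENTS[f"{limb}.L"]
        rp, rd = LIMB_SEGMENTS[f"{limb}.R"]
        llen = np.linalg.norm(
            positions[:, JOINT_INDEX[ld]] - positions[:, JOINT_INDEX[lp]], axis=1
        )
        rlen = np.linalg.norm(
            positions[:, JOINT_INDEX[rd]] - positions[:, JOINT_INDEX[rp]], axis=1
        )
        mean = (llen + rlen) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.abs(llen - rlen) / mean
        ok &= rel <= limb_asym_tol
    return ok


def align_rotation(positions: np.ndarray, signed_angle: float) -> np.ndarray:
    """Rigid rotation about the vertical axis removing the off-line heading.

    ``positions`` is (m, 25, 3); y coordinates are untouched, pairwise
    distances preserved. After rotation the recomputed step displacement
    direction angle is ~0.
    """
    c, s = math.cos(signed_angle), math.sin(signed_angle)
    out = positions.copy()
    x, z = positions[..., 0], positions[..., 2]
    out[..., 0] = c * x + s * z
    out[..., 2] = -s * x + c * z
    return out


def frame_alignment(
    step: GaitStep, recording: WalkRecording, align_thresh: float = ALIGN_THRESH
) -> np.ndarray:
    """Per-frame flag: spine base within ``align_thresh`` rad of the step direction.

    The test compares the direction of (frame spine-base - step-start
    spine-base) on the floor plane against the step displacement vector;
    frames still at the start point (zero vector) count as aligned.
    """
    sb = recording.joint_positions("spine_base")
    span = np.arange(step.start, step.end + 1)
    d = sb[step.end, [0, 2]] - sb[step.start, [0, 2]]
    dn = np.linalg.norm(d)
    v = sb[span][:, [0, 2]] - sb[step.start, [0, 2]]
    vn = np.linalg.norm(v, axis=1)
    aligned = np.ones(span.size, dtype=bool)
    nz = vn > 0
    if dn > 0:
        cosang = np.clip((v[nz] @ d) / (vn[nz] * dn), -1.0, 1.0)
        aligned[nz] = np.arccos(cosang) < align_thresh
    return aligned


def label_frames(
    category: str,
    toward_camera: bool,
    aligned: np.ndarray,
    frame_ok: np.ndarray,
    min_frames: int = MIN_LABEL_FRAMES,
) -> list[set[str]]:
    """Assign {a, b, c, spin} labels to the frames of one valid step.

    Straight toward-camera steps: aligned frames get ``a``. Slight
    toward-camera steps: all frames get ``c``, aligned frames additionally
    ``b`` (so b is a subset of c). Spin steps: all frames get ``spin``
    regardless of direction. A label observed on fewer than ``min_frames``
    frames within the step is withdrawn from all of them. Frames failing the
    limb-symmetry test never carry a, b or c.
    """
    m = len(aligned)
    labels: list[set[str]] = [set() for _ in range(m)]
    if category == "spin":
        for s in labels:
            s.add("spin")
        return labels
    if not toward_camera:
        return labels
    if category == "straight":
        for i in range(m):
            if aligned[i] and frame_ok[i]:
                labels[i].add("a")
    elif category == "slight":
        for i in range(m):
            if frame_ok[i]:
                labels[i].add("c")
                if aligned[i]:
                    labels[i].add("b")
    for lab in ("a", "b", "c"):
        n = sum(1 for s in labels if lab in s)
        if 0 < n < min_frames:
            for s in labels:
                s.discard(lab)
    return labels


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    max_inferred: int = MAX_INFERRED
    straight_thresh: float = STRAIGHT_THRESH
    slight_thresh: float = SLIGHT_THRESH
    align_thresh: float = ALIGN_THRESH
    min_frames: int = MIN_LABEL_FRAMES
    moved_thresh: float = MOVED_THRESH
    limb_asym_tol: float = LIMB_ASYM_TOL
    smooth_window: int = SMOOTH_WINDOW
    min_prominence: float = MIN_PROMINENCE
    min_separation: int = MIN_SEPARATION


def preprocess_recording(
    recording: WalkRecording, config: PreprocessConfig | None = None
) -> PreprocessResult:
    """Run the full cleaning/segmentation/labeling procedure on one recording."""
    cfg = config or PreprocessConfig()
    attrition: dict[str, int] = {"frames_in": recording.n_frames}

    cleaned, orig_idx = clean_inferred(recording, cfg.max_inferred)
    attrition["frames_removed_inferred"] = recording.n_frames - orig_idx.size
    if cleaned is None or cleaned.n_frames < 3:
        attrition["steps_detected"] = 0
        return PreprocessResult(recording.subject_id, recording.camera_id, [], 0, attrition)

    series = feet_distance(cleaned)
    steps = detect_steps(series, cfg.smooth_window, cfg.min_prominence, cfg.min_separation)
    attrition["steps_detected"] = len(steps)

    sym_ok = limb_symmetry_ok(cleaned.positions, cfg.limb_asym_tol)
    attrition["frames_removed_asymmetry"] = int((~sym_ok).sum())

    processed: list[ProcessedStep] = []
    n_spin = 0
    n_invalid = 0
    n_away_removed = 0
    for step in steps:
        angle, toward, signed = step_direction(step, cleaned)
        step.direction_angle = angle
        step.toward_camera = toward
        step.valid = (not math.isnan(angle)) and validate_step(step, cleaned, cfg.moved_thresh)
        step.category = (
            classify_step(angle, cfg.straight_thresh, cfg.slight_thresh)
            if step.valid
            else "invalid"
        )
        if not step.valid:
            n_invalid += 1
            continue
        if step.category == "spin":
            n_spin += 1
        elif not toward:
            # final cleaning: away-from-camera non-spin frames are dropped
            n_away_removed += step.end - step.start + 1
            continue
        span = np.arange(step.start, step.end + 1)
        aligned = frame_alignment(step, cleaned, cfg.align_thresh)
        labels = label_frames(
            step.category, toward, aligned, sym_ok[span], cfg.min_frames
        )
        rotated = align_rotation(cleaned.positions[span], signed)
        processed.append(
            ProcessedStep(step, span, orig_idx[span], rotated, labels, aligned)
        )
    attrition["steps_invalid"] = n_invalid
    attrition["frames_removed_away"] = n_away_removed
    return PreprocessResult(
        recording.subject_id, recording.camera_id, processed, n_spin, attrition
    )


def count_spin_steps(results) -> int:
    """Total spin steps pooled over a subject's recordings (all cameras)."""
    if isinstance(results, PreprocessResult):
        results = [results]
    return sum(r.n_spin_steps for r in results)
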