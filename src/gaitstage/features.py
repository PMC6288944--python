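"""Angular feature extraction: 115 features per subject.

For every labeled frame (types ``a``, ``b``, ``c``) 19 angles are measured
on the rotation-aligned skeleton:

* 16 limb projection angles — humerus, forearm, thigh and shin, left and
  right, each projected on the frontal (XY) and lateral (YZ) plane. The
  angle is measured between the bone's plane projection and the downward
  vertical, so a limb hanging straight down reads 0; signs are positive
  toward +x (XY) and toward the camera, i.e. -z (YZ).
* 3 trunk angles — fore-bent (FB) and lateral-bent (LB) from the
  spine-mid -> spine-shoulder vector, neck-flexion (NF) from
  spine-shoulder -> neck, measured against the upward vertical.

Each angle series is lowess-smoothed per contiguous step run, pooled per
frame type, and summarized by mean and standard deviation: 19 angles x
2 statistics x 3 frame types = 114 features, plus the number of spin steps,
for 115 in total. Features of an absent frame type are missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .preprocess import PreprocessResult
from .skeleton import JOINT_INDEX, LIMB_SEGMENTS

LOWESS_FRAC = 0.3
FRAME_TYPES = ("a", "b", "c")

#: the 19-angle registry: 16 limb projections + NF + FB + LB
ANGLE_NAMES: tuple[str, ...] = tuple(
    f"{limb}.{side}.{plane}"
    for limb in ("humerus", "forearm", "thigh", "shin")
    for side in ("L", "R")
    for plane in ("XY", "YZ")
) + ("NF", "FB", "LB")

N_ANGLES = len(ANGLE_NAMES)

#: canonical order of the 115 feature slots
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{t}.{stat}.{angle}"
    for t in FRAME_TYPES
    for stat in ("mean", "sd")
    for angle in ANGLE_NAMES
) + ("spin.n_steps",)

N_FEATURES = len(FEATURE_NAMES)


def _proj_angle(v: np.ndarray, i: int, j: int, ref_sign: float) -> np.ndarray:
    """Signed angle of the (i, j)-plane projection of v against the vertical.

    ``j`` is the vertical component; ``ref_sign`` -1 measures from the
    downward vertical (limbs), +1 from the upward vertical (trunk). Returns
    NaN where the projection has zero length.
    """
    a = v[:, i]
    b = ref_sign * v[:, j]
    ang = np.arctan2(a, b)
    ang[np.hypot(a, b) < 1e-12] = np.nan
    return ang


def limb_angle(positions: np.ndarray, bone: str, plane: str) -> np.ndarray:
    """Projection angle series for one bone over (m, 25, 3) aligned positions.

    ``bone`` is e.g. ``"shin.L"``; ``plane`` is ``"XY"`` (frontal, sign
    toward +x) or ``"YZ"`` (lateral, sign toward the camera at -z).
    """
    prox, dist = LIMB_SEGMENTS[bone]
    v = positions[:, JOINT_INDEX[dist]] - positions[:, JOINT_INDEX[prox]]
    if plane == "XY":
        return _proj_angle(v, 0, 1, -1.0)
    if plane == "YZ":
        return _proj_angle(-v, 2, 1, 1.0)  # atan2(-vz, -vy)
    raise ValueError(f"unknown plane {plane!r}")


def bent_angles(positions: np.ndarray) -> dict[str, np.ndarray]:
    """NF, FB and LB trunk angle series over (m, 25, 3) aligned positions."""
    trunk = (
        positions[:, JOINT_INDEX["spine_shoulder"]] - positions[:, JOINT_INDEX["spine_mid"]]
    )
    neck = positions[:, JOINT_INDEX["neck"]] - positions[:, JOINT_INDEX["spine_shoulder"]]
    return {
        "FB": _proj_angle(-trunk[:, [0, 1, 2]] * [1, -1, 1], 2, 1, 1.0),
        "LB": _proj_angle(trunk, 0, 1, 1.0),
        "NF": _proj_angle(-neck[:, [0, 1, 2]] * [1, -1, 1], 2, 1, 1.0),
    }


def compute_angles(positions: np.ndarray) -> np.ndarray:
    """(m, 19) matrix of all registry angles, columns following ANGLE_NAMES."""
    m = positions.shape[0]
    out = np.empty((m, N_ANGLES))
    col = 0
    for limb in ("humerus", "forearm", "thigh", "shin"):
        for side in ("L", "R"):
            for plane in ("XY", "YZ"):
                out[:, col] = limb_angle(positions, f"{limb}.{side}", plane)
                col += 1
    bent = bent_angles(positions)
    for name in ("NF", "FB", "LB"):
        out[:, col] = bent[name]
        col += 1
    return out


def smooth_series(values: np.ndarray, lowess_frac: float = LOWESS_FRAC) -> np.ndarray:
    """Lowess-smooth one contiguous run; single points pass through unchanged."""
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        return values
    x = np.arange(values.size, dtype=float)
    out = values.copy()
    out[finite] = lowess(
        values[finite], x[finite], frac=lowess_frac, it=1, return_sorted=False
    )
    return out


def aggregate(pooled: np.ndarray) -> tuple[float, float]:
    """(mean, sd) of pooled smoothed values; sd uses the n-1 denominator."""
    pooled = np.asarray(pooled, dtype=float)
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        return float("nan"), float("nan")
    mean = float(pooled.mean())
    sd = 0.0 if pooled.size == 1 else float(pooled.std(ddof=1))
    return mean, sd


def extract_features(
    results: PreprocessResult | list[PreprocessResult],
    lowess_frac: float = LOWESS_FRAC,
) -> pd.Series:
    """Assemble the 115-feature vector for one subject.

    ``results`` are the preprocessed recordings of that subject (one per
    camera); labeled frames and spin steps are pooled across them.
    """
    if isinstance(results, PreprocessResult):
        results = [results]
    pools: dict[str, list[list[np.ndarray]]] = {
        t: [[] for _ in range(N_ANGLES)] for t in FRAME_TYPES
    }
    n_spin = 0
    for res in results:
        n_spin += res.n_spin_steps
        for ps in res.steps:
            if ps.step.category not in ("straight", "slight"):
                continue
            angle_mat = None
            for t in FRAME_TYPES:
                mask = np.array([t in s for s in ps.labels], dtype=bool)
                if not mask.any():
                    continue
                if angle_mat is None:
                    angle_mat = compute_angles(ps.rotated)
                run = angle_mat[mask]
                for j in range(N_ANGLES):
                    pools[t][j].append(smooth_series(run[:, j], lowess_frac))
    values: dict[str, float] = {}
    for t in FRAME_TYPES:
        for j, angle in enumerate(ANGLE_NAMES):
            runs = pools[t][j]
            pooled = np.concatenate(runs) if runs else np.array([])
            mean, sd = aggregate(pooled)
            values[f"{t}.mean.{angle}"] = mean
            values[f"{t}.sd.{angle}"] = sd
    values["spin.n_steps"] = float(n_spin)
    return pd.Series([values[name] for name in FEATURE_NAMES], index=list(FEATURE_NAMES))


def cohort_features(subject_results: dict[str, list[PreprocessResult]]) -> pd.DataFrame:
    """One-row-per-subject feature table with the 115 canonical columns."""
    rows = {sid: extract_features(res) for sid, res in subject_results.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df[list(FEATURE_NAMES)]
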