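"""Cleaning, segmentation, direction, labeling: unit and closed-loop checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitstage.preprocess import (
    GaitStep,
    align_rotation,
    classify_step,
    clean_inferred,
    detect_steps,
    feet_distance,
    label_frames,
    limb_symmetry_ok,
    step_direction,
    validate_step,
)
from gaitstage.skeleton import JOINT_INDEX, N_JOINTS, WalkRecording


def _recording_with(positions, inferred=None):
    n = positions.shape[0]
    if inferred is None:
        inferred = np.zeros((n, N_JOINTS), bool)
    return WalkRecording("s", "c", np.arange(n) / 30.0, positions, inferred)


# -- initial cleaning -------------------------------------------------------

def test_clean_inferred_threshold_is_four_joints():
    pos = np.zeros((10, N_JOINTS, 3))
    pos[..., 2] = 2.0
    inf = np.zeros((10, N_JOINTS), bool)
    inf[1, :3] = True   # 3 inferred: kept
    inf[2, :4] = True   # 4 inferred: removed
    inf[5, :5] = True
    inf[7, :10] = True
    rec = _recording_with(pos, inf)
    cleaned, idx = clean_inferred(rec)
    assert cleaned.n_frames == 7
    assert 1 in idx and 2 not in idx and 5 not in idx and 7 not in idx


def test_clean_inferred_can_empty_a_recording():
    pos = np.ones((3, N_JOINTS, 3))
    inf = np.ones((3, N_JOINTS), bool)
    cleaned, idx = clean_inferred(_recording_with(pos, inf))
    assert cleaned is None and idx.size == 0


# -- feet distance & step detection ----------------------------------------

def test_feet_distance_345_triangle():
    pos = np.zeros((1, N_JOINTS, 3))
    pos[0, JOINT_INDEX["ankle_left"]] = (0.0, 0.0, 2.0)
    pos[0, JOINT_INDEX["ankle_right"]] = (0.3, 0.0, 2.4)
    assert feet_distance(_recording_with(pos))[0] == pytest.approx(0.5)
    pos[0, JOINT_INDEX["ankle_right"]] = (0.0, 0.0, 2.0)
    assert feet_distance(_recording_with(pos))[0] == 0.0


def test_detect_steps_constant_series_has_none():
    assert detect_steps(np.full(50, 0.3)) == []


def test_detect_steps_two_maxima_single_step():
    series = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
    steps = detect_steps(series, smooth_window=1, min_prominence=0.5, min_separation=1)
    assert len(steps) == 1
    assert (steps[0].start, steps[0].end) == (1, 3)


def test_detected_spans_tile_the_maxima_interval(noiseless_walk):
    recording, truth = noiseless_walk
    steps = detect_steps(feet_distance(recording))
    for prev, nxt in zip(steps, steps[1:]):
        assert prev.end == nxt.start  # shared boundary, no gaps, no overlap
    assert [s.start for s in steps] == truth.boundaries[:-1]
    assert [s.end for s in steps] == truth.boundaries[1:]


# -- direction and categories ----------------------------------------------

def _direction_of(dx, dz):
    pos = np.zeros((2, N_JOINTS, 3))
    pos[1, JOINT_INDEX["spine_base"], 0] = dx
    pos[1, JOINT_INDEX["spine_base"], 2] = dz
    return step_direction(GaitStep(0, 1), _recording_with(pos))


def test_step_direction_on_axis_toward():
    angle, toward, signed = _direction_of(0.0, -0.5)
    assert angle == pytest.approx(0.0) and toward and signed == pytest.approx(0.0)


def test_step_direction_perpendicular():
    angle, _, _ = _direction_of(0.5, 0.0)
    assert angle == pytest.approx(math.pi / 2)


def test_step_direction_slight_example():
    angle, toward, _ = _direction_of(0.1, -0.99)
    assert angle == pytest.approx(math.atan2(0.1, 0.99), abs=1e-12)
    assert toward
    assert classify_step(angle) == "slight"


def test_step_direction_away_straight_folds_to_zero():
    angle, toward, _ = _direction_of(0.0, 0.5)
    assert angle == pytest.approx(0.0) and not toward
    assert classify_step(angle) == "straight"


def test_zero_displacement_flags_invalid():
    angle, _, _ = _direction_of(0.0, 0.0)
    assert math.isnan(angle)
    assert classify_step(angle) == "invalid"


@pytest.mark.parametrize(
    "angle,category",
    [(0.05, "straight"), (0.0, "straight"), (0.0999, "straight"),
     (0.1, "slight"), (0.15, "slight"), (0.1999, "slight"),
     (0.2, "spin"), (0.25, "spin"), (math.pi / 2, "spin")],
)
def test_classify_step_thresholds(angle, category):
    assert classify_step(angle) == category


@given(st.floats(min_value=0.0, max_value=math.pi, allow_nan=False))
@settings(max_examples=200, deadline=None)
def test_classify_step_total_monotone_partition(angle):
    cat = classify_step(angle)
    assert cat in {"straight", "slight", "spin"}
    order = {"straight": 0, "slight": 1, "spin": 2}
    # monotone: a larger angle never maps to an earlier category
    assert order[classify_step(min(angle + 0.05, math.pi))] >= order[cat]


# -- validation --------------------------------------------------------------

def _step_with_feet(dl, dr):
    pos = np.zeros((2, N_JOINTS, 3))
    pos[1, JOINT_INDEX["ankle_left"], 0] = dl
    pos[1, JOINT_INDEX["ankle_right"], 0] = dr
    return GaitStep(0, 1), _recording_with(pos)


def test_validate_step_exactly_one_foot_moved():
    step, rec = _step_with_feet(0.4, 0.02)
    assert validate_step(step, rec)
    step, rec = _step_with_feet(0.4, 0.4)
    assert not validate_step(step, rec)
    step, rec = _step_with_feet(0.02, 0.03)
    assert not validate_step(step, rec)


def test_limb_asymmetry_drops_frame():
    pos = np.zeros((1, N_JOINTS, 3))
    # symmetric limb chains of 0.4 m per segment, left thigh stretched to 0.48
    for side in ("left", "right"):
        pos[0, JOINT_INDEX[f"elbow_{side}"], 1] = -0.4
        pos[0, JOINT_INDEX[f"wrist_{side}"], 1] = -0.8
        pos[0, JOINT_INDEX[f"knee_{side}"], 1] = -0.4
        pos[0, JOINT_INDEX[f"ankle_{side}"], 1] = -0.8
    pos[0, JOINT_INDEX["knee_left"], 1] = -0.48
    pos[0, JOINT_INDEX["ankle_left"], 1] = -0.88
    assert not limb_symmetry_ok(pos)[0]
    # 0.18 relative difference > 0.10 tolerance; at tol 0.25 the frame passes
    assert limb_symmetry_ok(pos, limb_asym_tol=0.25)[0]


# -- rotation alignment ------------------------------------------------------

def test_align_rotation_quarter_turn():
    pos = np.zeros((2, N_JOINTS, 3))
    pos[1, :, 0] = 0.5  # pure +x displacement
    rotated = align_rotation(pos, math.pi / 2)
    assert rotated[1, 0, 0] == pytest.approx(0.0, abs=1e-12)
    assert rotated[1, 0, 2] == pytest.approx(-0.5, abs=1e-12)


@given(st.floats(min_value=-1.5, max_value=1.5), st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_align_rotation_is_rigid_and_annihilates_heading(angle, seed):
    rng = np.random.default_rng(seed)
    pos = rng.normal(size=(4, N_JOINTS, 3))
    rotated = align_rotation(pos, angle)
    # inter-joint distances preserved
    d0 = np.linalg.norm(pos[0, :5, None] - pos[0, None, :5], axis=-1)
    d1 = np.linalg.norm(rotated[0, :5, None] - rotated[0, None, :5], axis=-1)
    np.testing.assert_allclose(d0, d1, atol=1e-9)
    np.testing.assert_array_equal(rotated[..., 1], pos[..., 1])
    # a displacement at that heading angle is mapped onto the corridor axis
    disp = np.zeros((1, N_JOINTS, 3))
    disp[0, :, 0] = math.sin(angle)
    disp[0, :, 2] = -math.cos(angle)
    out = align_rotation(disp, angle)
    assert abs(out[0, 0, 0]) < 1e-9


def test_preprocessed_steps_are_rotation_aligned(processed_noiseless):
    for ps in processed_noiseless.steps:
        sb = ps.rotated[:, JOINT_INDEX["spine_base"], :]
        dx = sb[-1, 0] - sb[0, 0]
        dz = sb[-1, 2] - sb[0, 2]
        assert abs(math.atan2(abs(dx), abs(dz))) < 1e-9


# -- labeling ----------------------------------------------------------------

def test_label_frames_straight_aligned_get_a():
    aligned = np.array([True] * 6)
    ok = np.ones(6, bool)
    labels = label_frames("straight", True, aligned, ok)
    assert all(s == {"a"} for s in labels)


def test_label_withdrawn_below_five_frames():
    # slight step, 7 frames, only 4 aligned: b withdrawn, c kept on all 7
    aligned = np.array([True, True, True, True, False, False, False])
    ok = np.ones(7, bool)
    labels = label_frames("slight", True, aligned, ok)
    assert all("b" not in s for s in labels)
    assert sum("c" in s for s in labels) == 7


def test_label_b_subset_of_c():
    aligned = np.array([True] * 5 + [False] * 3)
    ok = np.ones(8, bool)
    labels = label_frames("slight", True, aligned, ok)
    for s in labels:
        assert not ("b" in s and "c" not in s)
    assert sum("b" in s for s in labels) == 5
    assert sum("c" in s for s in labels) == 8


def test_label_spin_regardless_of_direction():
    labels = label_frames("spin", False, np.ones(6, bool), np.ones(6, bool))
    assert all(s == {"spin"} for s in labels)


def test_away_non_spin_frames_removed(processed_noiseless):
    for ps in processed_noiseless.steps:
        if ps.step.category in ("straight", "slight"):
            assert ps.step.toward_camera


# -- generator closed loop ---------------------------------------------------

def test_noiseless_labels_equal_ground_truth(noiseless_walk, processed_noiseless):
    recording, truth = noiseless_walk
    n = recording.n_frames
    labels = [set() for _ in range(n)]
    for ps in processed_noiseless.steps:
        for i, f in enumerate(ps.orig_idx):
            labels[f] |= ps.labels[i]
    assert labels == truth.frame_labels


def test_noiseless_spin_count_equals_ground_truth(noiseless_walk, processed_noiseless):
    _, truth = noiseless_walk
    assert processed_noiseless.n_spin_steps == truth.spin_step_count


def test_noiseless_toward_categories_equal_ground_truth(noiseless_walk, processed_noiseless):
    _, truth = noiseless_walk
    gt = {(s.start_frame, s.end_frame): s.category for s in truth.steps}
    checked = 0
    for ps in processed_noiseless.steps:
        key = (ps.step.start, ps.step.end)
        assert key in gt
        assert ps.step.category == gt[key]
        checked += 1
    # every toward-camera walking step and every spin step is retained
    expected = sum(
        1 for s in truth.steps if s.category == "spin" or s.toward_camera
    )
    assert checked == expected
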