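"""Synthetic skeleton-walk generator with stage-dependent gait structure.

The generator emulates the clinical recording protocol: a subject walks a
corridor of ~4.5-5.5 m back and forth in front of a depth camera, turning
(spinning) between passes, while 25 skeleton joints are captured at 30 fps.
It produces a :class:`~gaitstage.skeleton.WalkRecording` together with frame-
exact ground truth (step boundaries, step categories, frame labels, spin
count) so every downstream stage is testable without patient data.

Kinematic model
---------------
Gait is modeled as alternating single-foot support. Foot plants are anchored
in world coordinates; during each step the stance ankle is stationary and the
swing ankle transfers linearly (with a sinusoidal lift) to its next plant, so
the inter-feet distance has exactly one local maximum per step, at the foot
strike. The pelvis follows the midline piecewise-linearly, advancing one step
length per step along the step's heading, which makes every frame of a step
exactly aligned with the step displacement. Legs close the chain by two-link
inverse kinematics (segment lengths exactly constant); trunk and arms swing
as deterministic sinusoids at the amplitudes given by the profile. Parameters
expressed as standard deviations are realized as sinusoids of amplitude
sd*sqrt(2), whose series standard deviation equals sd.

Away-from-camera passes are emitted with the mirrored-skeleton tracking
artifact (left/right joint labels swapped), as the real sensor fits skeletons
assuming the subject faces the camera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .skeleton import (
    JOINT_INDEX,
    N_JOINTS,
    Subject,
    WalkRecording,
    mirror_left_right,
)

FPS = 30

# Body segment lengths (meters); chosen for an average adult so that the leg
# chain stays within reach for step lengths up to ~0.75 m.
HIP_HEIGHT = 0.84
SPINE_BASE_HEIGHT = 0.86
THIGH_LEN = 0.46
SHIN_LEN = 0.44
ANKLE_HEIGHT = 0.08
TRUNK_SEG = 0.22
NECK_SEG = 0.08
HEAD_SEG = 0.13
SHOULDER_HALF = 0.185
HIP_HALF = 0.10
FOOT_HALF = 0.11
HUMERUS_LEN = 0.28
FOREARM_LEN = 0.26
SPIN_STEP_LEN = 0.35
SLIGHT_OFFSET = 0.15  # rad off the corridor line for slightly displaced steps
NECK_EXTRA_FLEXION = 0.05


class DegenerateProfileError(ValueError):
    """Profile cannot produce at least one full gait step."""


@dataclass
class GaitProfile:
    """Subject-level kinematic parameters of one synthetic walk.

    Angles in radians, lengths in meters, cadence in steps/second. The
    ``*_sd`` parameters control the standard deviation of the corresponding
    angle series; ``jitter_sd`` is isotropic positional sensor noise and
    ``inferred_prob`` the per-(frame, joint) probability of a low-confidence
    inferred position.
    """

    step_length: float = 0.60
    cadence: float = 1.5
    arm_swing_amp_left: float = 0.25
    arm_swing_amp_right: float = 0.28
    arm_lateral_sd_left: float = 0.03
    arm_lateral_sd_right: float = 0.03
    forearm_hang_angle_left: float = 0.30
    forearm_hang_angle_right: float = 0.30
    trunk_flexion_mean: float = 0.08
    lateral_bent_sd: float = 0.03
    knee_flexion_amp: float = 0.35
    spin_step_count: int = 3
    inferred_prob: float = 0.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        amps = (
            self.step_length,
            self.arm_swing_amp_left,
            self.arm_swing_amp_right,
            self.arm_lateral_sd_left,
            self.arm_lateral_sd_right,
            self.lateral_bent_sd,
            self.knee_flexion_amp,
        )
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be >= 0")
        if self.cadence <= 0:
            raise ValueError("cadence must be > 0")
        if not 0.0 <= self.inferred_prob <= 1.0:
            raise ValueError("inferred_prob must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if int(self.spin_step_count) < 2:
            raise ValueError("spin_step_count must be >= 2")
        self.spin_step_count = int(self.spin_step_count)


@dataclass(frozen=True)
class StageTemplate:
    """Per-stage defaults and between-subject spreads for cohort simulation."""

    stage_label: str
    profile: GaitProfile
    spread: dict[str, float] = field(default_factory=dict)

    def sample(self, rng: np.random.Generator) -> GaitProfile:
        params = vars(self.profile).copy()
        for name, sd in self.spread.items():
            base = params[name]
            value = rng.normal(base, sd)
            if name == "spin_step_count":
                value = max(2, int(round(value)))
            elif name in ("inferred_prob",):
                value = float(np.clip(value, 0.0, 1.0))
            elif name == "cadence":
                value = max(0.5, value)
            elif name == "step_length":
                value = max(0.15, value)
            else:
                value = max(0.0, value)
            params[name] = value
        return GaitProfile(**params)


@dataclass(frozen=True)
class GroundTruthStep:
    start_frame: int
    end_frame: int  # inclusive boundary-maximum frame
    category: str  # straight | slight | spin
    toward_camera: bool
    direction_angle: float  # folded to the corridor line, [0, pi/2]


@dataclass
class GroundTruth:
    boundaries: list[int]  # frame indices of the inter-feet distance maxima
    steps: list[GroundTruthStep]
    frame_labels: list[set[str]]  # per emitted frame, subset of {a,b,c,spin}
    spin_step_count: int  # total spin steps over the whole walk


@dataclass(frozen=True)
class _PlannedStep:
    kind: str  # walk | spin
    u: np.ndarray  # XZ-horizontal unit heading (3,)
    length: float
    toward_pass: bool  # True while walking toward the camera


def _left_dir(u: np.ndarray) -> np.ndarray:
    """Subject's left, for horizontal heading u (u x yhat)."""
    return np.array([-u[2], 0.0, u[0]])


def _folded_angle(dx: float, dz: float) -> float:
    r = math.hypot(dx, dz)
    if r == 0:
        return 0.0
    return math.acos(min(1.0, abs(dz) / r))


def _plan_walk(profile: GaitProfile, corridor_length: float, n_passes: int) -> list[_PlannedStep]:
    n_walk = int(math.floor(corridor_length / profile.step_length))
    if n_walk < 1:
        raise DegenerateProfileError(
            f"step_length {profile.step_length} exceeds corridor {corridor_length}"
        )
    plan: list[_PlannedStep] = []
    slight_parity = 0
    for p in range(n_passes):
        toward = p % 2 == 0
        for i in range(n_walk):
            if toward and i % 3 == 2:
                sign = 1.0 if slight_parity % 2 == 0 else -1.0
                slight_parity += 1
                theta = SLIGHT_OFFSET
                u = np.array([sign * math.sin(theta), 0.0, -math.cos(theta)])
            else:
                u = np.array([0.0, 0.0, -1.0 if toward else 1.0])
            plan.append(_PlannedStep("walk", u, profile.step_length, toward))
        if p < n_passes - 1:
            s = profile.spin_step_count
            side = 1.0 if p % 2 == 0 else -1.0
            for j in range(s):
                # line offsets confined to [0.25, pi-0.25] so the >0.2 rad
                # spin criterion always fires regardless of s
                alpha = 0.25 + (j + 0.5) * (math.pi - 0.5) / s
                theta = alpha if toward else math.pi - alpha
                u = np.array([side * math.sin(theta), 0.0, -math.cos(theta)])
                plan.append(_PlannedStep("spin", u, SPIN_STEP_LEN, toward))
    return plan


def simulate_walk(
    profile: GaitProfile,
    corridor_length: float = 5.0,
    n_passes: int = 8,
    seed: int = 0,
    subject_id: str = "synthetic",
    camera_id: str = "cam0",
    fps: int = FPS,
) -> tuple[WalkRecording, GroundTruth]:
    """Simulate one multi-pass corridor walk.

    Returns the recording plus ground truth. Deterministic under fixed seed.
    """
    if corridor_length < 2.0:
        raise ValueError("corridor_length must be >= 2 m")
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    rng = np.random.default_rng(seed)

    frames_per_step = int(round(fps / profile.cadence))
    if frames_per_step < 4:
        raise DegenerateProfileError("cadence too high for the frame rate")
    dt = 1.0 / fps
    step_dur = frames_per_step * dt

    plan = _plan_walk(profile, corridor_length, n_passes)
    k_steps = len(plan)
    # pad with a virtual copy of the first/last step so the first and last
    # true foot strikes are interior maxima of the sampled distance series
    full = [plan[0]] + plan + [plan[-1]]
    n_full = len(full)

    # pelvis midline nodes at boundaries of the padded plan
    n_walk = int(math.floor(corridor_length / profile.step_length))
    start = np.array([0.0, 0.0, 1.5 + n_walk * profile.step_length])
    nodes = np.zeros((n_full + 1, 3))
    nodes[0] = start - full[0].u * full[0].length
    for k, st in enumerate(full):
        nodes[k + 1] = nodes[k] + st.u * st.length

    # foot plants: the strike at padded boundary b plants foot side (b % 2,
    # 0 = left) at the pelvis node plus half the upcoming displacement plus a
    # lateral offset; stored with offset 1 so boundary -1 (pre-plant of the
    # lead-in swing) sits at index 0
    plants = np.zeros((n_full + 2, 3))
    for i in range(n_full + 2):
        b = i - 1  # boundary index, -1 .. n_full
        st = full[min(max(b, 0), n_full - 1)]
        node = nodes[b] if b >= 0 else nodes[0] - full[0].u * full[0].length
        side = 1.0 if b % 2 == 0 else -1.0
        plants[i] = node + st.u * st.length / 2.0 + side * FOOT_HALF * _left_dir(st.u)
        plants[i][1] = ANKLE_HEIGHT

    half = frames_per_step // 2
    g_start = frames_per_step - half  # global frame index of first emitted frame
    g_end = (n_full - 1) * frames_per_step + half  # inclusive
    n_frames = g_end - g_start + 1

    positions = np.zeros((n_frames, N_JOINTS, 3))
    mirrored = np.zeros(n_frames, dtype=bool)

    lift_height = 0.8 * profile.knee_flexion_amp * SHIN_LEN
    omega = math.pi / step_dur  # arm/trunk drive: one cycle per two steps

    away_walk = [st.kind == "walk" and not st.toward_pass for st in full]

    for k in range(n_full):
        # frames are assigned half-open to the step starting at them; the
        # kinematics are continuous across boundaries either way
        g0 = max(k * frames_per_step, g_start)
        g1 = min((k + 1) * frames_per_step, g_end + 1)
        g = np.arange(g0, g1)
        if g.size == 0:
            continue
        tau = (g - k * frames_per_step) / frames_per_step
        t = g * dt
        m = g.size
        st = full[k]
        u, left = st.u, _left_dir(st.u)

        pelvis = nodes[k][None, :] + tau[:, None] * (st.u * st.length)[None, :]

        # feet: the foot that struck at boundary k is stance, the other
        # transfers from its plant at boundary k-1 to boundary k+1, routed
        # through a via-point in its own lateral lane beside the stance ankle
        # (the ankles pass close mid-swing, which guarantees the inter-feet
        # distance maximum at each strike is prominent even for short turning
        # steps)
        stance_side = 0 if k % 2 == 0 else 1  # 0 = left
        stance = np.repeat(plants[k + 1][None, :], m, axis=0)
        s_swing = 1.0 if stance_side == 1 else -1.0  # swing foot side sign
        via = plants[k + 1] + s_swing * 2.0 * FOOT_HALF * left
        tau2 = 2.0 * tau
        first = tau2 <= 1.0
        swing = np.empty((m, 3))
        swing[first] = plants[k][None, :] + tau2[first, None] * (via - plants[k])[None, :]
        swing[~first] = via[None, :] + (tau2[~first, None] - 1.0) * (plants[k + 2] - via)[None, :]
        swing[:, 1] = ANKLE_HEIGHT + lift_height * np.sin(math.pi * tau)
        ankle_l, ankle_r = (stance, swing) if stance_side == 0 else (swing, stance)

        frame_pos = np.zeros((m, N_JOINTS, 3))

        def put(name: str, arr: np.ndarray) -> None:
            frame_pos[:, JOINT_INDEX[name], :] = arr

        spine_base = pelvis + np.array([0.0, SPINE_BASE_HEIGHT, 0.0])
        fb = np.full(m, profile.trunk_flexion_mean)
        lb = profile.lateral_bent_sd * math.sqrt(2.0) * np.sin(0.61 * omega * t + 0.3)
        u_trunk = _tilted_up(fb, lb, u, left)
        u_neck = _tilted_up(fb + NECK_EXTRA_FLEXION, lb, u, left)
        spine_mid = spine_base + TRUNK_SEG * u_trunk
        spine_shoulder = spine_mid + TRUNK_SEG * u_trunk
        neck = spine_shoulder + NECK_SEG * u_neck
        head = neck + HEAD_SEG * u_neck
        put("spine_base", spine_base)
        put("spine_mid", spine_mid)
        put("spine_shoulder", spine_shoulder)
        put("neck", neck)
        put("head", head)

        for side_name, sgn, amp, lat_sd, hang, phase in (
            ("left", 1.0, profile.arm_swing_amp_left, profile.arm_lateral_sd_left,
             profile.forearm_hang_angle_left, 0.0),
            ("right", -1.0, profile.arm_swing_amp_right, profile.arm_lateral_sd_right,
             profile.forearm_hang_angle_right, math.pi),
        ):
            shoulder = spine_shoulder + sgn * SHOULDER_HALF * left
            a_sag = amp * np.sin(omega * t + phase)
            a_lat = lat_sd * math.sqrt(2.0) * np.sin(0.737 * omega * t + 0.9 + phase)
            v_hum = _tilted_down(a_sag, a_lat, u, left)
            elbow = shoulder + HUMERUS_LEN * v_hum
            v_fore = _tilted_down(np.full(m, hang), 0.5 * a_lat, u, left)
            wrist = elbow + FOREARM_LEN * v_fore
            hand = wrist + 0.08 * v_fore
            put(f"shoulder_{side_name}", shoulder)
            put(f"elbow_{side_name}", elbow)
            put(f"wrist_{side_name}", wrist)
            put(f"hand_{side_name}", hand)
            put(f"hand_tip_{side_name}", hand + 0.05 * v_fore)
            put(f"thumb_{side_name}", hand + sgn * 0.03 * left)

        hip_l = spine_base + HIP_HALF * left + np.array([0.0, HIP_HEIGHT - SPINE_BASE_HEIGHT, 0.0])
        hip_r = spine_base - HIP_HALF * left + np.array([0.0, HIP_HEIGHT - SPINE_BASE_HEIGHT, 0.0])
        knee_l, ankle_l = _leg_ik(hip_l, ankle_l, u)
        knee_r, ankle_r = _leg_ik(hip_r, ankle_r, u)
        put("hip_left", hip_l)
        put("hip_right", hip_r)
        put("knee_left", knee_l)
        put("knee_right", knee_r)
        put("ankle_left", ankle_l)
        put("ankle_right", ankle_r)
        foot_off = 0.14 * u + np.array([0.0, -0.03, 0.0])
        put("foot_left", ankle_l + foot_off)
        put("foot_right", ankle_r + foot_off)

        idx = g - g_start
        positions[idx] = frame_pos
        # boundary frames belong to two steps; mirror only if both are
        # away-pass walking steps
        interior = (g != k * frames_per_step) | (g == g_start)
        mirrored[idx[interior]] = away_walk[k]
        bmask = (g == k * frames_per_step) & (g != g_start)
        if bmask.any() and k > 0:
            mirrored[idx[bmask]] = away_walk[k] and away_walk[k - 1]

    if profile.jitter_sd > 0:
        positions += rng.normal(0.0, profile.jitter_sd, size=positions.shape)

    if np.any(mirrored):
        positions[mirrored] = mirror_left_right(positions[mirrored])

    timestamps = np.arange(n_frames) * dt
    inferred = np.zeros((n_frames, N_JOINTS), dtype=bool)
    recording = WalkRecording(subject_id, camera_id, timestamps, positions, inferred)
    if profile.inferred_prob > 0:
        recording = inject_inferred_noise(
            recording, profile.inferred_prob, burst_len=5, seed=int(rng.integers(2**31))
        )

    # ground truth: padded boundaries 1..n_full-1 are the true foot strikes
    boundaries = [k * frames_per_step - g_start for k in range(1, n_full)]
    steps: list[GroundTruthStep] = []
    frame_labels: list[set[str]] = [set() for _ in range(n_frames)]
    for j, st in enumerate(plan):
        s, e = boundaries[j], boundaries[j + 1]
        angle = _folded_angle(float(st.u[0]), float(st.u[2]))
        toward = bool(st.u[2] < 0)
        if st.kind == "spin":
            category = "spin"
            labels = {"spin"}
        elif angle < 0.1:
            category = "straight"
            labels = {"a"} if toward else set()
        else:
            category = "slight"
            labels = {"b", "c"} if toward else set()
        steps.append(GroundTruthStep(s, e, category, toward, angle))
        for f in range(s, e + 1):
            frame_labels[f] |= labels
    spin_total = sum(1 for st in steps if st.category == "spin")
    truth = GroundTruth(boundaries, steps, frame_labels, spin_total)
    return recording, truth


def _tilted_up(sag: np.ndarray, lat: np.ndarray, u: np.ndarray, left: np.ndarray) -> np.ndarray:
    """Unit up-vector tilted by sagittal angle toward heading and lateral angle."""
    ss, sl = np.sin(sag), np.sin(lat)
    c = np.sqrt(np.clip(1.0 - ss**2 - sl**2, 1e-12, None))
    v = ss[:, None] * u[None, :] + sl[:, None] * left[None, :]
    v[:, 1] += c
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _tilted_down(sag: np.ndarray, lat: np.ndarray, u: np.ndarray, left: np.ndarray) -> np.ndarray:
    """Unit down-vector (hanging limb) tilted toward heading / laterally."""
    ss, sl = np.sin(sag), np.sin(lat)
    c = np.sqrt(np.clip(1.0 - ss**2 - sl**2, 1e-12, None))
    v = ss[:, None] * u[None, :] + sl[:, None] * left[None, :]
    v[:, 1] -= c
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _leg_ik(hip: np.ndarray, ankle: np.ndarray, u: np.ndarray):
    """Two-link knee solution bending toward the heading; exact segment lengths.

    If the ankle is out of reach (extreme profiles only) it is pulled in
    along the hip-ankle line so the chain stays rigid.
    """
    reach = 0.998 * (THIGH_LEN + SHIN_LEN)
    d_vec = ankle - hip
    d = np.linalg.norm(d_vec, axis=1)
    over = d > reach
    if np.any(over):
        ankle = ankle.copy()
        ankle[over] = hip[over] + d_vec[over] * (reach / d[over])[:, None]
        d_vec = ankle - hip
        d = np.linalg.norm(d_vec, axis=1)
    uhat = d_vec / d[:, None]
    a = (THIGH_LEN**2 - SHIN_LEN**2 + d**2) / (2.0 * d)
    h = np.sqrt(np.clip(THIGH_LEN**2 - a**2, 0.0, None))
    w = u[None, :] - (uhat @ u)[:, None] * uhat
    w = w / np.clip(np.linalg.norm(w, axis=1, keepdims=True), 1e-12, None)
    knee = hip + a[:, None] * uhat + h[:, None] * w
    return knee, ankle


def inject_inferred_noise(
    recording: WalkRecording,
    inferred_prob: float,
    burst_len: int = 5,
    seed: int = 0,
) -> WalkRecording:
    """Flag joints as inferred in temporal bursts and inflate their noise.

    The per-(frame, joint) marginal flag probability is approximately
    ``inferred_prob``; flags come in runs of up to ``burst_len`` frames, as
    occlusions do.
    """
    if not 0.0 <= inferred_prob <= 1.0:
        raise ValueError("inferred_prob must be in [0, 1]")
    if inferred_prob == 0.0:
        return recording
    rng = np.random.default_rng(seed)
    n = recording.n_frames
    p_start = 1.0 - (1.0 - inferred_prob) ** (1.0 / burst_len)
    starts = rng.random((n, N_JOINTS)) < p_start
    flags = np.zeros((n, N_JOINTS), dtype=bool)
    for off in range(burst_len):
        flags[off:] |= starts[: n - off]
    positions = recording.positions.copy()
    positions[flags] += rng.normal(0.0, 0.02, size=(int(flags.sum()), 3))
    return WalkRecording(
        recording.subject_id,
        recording.camera_id,
        recording.timestamps.copy(),
        positions,
        recording.inferred | flags,
    )


# ---------------------------------------------------------------------------
# Stage templates
# ---------------------------------------------------------------------------

def default_stage_templates() -> dict[str, StageTemplate]:
    """Templates for the three gait-impairment stages plus healthy controls.

    Orderings encode the clinical picture: advancing stage shortens the step,
    reduces knee excursion and arm swing (left side more affected), increases
    stooped posture (frontal bent), lateral sway, lateral arm movement, and
    the number of small steps needed to turn.
    """
    common_spread = {
        "step_length": 0.03,
        "trunk_flexion_mean": 0.015,
        "lateral_bent_sd": 0.006,
        "arm_swing_amp_left": 0.02,
        "arm_swing_amp_right": 0.02,
        "arm_lateral_sd_left": 0.006,
        "arm_lateral_sd_right": 0.006,
        "forearm_hang_angle_left": 0.02,
        "forearm_hang_angle_right": 0.02,
        "knee_flexion_amp": 0.03,
        "spin_step_count": 0.5,
    }
    templates = {
        "1": GaitProfile(
            step_length=0.65,
            cadence=1.5,
            arm_swing_amp_left=0.26,
            arm_swing_amp_right=0.28,
            arm_lateral_sd_left=0.02,
            arm_lateral_sd_right=0.02,
            forearm_hang_angle_left=0.35,
            forearm_hang_angle_right=0.35,
            trunk_flexion_mean=0.05,
            lateral_bent_sd=0.02,
            knee_flexion_amp=0.45,
            spin_step_count=3,
            inferred_prob=0.02,
            jitter_sd=0.003,
        ),
        "2": GaitProfile(
            step_length=0.50,
            cadence=1.36,
            arm_swing_amp_left=0.14,
            arm_swing_amp_right=0.22,
            arm_lateral_sd_left=0.05,
            arm_lateral_sd_right=0.03,
            forearm_hang_angle_left=0.25,
            forearm_hang_angle_right=0.30,
            trunk_flexion_mean=0.15,
            lateral_bent_sd=0.07,
            knee_flexion_amp=0.30,
            spin_step_count=4,
            inferred_prob=0.02,
            jitter_sd=0.003,
        ),
        "3": GaitProfile(
            step_length=0.35,
            cadence=1.2,
            arm_swing_amp_left=0.06,
            arm_swing_amp_right=0.12,
            arm_lateral_sd_left=0.09,
            arm_lateral_sd_right=0.05,
            forearm_hang_angle_left=0.06,
            forearm_hang_angle_right=0.20,
            trunk_flexion_mean=0.28,
            lateral_bent_sd=0.10,
            knee_flexion_amp=0.15,
            spin_step_count=7,
            inferred_prob=0.02,
            jitter_sd=0.003,
        ),
        "control": GaitProfile(
            step_length=0.68,
            cadence=1.58,
            arm_swing_amp_left=0.30,
            arm_swing_amp_right=0.30,
            arm_lateral_sd_left=0.015,
            arm_lateral_sd_right=0.015,
            forearm_hang_angle_left=0.38,
            forearm_hang_angle_right=0.38,
            trunk_flexion_mean=0.03,
            lateral_bent_sd=0.015,
            knee_flexion_amp=0.48,
            spin_step_count=3,
            inferred_prob=0.02,
            jitter_sd=0.003,
        ),
    }
    return {
        label: StageTemplate(label, prof, dict(common_spread))
        for label, prof in templates.items()
    }


def simulate_cohort(
    templates: Sequence[StageTemplate] | dict[str, StageTemplate],
    n_per_stage: int,
    seed: int = 0,
    corridor_length: float = 5.0,
    n_passes: int = 8,
) -> list[tuple[WalkRecording, Subject, GroundTruth]]:
    """Simulate ``n_per_stage`` subjects for each stage template.

    Subject-level profiles are drawn from the template spreads; everything is
    reproducible under a fixed seed.
    """
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    if isinstance(templates, dict):
        templates = list(templates.values())
    rng = np.random.default_rng(seed)
    out = []
    for template in templates:
        for i in range(n_per_stage):
            profile = template.sample(rng)
            sid = f"s{template.stage_label}_{i:02d}"
            walk_seed = int(rng.integers(2**31))
            rec, truth = simulate_walk(
                profile,
                corridor_length=corridor_length,
                n_passes=n_passes,
                seed=walk_seed,
                subject_id=sid,
            )
            out.append((rec, Subject(sid, template.stage_label), truth))
    return out
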