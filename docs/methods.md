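# Methods

This note documents the models, conventions and numerical choices behind
`gaitstage`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, and what the
synthetic experiments do and do not demonstrate.

## Coordinate conventions

Skeletons live in a right-handed camera frame: x lateral, y vertical, z
depth into the scene, units meters. The camera sits at z = 0 facing the
corridor, so a subject walking toward the camera moves in −z. Each frame
carries exactly 25 named joints and a per-joint *inferred* flag marking
positions reconstructed by the tracker while the joint was occluded.

The canonical on-disk dialect is a flat CSV (`timestamp, <joint>_x, _y, _z,
_inferred` in a fixed joint order) with floats written as shortest
round-trip `repr`, so reading and rewriting a canonical file is
byte-identical; a JSON dialect mirrors it. No capture-device format is
assumed.

## Step segmentation and direction

A gait step is the frame span between two consecutive local maxima of the
3-D distance between the ankle joints (ankles track more reliably than foot
tips; the choice is configurable). The series is smoothed with a centered
moving average (window 5 frames) and peaks are picked with minimum
prominence 0.05 m and minimum separation 5 frames — values sized to 30 fps
gait. Each smoothed peak is then refined to the raw-series argmax within
one window of the smoothed location: centered smoothing provably shifts the
maximum of an asymmetric cusp by a frame or two (e.g. where a long walking
step meets a short turning step), and the refinement removes that bias.
Consecutive maxima share the boundary frame, so step spans tile the
interval between the first and last maximum with no gaps.

The displacement direction of a step is taken from the spine-base floor
(XZ) projection at the two bounding maxima. The direction angle is measured
against the corridor **line** (the camera z-axis, unsigned), folding
walking-away headings onto [0, π/2]; a separate `toward_camera` flag keeps
the depth sign. This folding is what makes "an away-from-camera straight
step" a representable concept — such steps are then removed by the final
cleaning rule, while spin frames are kept whichever way they face. Category
thresholds are half-open: [0, 0.1) straight, [0.1, 0.2) slightly displaced,
[0.2, π] spin; exact equality at a threshold promotes to the larger
category, a convention chosen because strict "less than" wording leaves
boundaries undefined.

Step validity requires exactly one ankle to displace more than 0.1 m in the
floor plane across the span ("one foot moved"); the threshold is the order
of a short Parkinsonian step. Frames whose left/right limb lengths differ
by more than 10% of their mean for any limb type (humerus, forearm, thigh,
shin) are excluded from labeling — a generous bound for tracking noise.

Before any angle is measured, each step's frames are rigidly rotated about
the vertical axis by the signed off-line heading so the walking direction
coincides with the camera axis. The rotation preserves y coordinates and
all pairwise distances to 1e−9 and drives the recomputed direction angle
below 1e−9.

## Frame labels

Type `a` frames are aligned frames of straight toward-camera steps; type
`b` aligned frames of slightly displaced toward-camera steps; type `c` all
frames of such slight steps, so b ⊆ c by construction (the inclusive
reading of "equally aligned or not aligned"). A frame is *aligned* when the
spine-base displacement from the step start deviates less than 0.1 rad from
the step direction; frames still at the start point count as aligned. Any
label supported by fewer than 5 frames within its step is withdrawn from
the whole step, an outlier guard evaluated per step. Non-aligned frames of
straight steps stay unlabeled and contribute to no feature.

## Features

The 19-angle registry holds 16 limb projection angles — humerus
(shoulder→elbow), forearm (elbow→wrist), thigh (hip→knee), shin
(knee→ankle), left and right, projected on the frontal (XY) and lateral
(YZ) planes — plus fore-bent FB and lateral-bent LB from the spine-mid→
spine-shoulder vector and neck-flexion NF from spine-shoulder→neck. Limb
angles are measured from the *downward* vertical (a hanging limb reads 0),
positive toward +x in XY and toward the camera in YZ; trunk angles are
measured from the upward vertical with the same signs. A zero-length
projection yields a missing value for that frame.

Angle series are smoothed with lowess (fraction 0.3, one robustness
iteration) independently per contiguous step run, so smoothing never
bridges discarded frames; smoothed values are pooled across runs per frame
type and summarized by mean and sample standard deviation (n−1). The n−1
convention is a documented choice; at these series lengths the difference
from n is far below between-subject variability. Feature slots of an absent
frame type are missing, marked as NaN and skipped downstream. Spin steps
contribute no angles, only their count, pooled over a subject's recordings.

## Classifier

Class balancing assigns each instance weight (N/Kn_c) so every class totals
N/K. Discretization is Fayyad–Irani recursive entropy minimization with the
MDL acceptance rule, computed on instance weights (weighted class counts
replace integer counts in every entropy and in the log₂(N−1) penalty). CFS
scores subsets by k·r̄_cf / √(k + k(k−1)·r̄_ff) with symmetric uncertainty
on the discretized codes; the search is forward best-first stopping after 5
non-improving expansions, with an exhaustive mode for ≤ 15 features used as
the optimality oracle in tests. The classifier is a naive-star Bayes model:
uniform priors after balancing, and per-feature conditional tables with
Laplace smoothing α = 0.5 — the unique smoothing consistent with the
published worked examples of this estimator at class weight 10 (e.g.
(0 + 0.5)/11 = 0.045, (7·10/11 + 0.5)/11 = 0.624,
(5·1.25 + 0.5)/11.5 = 0.587). Missing values are excluded from counts (mass
renormalized over non-missing weight), excluded pairwise from symmetric
uncertainty, and skipped as factors at prediction; argmax ties break toward
the lower stage label.

Cross-validation is repeated stratified 10-fold: folds are stratified by
class because with unequal groups (e.g. 8/11/11) unstratified folds can
lose a class entirely; discretization, selection, balancing and fitting
happen inside each training fold only, the leak-free protocol. Reported
accuracy pools all folds of all runs, and the quoted spread is the fold-
level standard deviation. A label-permutation control drives accuracy to
chance, confirming no leakage. Alternative classifiers (1-NN, decision
tree, SVM, multilayer perceptron) are exposed through thin scikit-learn
adapters behind the same harness for comparison experiments; they are not
part of the modeled method.

## Synthetic gait generator

The generator emulates the clinical protocol: ~5 m corridor, eight passes
(four round trips), seven turns, ≤ 30 fps. Its kinematic model:

* **Feet** are world-anchored. The stance ankle is stationary within a
  step; the swing ankle transfers linearly from its previous plant to the
  next, routed through a via-point in its own lateral lane beside the
  stance ankle (ankles pass close mid-swing) with a sinusoidal lift
  proportional to the knee-flexion amplitude. Plants advance one step
  length per step, so the inter-feet distance has exactly one prominent
  local maximum per step, at the strike, and "exactly one foot moved" holds
  for every step. A purely pelvis-relative sinusoidal leg model cannot
  satisfy that validity rule, which is why plants are anchored.
* **Pelvis** moves piecewise-linearly one step length per step along the
  step heading, which makes every frame exactly aligned with the step
  displacement.
* **Legs** close the chain with a two-link inverse-kinematics knee bending
  toward the heading; segment lengths are exactly constant.
* **Trunk and arms** swing as deterministic sinusoids: humerus sagittal
  amplitude per side, forearm hang angle, constant trunk flexion, and
  lateral oscillations whose amplitudes are sd·√2 so the *series standard
  deviation equals the named sd parameter* — this keeps the zero-noise
  closed loop exact and bit-deterministic under a fixed seed.
* **Headings**: within toward-camera passes every third step deviates
  ±0.15 rad (slightly displaced steps, as at turn onset); turns consist of
  `spin_step_count` short (0.35 m) steps whose line offsets are confined to
  [0.25, π−0.25] rad so the > 0.2 rad spin criterion always fires, with
  half-step lead-in/out padding so the first and last strikes are interior
  maxima.
* **Artifacts**: away-pass frames are emitted with left/right joint labels
  swapped (the "impossible skeleton" the tracker produces when fitting a
  receding subject as if facing the camera); inferred flags arrive in
  bursts (≤ 5 frames) at a requested marginal rate with inflated positional
  noise; optional isotropic jitter models sensor noise.

Stage templates encode the clinical ordering — advancing stage shortens the
step (0.65/0.50/0.35 m), reduces knee excursion and arm swing (left side
more affected), increases trunk flexion (0.05/0.15/0.28 rad), lateral sway,
lateral arm movement and the turning step count (3/4/7 per turn) — plus a
healthy-control template. Between-subject spreads are modest Gaussian
perturbations. These magnitudes are package conventions chosen to be
physiologically plausible, not published measurements.

What the closed loop shows: on noiseless walks the pipeline recovers step
boundaries, categories, frame labels and spin counts *exactly*, and angular
features match their generating parameters within 0.02 rad; a 30-subject
cohort at default noise is staged with ≥ 90% repeated-CV accuracy. What it
does not show: performance on real tracker output, whose artifacts
(depth-dependent noise, partial occlusion, soft-tissue motion) are far
richer than the emulation, and any clinical validity of the stage labels.
One consequence of the mirror artifact is reproduced faithfully: the first
away-pass step after a turn can fail the one-foot-moved test because the
ankle labels swap mid-span; such steps are away-facing and are removed by
final cleaning regardless.

## Problem sizes

The default experiments use 10 subjects per stage, eight 5 m passes per
subject (~2,000–4,000 frames each), and 5 repeats of 10-fold CV in the
acceptance script (the library default is 100 repeats). The full test suite
runs in about a minute; the acceptance script in about half a minute.

## Known limitations

* The two-camera overlap merge of the clinical setup is not modeled; each
  recording is processed independently and subject features are pooled
  across recordings.
* Discretizing inside small training folds can yield no accepted cuts for
  weakly informative features; such features fall out of the model (single
  bin), which is the intended MDL behavior but makes very small cohorts
  fragile.
* The generator's slight-step placement and turn geometry are deterministic
  patterns, not a behavioral model of veering.
* Classic spatiotemporal parameters (step length, velocity, cadence) are
  not classifier inputs; they can be derived from ground truth for
  diagnostics only.
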