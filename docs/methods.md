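# Methods

## Problem and scope

`skelpose` classifies single frames of 3D skeletal-tracking data into
four postures relevant to safety monitoring of people living alone:
standing (1), sitting (2), lying down (3), and "dangerous sitting" (4)
— a seated person whose head has dropped forward or whose trunk/head
has fallen backward, proxying fainting in a chair. The classifier is
static by design: it labels each frame independently and leaves alarm
logic (which would also weigh the subject's position relative to
furniture) to downstream components. Device drivers, depth-image
processing and the skeletal tracker itself are out of scope; the
pipeline starts from per-frame joint coordinates.

## Skeleton model and geometry

The tracker's 25-joint skeleton is reduced to 17 joints: head, C7
(shoulder-segment midpoint), left/right acromion, elbow, wrist, iliac
crest, knee, malleolus and foot, plus Hc, the midpoint of the two hip
joints. The source mapping is the anatomically direct one (head←Head,
C7←SpineShoulder, acromion←Shoulder, iliac←Hip, malleolus←Ankle, …)
and is configurable; hands, thumbs and the lower spine joints are
dropped as unreliable and uninformative for posture. We map C7 to the
device's SpineShoulder rather than Neck joint because it is defined as
the shoulder-segment midpoint; the choice only shifts the trunk/head
segment boundary by a few centimeters and is overridable in the
mapping table.

Per-camera streams are processed independently and never fused at
frame level. Each stream is roto-translated into a right-handed
room-fixed frame, Z up, origin in a room corner, via a per-camera
rigid calibration `p_room = R p_cam + t`; calibrations are validated
orthonormal with det +1 to 1e-9. All "vertical coordinate" logic reads
the Z component.

**Sentinel rule.** Tracking failures are all-or-nothing: an untracked
frame carries exactly 999.0 in every coordinate (and every derived
feature), keeping multi-camera files aligned. Sentinel frames are
absorbing — no geometry or feature operation revives one — and they
are excluded from training; at inference they are reported as
untracked, never force-classified.

## Features

Each tracked frame yields 37 features in a fixed order:

1. `Z_1, Z_C7, Z_3 … Z_16, Z_Hc` — the 17 joint heights divided by the
   subject's stature (supplied metadata in meters; a fallback
   estimator, the 97.5th percentile of head height over a calibration
   window, exists but is off by default).
2. 16 articular angles, each the angle at a shared joint between the
   two adjacent segment vectors — equivalently the arccos of their
   normalized dot product, measured in the plane the segments span —
   divided by 180° so the value lies in [0, 1]. The triplets
   (vertex; endpoints) are: μ₁/μ₂ = (C7; head, acromion L/R),
   ξ = (C7; head, Hc), τ₁ = (C7; acromion L, Hc), η₁/η₂ = (acromion;
   C7, elbow), θ₁/θ₂ = (elbow; acromion, wrist), δ₁/δ₂ = (Hc; C7,
   iliac), γ₁/γ₂ = (iliac; Hc, knee), β₁/β₂ = (knee; iliac,
   malleolus), α₁/α₂ = (malleolus; knee, foot). A 17th candidate, τ₂,
   is omitted: with the two acromions and C7 nearly collinear it is
   redundant with τ₁ (τ₂ ≈ 180° − τ₁), and it is not in the selected
   subset. The set is configurable.
3. Four absolute angles: signed pitch and roll of the trunk (C7 − Hc)
   and head (head − C7) segments, divided by 180° (range (−1, 1]).
   With z the room vertical, m the unit horizontal projection of the
   shoulder axis (acromion_R − acromion_L) and f = z × m the forward
   axis, pitch = atan2(v·f, v·z) and roll = atan2(v·m, v·z). A signed
   decomposition is essential here: dangerous sitting is defined by
   forward versus backward lean, which an unsigned inclination cannot
   separate. If the shoulder axis is nearly vertical (horizontal norm
   < 1e-6 m) the iliac-crest axis is used, then the room X axis, with
   a log record.

Numerics: angles are computed as `atan2(‖u×v‖, u·v)`, which equals the
arccos form but stays well-conditioned at 0° and 180°; the articular
angles are then invariant under any proper rigid motion of the frame
to better than 1e-9 degrees (verified over random poses and
transforms), and pitch/roll are invariant under vertical-axis
rotations and translations. Segments shorter than 1e-9 m make the
angle undefined; the whole frame is then mapped to untracked (logged),
keeping the sentinel rule all-or-nothing.

### Feature selection

Multi-class ReliefF scores each feature by the difference between its
mean separation of nearest misses (other classes, prior-weighted by
P(c)/(1 − P(class(i)))) and nearest hits (same class): per sampled
instance, k nearest hits and per-class k nearest misses under the
Manhattan metric on features scaled to [0, 1] range, weight updates
±diff/(m·k). Defaults: k = 10 neighbors, m = all rows (deterministic),
following the standard multi-class formulation. The canonical working
subset is the 10 attributes `A_pitch, A_roll, B_pitch, B_roll, ξ, μ₂,
δ₂, Z_1, Z_C7, Z_Hc`; any other subset can be configured by name.

### Dataset assembly

Frames labeled as pose transitions, and sentinel frames, are removed
before training; removal counts are logged so dataset arithmetic is
auditable. Train/test splits are always by whole subject — the
evaluation question is generalization to unseen people, and splitting
by frame would leak near-duplicate frames across the boundary.

## Classifier

A fixed-topology MLP: input = number of selected features (10),
hidden layers of 10 and 6 tanh units, output 4 softmax units giving
class probabilities (sum to 1 within 1e-12). Prediction is the argmax
with lowest-class-index tie-break. Weights initialize uniform in
[−0.5, 0.5] scaled by 1/√fan-in, biases zero, from a seeded generator.

Training pairs softmax outputs with a **sum-of-squared-errors** loss
against one-hot targets and optimizes with Levenberg-Marquardt — the
classic least-squares pairing for this optimizer. Per epoch the full
residual Jacobian (n·4 × 204 weights for the default topology) is
computed analytically via the softmax differential S = diag(p) − ppᵀ
backpropagated through the tanh layers (verified against central
finite differences to 1e-5 relative); the update solves
(JᵀJ + λI)δ = −Jᵀr. λ starts at 1e-3, shrinks ×0.1 on an accepted
(loss-reducing) step and grows ×10 otherwise, capped at 1e10 —
so the accepted-loss history is non-increasing by construction, and as
λ → ∞ the step approaches −∇/λ (scaled gradient descent). Stopping:
gradient infinity-norm < 1e-7, relative loss improvement < 1e-10,
λ saturation after progress (treated as converged), or the epoch cap.
λ saturation with no accepted step ever raises a convergence error
carrying the last weights. The epoch cap defaults to 1000; the
synthetic benchmarks converge in a few dozen accepted steps, so
benchmark protocol runs use a 60-epoch cap.

LM's Jacobian cost is O(n · weights); for much larger training sets a
cross-entropy loss minimized by L-BFGS (analytic gradient) is provided
as `loss="cross_entropy"`.

Protocol utilities mirror the study design: stratified 10-fold
cross-validation (stratified because the lying class is rare, ~14%)
followed by a full-training-set refit, and repeated simulations — n
independent initializations (seed + i) trained on the full training
set and scored on the fixed test set, with individual failures
recorded rather than fatal. Everything is reproducible from one master
seed.

## Evaluation

Confusion matrices are oriented rows = predicted, columns = actual.
Per class, the one-vs-rest reduction gives TP/TN/FP/FN and accuracy,
sensitivity (= recall), specificity, precision and F-score; a zero
denominator defines the metric as 0 (logged per occurrence).
`total_accuracy` is the overall fraction correct (trace/total);
`mean_class_accuracy` (the mean of the four one-vs-rest accuracies) is
reported alongside because the two are often conflated and differ
whenever errors concentrate in particular classes.

ROC curves are one-vs-rest over each class's probability column, with
thresholds at every distinct score (exact curve, endpoints pinned at
(0,0) and (1,1)) and trapezoidal AUC — numerically identical to the
Mann–Whitney U statistic over score pairs, which the tests use as an
independent oracle. The mean ROC over repeated simulations is the
pointwise mean true-positive rate on a fixed false-positive-rate grid
(0 to 1, step 0.001); duplicate-FPR vertices collapse to their best
TPR before interpolation. AUC is stored in [0, 1] and displayed ×100.
Per-simulation metric distributions can be checked for normality with
the Shapiro–Wilk test (3 ≤ n ≤ 5000, non-constant input required)
before summarizing as mean ± SD.

## Synthetic data generator

No recordings are publicly available for this task, so the generator
produces streams with the statistical structure the pipeline assumes:

- **Anthropometry**: heights uniform on 1.55–1.90 m (the cohort range
  of the motivating protocol); segment lengths as fixed fractions of
  stature drawn from standard anthropometric tables (hip 0.53 h, C7
  0.818 h, head joint 0.95 h, biacromial half-width 0.129 h, …). The
  vertical chain ratios sum to the head-joint height within 5%.
- **Pose templates**: deterministic 17-joint skeletons parameterized
  by trunk/head pitch and roll, room location and heading. Standing:
  upright chain, arms hanging. Seated (classes 2 and 4): pelvis at
  0.30 h, thighs horizontal, shanks vertical (knee ≈ 90°). Lying:
  supine, trunk pitch ≈ 90°, all joints below 0.2 h. Dangerous
  sitting samples one of two signatures: head pitched forward ≥ 30°
  (slumped) or trunk pitched backward ≤ −20° (fallen back). Jitter
  ranges are uniform per frame; in **hard** mode the class 4 forward
  head pitch extends down to 15° and class 2 head jitter up to ±20°,
  deliberately overlapping the two seated classes, and joint noise
  rises from σ = 0.01 m to 0.05 m. Template coordinates and jitter
  ranges are invented parameters (there is no kinematic ground truth
  to copy), chosen so the noiseless classes are separable in the 10
  selected features; all are configurable.
- **Sessions**: scripted (pose, duration, location, heading) entries
  at a chosen frame rate (10 Hz default for benchmarks; the tracker's
  native 30 Hz is supported); pose changes are bridged by linear
  joint interpolation labeled as transitions — only their existence
  and removability matter, since real transitions were hand-labeled
  and removed. Occlusion/dropout converts whole frames to sentinel
  (matching the all-or-nothing sentinel rule), labeled untracked.
- **Benchmark**: 12 subjects by default, 10 train / 2 test (chosen by
  seeded permutation), 500 frames per subject allocated to classes by
  largest-remainder at the mix (0.241, 0.388, 0.144, 0.227) — the
  class shares of the motivating study's database — then run through
  the full feature pipeline and subject-wise split.

What passing on synthetic data does *not* show: robustness to real
tracker artifacts (correlated joint errors, partial-body occlusion,
identity switches), to subjects' idiosyncratic interpretations of a
pose, or to furniture interaction. The generator's per-frame
independent jitter also makes frames easier than real correlated
noise; synthetic accuracies are therefore upper bounds and the hard
benchmark is designed to reproduce the *qualitative* error structure
(seated-class confusion, standing/lying near-perfect), not any
particular accuracy value.

## Problem sizes used by the shipped protocols

Benchmark runs in the test-suite and acceptance script use 12 subjects
× 500 frames, 10 repeated simulations, and the 60-epoch LM cap; these
sizes give stable means (SD of total accuracy < 0.01) while keeping a
full run around a minute on one CPU. The cross-validation helper
defaults to k = 10.

## Known limitations

- Single-person scenes only; no frame-level fusion across cameras.
- Height must be supplied (or estimated from a standing calibration
  window); errors in it scale the Z features directly.
- LM training is impractical beyond a few tens of thousands of frames
  × hundreds of weights; use the cross-entropy/L-BFGS path there.
- The generator's transitions are linear interpolations and its noise
  is i.i.d. Gaussian; neither mimics real tracker failure modes.
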