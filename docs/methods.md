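# Methods

## The assessment and the staging problem

The package models an instrumented, modified Timed-Up-and-Go (TUG) test for
people with Parkinson's disease: 30 s of quiet bipedal stance, an auditory
go stimulus, a 3 m walk to a chair, turning and sitting down, quiet sitting,
standing up, and a 3 m walk back.  A single six-axis IMU (3-axis
accelerometer, 3-axis gyroscope, 100 Hz) worn at L4–L5 records the whole
test.  The target is the subject's Hoehn–Yahr (HY) stage, restricted to the
ambulatory stages I–III.

The pipeline has two stages:

1. **Stage 1 — semantic segmentation + biomechanics.**  A 1D U-Net labels
   every timestamp with one of six activity categories (balance, walk,
   turn-and-sit, sit, get-up, noise).  From the detected phase intervals,
   eleven biomechanical variables are computed: postural sway ranges and
   swept area (MLDisp, APDisp, DispA), gait COM displacement ranges
   (VRange, MLRange), chair-transfer peak powers and jerk ranges (PTurnSit,
   PStand, JerkSit, JerkStand), and the timing variables (TTime, RTime).
2. **Stage 2 — mixed-input staging network.**  A three-branch network maps
   each 64-sample window of the test to a continuous severity score in
   [0, 1] by regression (MSE loss), discretized at 0.33/0.66 into stages
   I/II/III.  Branch 1 consumes the raw normalized window (1D convolutions
   → LSTM); branch 2 a log-magnitude STFT spectrogram of the six channels
   concatenated into one 384-sample sequence (frame 20, step 2 → 183×11
   image; 2D convolutions); branch 3 the min-max-scaled biomechanical
   vector (dense layers).  A subject's stage is the discretized mean of
   their window scores.

## Signal conditioning

* Linear interpolation onto a uniform 100 Hz grid spanning
  t = 0 … (N−1)/rate inclusive, preserving endpoints.
* 4th-order zero-lag Butterworth low-pass at 20 Hz (forward–backward, so
  the effective magnitude response is the squared design response).
* Per-recording, per-channel min–max normalization to [−1, 1]; constant
  channels map to the midpoint.  Normalization statistics are deliberately
  fit per recording, never across subjects, to avoid leaking cohort
  statistics into held-out data; the consequence (documented limitation) is
  that absolute amplitude information reaches the networks only through
  within-recording contrasts.
* Windowing: 64 timestamps × 6 channels; stride 1 (63-sample overlap) for
  segmentation inference, stride 8 for segmentation training (a desk-scale
  subsample), stride 32 (50% overlap) for classification.

Biomechanical features are always computed from the *physical-unit*
filtered signals, not the normalized ones: the clinical variables carry
units (mm, W, s) that normalization would destroy.

## Center-of-mass kinematics

COM displacement is estimated by trapezoidal integration of trunk
acceleration with drift control after each integration: linear detrending
followed by a 4th-order zero-lag Butterworth high-pass at 0.2 Hz.  The
high-pass uses Gustafsson's initial-condition method rather than scipy's
default odd-reflection padding: at a 0.2 Hz cutoff the default padding
leaves multi-second edge transients that dominate the displacement range of
a 3–4 s walk segment (errors of 2–4×); with Gustafsson initial conditions
the double-integration error on analytic sinusoids is below 7% for segments
down to 2 s.

Swept area (DispA) is the centroid-anchored triangle-fan area of the ML–AP
trajectory: the sum over consecutive sample pairs of the triangle spanned
with the trajectory centroid.  It converges to the enclosed area for convex
loops (πr² for a circle) and vanishes for collinear trajectories.

Transfer power follows the body-fixed-sensor convention: vertical velocity
from a single integration re-zeroed at the interval start (linear endpoint
correction, since transfers start and end at rest), instantaneous power
p(t) = m·(a_v(t)+g)·v(t), and the reported value is max p(t) within the
interval, floored at zero.  Jerk is the central-difference derivative of
the acceleration magnitude; its max−min within the interval is reported.

Timing: RTime = onset of the first walk after the stimulus − stimulus
time; TTime = end of the final walk − stimulus time.  A strictly negative
RTime raises an error by default; the evaluation protocol enables a
documented clip-to-zero option because stage-1 boundary noise can place a
predicted onset a few samples before the stimulus when the true reaction
delay is short.

## The synthetic cohort generator

No public recordings exist for this assessment, so the generator is a
first-class module that emulates the *statistical structure* the pipeline
consumes — not gait dynamics.  Stage-conditional parameters (total time,
reaction time, sway and gait displacement ranges, transfer powers, body
mass) are drawn from normal distributions with the reference cohort's per-stage
means and SDs, truncated below at 0.1× the mean; draws whose active time
(TTime − RTime) cannot host five phases of at least 0.7 s are redrawn.
Times are quantized to the sample grid so ground-truth boundaries recover
them exactly.

Synthesis inverts the feature definitions:

* **Balance sway**: band-limited (0.3–2 Hz) noise synthesized in the
  displacement domain, scaled to the drawn ML/AP ranges, differentiated
  twice; a cosine taper ends the sway smoothly at the walk onset.
* **Gait**: sinusoidal vertical COM displacement at the cadence frequency
  (default 2.0 Hz) with peak-to-peak amplitude equal to the drawn VRange,
  and an ML component at the stride frequency (cadence/2) for MLRange.
  Amplitudes are calibrated against the package's own double-integration
  operator so the drawn ranges are recovered unbiasedly despite the
  short-segment filter response.
* **Transfers**: half-sine vertical velocity pulses whose amplitude is
  fixed-point–scaled so the Lindemann-style peak power matches the drawn
  PTurnSit/PStand.
* **Tremor**: a sinusoid at a drawn 4–6 Hz frequency added to all
  accelerometer channels with stage-increasing amplitude (means 0.05,
  0.15, 0.30 m/s² for HY I/II/III — invented constants; tremor
  characteristics are not part of the reference statistics, and rest tremor
  increasing with stage is the motivating clinical observation).
* **Phase signatures**: the turn carries a 1.5 rad/s yaw-rate half-sine,
  standing up a 1.0 rad/s pitch-rate half-sine, and quiet sitting a
  0.08 rad/s band-limited pitch wobble.  These invented constants give
  every phase a signature resolvable within a 0.64 s window; without them
  quiet sitting is indistinguishable from quiet stance at window scale.
* **Noise**: white accelerometer noise (SD 0.005 m/s²) and gyroscope noise
  (SD 0.01 rad/s).  The accelerometer value is chosen so that the
  double-integrated noise floor (~0.7 mm displacement range over 30 s)
  stays well below the smallest stage-I sway targets.

Gravity is excluded from the stored vertical channel by default (a flag
adds +g) — the transfer-power formula adds g explicitly, and the choice
simplifies double integration without affecting any filtered feature.

The phase order is fixed at balance → walk → turn-and-sit → sit → get-up →
walk; the post-reaction span is carved with jittered nominal fractions
(0.28/0.22/0.14/0.12/0.24).  The BALANCE ground-truth interval extends
through the reaction gap (the subject is still standing), so the stimulus
sample is stored separately from the interval boundaries.

A single `difficulty` multiplier scales every between-stage parameter gap
around the grand mean (1.0 = reference gaps), so separability can be
changed explicitly rather than implicitly.

**What the generator does not emulate** — and hence what passing tests do
not show about clinical data: realistic gait harmonics and asymmetry,
freezing episodes, non-scripted movement, sensor mounting variation,
drift/saturation artifacts, and any within-stage correlation structure
beyond the marginal distributions.  Synthetic separability between stages
is governed by the reference between-group differences plus the invented
tremor scaling; real cohorts are harder.

## Networks and training

Both networks are trained with Adam at learning rate 0.001 (the reference
setting) on a small in-package reverse-mode autodiff stack over numpy
(float32), written for exactly the operations these models need; every
backward rule is verified against central finite differences in the test
suite.

**Segmenter** (1D U-Net): four encoder blocks (two same-padded kernel-3
convolutions + channel normalization, 2× max pooling), a bridge, four
mirrored decoder blocks (2× nearest-neighbour upsampling + skip
concatenation), and a kernel-1 output convolution to six per-timestamp
logits; categorical cross-entropy.  The reference design fixes this
topology but not the filter counts; the package default is base 8 doubling
to 128 at the bridge (configurable).  Channel normalization (layer
normalization over the channel axis) is used instead of batch
normalization: it has no train/eval mode split and keeps single-window
inference deterministic.  Whole-recording segmentation labels each sample
from the stride-1 window whose center is nearest, merges label runs
shorter than 0.5 s into the longer neighbour, and reports change points as
boundaries.  Majority voting (ties → lowest class code) gives window-level
labels.

**Classifier**: time branch = conv 32/64/64 (kernel 3, each followed by 2×
max pooling) → LSTM 64 → LSTM 32 → dense 64/32/16; frequency branch = 2D
conv 8/16/32 (3×3, 2×2 pooling; the first convolution strides by 2 along
the redundant frame axis) on the 183×11 spectrogram → flatten;
biomechanics branch = dense 32/16; top = dense 128 → 64 → linear 1.  The
reference design fixes the top model, the output encoding, the
cut-offs, MSE/Adam, and batch 32; branch sizes are package defaults.  The
STFT treats the 6×64 concatenation as one sequence including the
cross-channel seam frames (not masked), with a periodic Hann window and a
log floor of 1e-6.  Stage encodings 0.0/0.5/1.0 are midpoint-consistent
with the 0.33/0.66 cut-offs; a score exactly at a cut-off takes the higher
stage.

**Regularization.**  Two training-time measures keep the three branches
honest; both are off at inference:

* *Modality dropout* (probability 0.3 per training sample of zeroing one
  randomly chosen input branch).  The biomechanical vector is constant
  across a subject's windows and — on clean synthetic data — can be
  memorized within two epochs, zeroing the loss before the signal branches
  receive any gradient.  The trained model then carries no signal-branch
  information (zero-input sensitivity deltas of 0), generalizes only as
  far as the feature table allows, and degrades catastrophically when one
  input is missing.  With modality dropout every branch must be
  independently predictive, which also makes the degraded-input fallback
  meaningful.
* *Biomechanical input jitter* (Gaussian, SD 0.1 on the 0–1 scaled
  features, clipped).  Without it the branch is perfectly reliable during
  training (memorized) but only imperfectly reliable on new subjects, so
  the fusion over-weights it; the jitter aligns its training-time
  reliability with reality.

Training history records the per-epoch MSE, the accuracy over the
(corrupted) training batches, and — for the final fit — a clean epoch-end
evaluation over the training set, which is the quantity "training window
accuracy" refers to when regularization corrupts the batches.

## Evaluation protocol

Hold-out: five subjects per stage, drawn once per run, excluded from all
training, validation, scaler fitting, SMOTE and augmentation.  The
remaining subjects run a stratified, subject-disjoint three-fold
cross-validation (per-class fold counts differ by ≤1; class remainders go
to the smallest folds so fold sizes balance).

Class balancing happens strictly inside training folds.  SMOTE
(convex combinations of same-class nearest neighbours, k = min(5,
class−1)) balances the scaled biomechanical table to the majority count;
each synthetic row is paired with a copy of its base subject's windows, so
balancing acts at subject level and the signal branches see the rotation
augmentation (original + 90° + 180° about the vertical axis, applied to
the AP/ML accelerometer and pitch/roll gyroscope pairs).  Feature min–max
scaling is fit on the training subjects of each fold.

The stage-1 segmenter is trained once per protocol run on the non-held-out
subjects (with a 20% subject-level validation split for its history) and
reused across CV folds: its task — phase labelling — does not touch the
stage labels the CV protects, and the hold-out subjects never contribute
windows to it.

Metrics: confusion matrix (rows = true), subject-level accuracy, macro F1,
and the G-mean generalized to three classes as the geometric mean of the
per-class recalls.  Classes absent from the truth are excluded with a
warning.  The zero-input sensitivity analysis re-evaluates the trained
model on the same subjects with one input branch forced to zeros and
reports the accuracy delta per branch.

**Degraded-input fallback.**  If stage 1 fails to produce the phases a
feature needs for a *test* subject (a segmentation failure, not a reason to
crash an evaluation), the subject's biomechanical input is fed as zeros and
the prediction runs on the signal branches alone — the same semantics as
the sensitivity analysis; a warning is emitted.  Training subjects with
failed feature extraction are dropped from the fold with a warning.

## Problem sizes and numerical choices

Desk-scale defaults (all configurable): segmenter training on stride-8
windows for 3 epochs, batch 128; classification windows at stride 32;
classifier training for 6 epochs per CV fold and 10 epochs for the final
fit, batch 32; segmentation inference at stride 1.  The acceptance script
runs the default 87-subject cohort (21/30/36) end to end and 100 stage-I
trials for the timing-recovery checks.  One master seed expands through
numpy's SeedSequence into all module seeds; equal seeds give byte-identical
reports (training, splits, SMOTE, augmentation and initialization all draw
from derived generators).

Degenerate inputs: constant channels normalize to the range midpoint;
constant acceleration yields bounded COM displacement (drift removal);
all-zero spectrogram windows sit at the log floor; single-class segmenter
training warns and fits the degenerate optimum; SMOTE refuses singleton
classes; majority-vote ties take the lowest class code.

## Known limitations

* The synthetic cohort's stage separability is partly driven by the
  invented tremor-amplitude scaling; accuracy figures on synthetic data are
  upper bounds relative to clinical data.
* Half HY stages (1.5/2.5) and stages IV–V are out of scope.
* The segmenter confuses quiet sitting with quiet stance when the sitting
  signature is weak; the affected features (none use the SIT interval) and
  timing variables are insensitive to this, which the boundary-recovery
  tests exploit.
* Window-level normalization removes absolute amplitude; a model
  transferred to recordings normalized differently would need re-fitting.
* Per-recording normalization also corrupts the one cleanly
  stage-separated synthetic cue (tremor amplitude), and body mass — the
  factor that would undo it — is deliberately excluded from the model
  inputs.  The staging accuracy on a given cohort realization is therefore
  bounded by the information surviving in the scaled feature table and the
  normalized spectra: hold-out accuracy varies between roughly 67% and
  100% across master seeds, with the hard draws identifiable as such by a
  linear classifier on the feature table alone.
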