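# tugstage

Hoehn–Yahr staging of early Parkinson's disease (stages I–III) from a
single trunk-worn IMU recorded during a modified Timed-Up-and-Go test, with
a two-stage deep pipeline and a calibrated synthetic cohort generator.

## Who this is for

Movement-analysis and digital-biomarker researchers who want a fully
self-contained, reproducible implementation of functional-test staging:
semantic segmentation of test phases from raw six-axis signals, clinically
interpretable biomechanical variables, and a mixed-input neural classifier
— all runnable end to end without access to clinical recordings.

## The method

A subject performs: 30 s quiet stance → auditory go stimulus → 3 m walk →
turn + sit → quiet sit → stand up → 3 m walk back, with a 100 Hz
accelerometer + gyroscope at L4–L5.

**Stage 1.** Signals are resampled to 100 Hz, low-pass filtered (4th-order
zero-lag Butterworth, 20 Hz) and min–max normalized to [−1, 1].  A 1D
U-Net over sliding 64×6 windows (stride 1, majority vote, change-point
extraction) labels each timestamp as balance / walk / turn-and-sit / sit /
get-up / noise.  From the phase intervals, eleven biomechanical variables
are computed from the physical-unit signals — postural sway ranges and
swept area (MLDisp, APDisp, DispA), gait center-of-mass displacement
ranges by double integration (VRange, MLRange), chair-transfer peak powers
m·(a_v+g)·v and jerk ranges (PTurnSit, PStand, JerkSit, JerkStand), and
timing (TTime, RTime).

**Stage 2.** A three-branch network scores each 64-sample window (50%
overlap) on a continuous severity scale in [0, 1] (MSE regression, Adam,
batch 32): raw windows (1D CNN → LSTM), a log-magnitude STFT spectrogram
of the six channels concatenated to one 384-sample sequence (frame 20,
step 2 → 183×11 image, 2D CNN), and the scaled biomechanical vector
(dense).  Scores discretize at 0.33/0.66 into stages I/II/III; a subject's
stage is the discretized mean of their window scores.

**Evaluation.** Five subjects per stage are held out; the rest run a
stratified subject-disjoint three-fold cross-validation with SMOTE
balancing of the biomechanical table and 90°/180° axis-rotation
augmentation of the windows, strictly inside training folds.  Metrics:
confusion matrix, accuracy, macro-F1, G-mean, and a zero-input sensitivity
analysis per branch.  Simplified baselines (`cnn_lstm`, `cnn_biomech`) use
subsets of the inputs.

Because the underlying clinical recordings are not public, the package
ships a synthetic cohort generator calibrated to reference per-stage
parameter distributions (timing, sway, gait amplitude, transfer power,
body mass, and a stage-increasing 4–6 Hz tremor), with exact ground-truth
phase boundaries.  See `docs/methods.md` for the signal model and its
limitations.

## Worked example

```python
from tugstage import CohortSpec, TwoStageModel
from tugstage.evaluation import ProtocolConfig

spec = CohortSpec(counts=(7, 7, 7), seed=42)   # small synthetic cohort
model = TwoStageModel.from_synthetic(spec, ProtocolConfig(per_class_holdout=2))
results = model.fit(seed=1)
print(results.summary())
score, stage = results.predict(model.cohort[0][0])
print(f"subject {model.cohort[0][0].subject_id}: score={score:.3f} -> stage {stage}")
```

prints (abridged; exact numbers for these seeds):

```
Two-stage Hoehn-Yahr staging pipeline
======================================================
Stage 1 (1D U-Net segmenter): val per-timestamp accuracy 90.7% after 3 epochs

Model: two_stage
  3-fold CV subject accuracy: 86.67% (folds: 100.0, 100.0, 60.0)
  Hold-out: accuracy 100.0%  macro-F1 100.0%  G-mean 1.00
  Confusion matrix (rows = true I/II/III):
      2    0    0
      0    2    0
      0    0    2
...
subject S001: score=0.005 -> stage I
```

The segmenter line is stage 1's per-timestamp validation accuracy; the CV
line is subject-level cross-validation accuracy on the training subjects;
the hold-out block scores the untouched test subjects; the final line runs
one recording end to end (segmentation → features → staging score, where
scores below 0.33 mean stage I).

The same flows are scriptable from a shell:

```bash
tugstage generate --counts 21 30 36 --seed 7 --out cohort/
tugstage train --out artifacts/
tugstage predict --in cohort/S001.csv --artifacts artifacts/
```

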