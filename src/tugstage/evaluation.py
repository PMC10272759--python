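"""Training, validation and testing protocol for the staging models.

The protocol mirrors a clinical ML evaluation with a small imbalanced
cohort: a fixed hold-out test set (five subjects per stage) never touches
training; the remaining subjects run a subject-disjoint stratified
three-fold cross-validation.  Class imbalance is addressed inside training
folds only, by SMOTE over the biomechanical feature vectors (synthetic rows
are attached to a copy of the base subject's windows, balancing classes at
subject level) and by axis-rotation augmentation (90 and 180 degrees about
the vertical axis) of the signal windows.  Metrics: confusion matrix,
subject-level accuracy, macro F1 and the G-mean (geometric mean of the
per-class recalls, generalized to three classes).  A zero-input sensitivity
analysis measures each branch's contribution by re-evaluating the trained
model with one input forced to zeros.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neighbors import NearestNeighbors

from .biomech import FEATURE_NAMES, FeatureScaler, extract_features
from .classifier import (
    ClassifierConfig,
    StagingModel,
    build_baseline,
    build_classifier,
    discretize,
    encode_stage,
    train_classifier,
    windows_to_spectrograms,
)
from .nn.autograd import DTYPE
from .preprocess import (
    CLASSIFICATION_STRIDE,
    WindowSet,
    make_windows,
    preprocess_recording,
)
from .recording import CHANNELS
from .segmenter import (
    SegmenterConfig,
    build_segmenter,
    segment_recording,
    train_segmenter,
)

STAGES = ("I", "II", "III")


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def _stages_of(cohort) -> np.ndarray:
    return np.array([rec.stage for rec, _ in cohort], dtype=object)


def holdout_split(cohort, per_class: int = 5, seed: int = 0):
    """Reserve ``per_class`` subjects per stage as a test set, rest as train.

    The split is by subject, so no windows of a test subject can appear in
    training.  Raises if a class has too few subjects to leave at least one
    in training.
    """
    stages = _stages_of(cohort)
    rng = np.random.default_rng(seed)
    test_idx = []
    for stage in STAGES:
        idx = np.flatnonzero(stages == stage)
        if per_class > 0 and len(idx) <= per_class:
            raise ValueError(
                f"stage {stage} has only {len(idx)} subjects; cannot hold out "
                f"{per_class}")
        test_idx.extend(rng.choice(idx, size=per_class, replace=False))
    test_set = set(int(i) for i in test_idx)
    train = [cohort[i] for i in range(len(cohort)) if i not in test_set]
    test = [cohort[i] for i in sorted(test_set)]
    return train, test


def stratified_threefold(subjects, seed: int = 0, n_folds: int = 3):
    """Partition subjects into stratified, subject-disjoint folds.

    Per-class counts across folds differ by at most one (round-robin deal of
    a shuffled class).  ``subjects`` is any sequence whose items expose a
    stage via item[0].stage (cohort tuples) or item.stage.
    """
    def stage_of(item):
        return item[0].stage if isinstance(item, tuple) else item.stage

    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(n_folds)]
    for stage in STAGES:
        idx = [i for i, s in enumerate(subjects) if stage_of(s) == stage]
        if 0 < len(idx) < n_folds:
            raise ValueError(
                f"stage {stage} has {len(idx)} subjects; need >= {n_folds} "
                f"for {n_folds}-fold stratification")
        idx = rng.permutation(idx)
        base, extra = divmod(len(idx), n_folds)
        # class remainders go to the currently smallest folds, keeping both
        # the per-class counts (diff <= 1) and the fold sizes balanced
        order = sorted(range(n_folds), key=lambda j: (len(folds[j]), j))
        take = 0
        for rank, j in enumerate(order):
            n = base + (1 if rank < extra else 0)
            folds[j].extend(int(i) for i in idx[take : take + n])
            take += n
    return [sorted(f) for f in folds]


# ---------------------------------------------------------------------------
# Balancing and augmentation
# ---------------------------------------------------------------------------

def smote_balance(features: np.ndarray, labels: np.ndarray, seed: int = 0,
                  k_neighbors: int = 5, return_base: bool = False):
    """SMOTE oversampling to the majority-class count.

    Synthetic rows are convex combinations x_i + u*(x_j - x_i) of a sample
    and one of its k same-class nearest neighbours (k adapts to
    min(k_neighbors, class count - 1)); originals are preserved and come
    first.  With ``return_base`` also returns, for each output row, the
    index of the originating input row (originals map to themselves).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    n_major = counts.max()
    rng = np.random.default_rng(seed)
    out_X = [X]
    out_y = [y]
    base = [np.arange(X.shape[0])]
    for cls, count in zip(classes, counts):
        need = n_major - count
        if need == 0:
            continue
        if count < 2:
            raise ValueError(
                f"class {cls!r} has a single sample; SMOTE needs at least 2")
        idx = np.flatnonzero(y == cls)
        k = min(k_neighbors, count - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X[idx])
        _, neigh = nn.kneighbors(X[idx])  # column 0 is the point itself
        picks = rng.integers(0, count, size=need)
        which = rng.integers(1, k + 1, size=need)
        u = rng.uniform(0.0, 1.0, size=need)[:, None]
        xi = X[idx[picks]]
        xj = X[idx[neigh[picks, which]]]
        out_X.append(xi + u * (xj - xi))
        out_y.append(np.full(need, cls, dtype=object))
        base.append(idx[picks])
    Xb = np.concatenate(out_X)
    yb = np.concatenate(out_y)
    if return_base:
        return Xb, yb, np.concatenate(base)
    return Xb, yb


# rotation about the vertical axis permutes/negates the horizontal pairs:
# accelerometer (AP, ML) and gyroscope (pitch, roll); yaw and V are invariant
_AP, _ML = CHANNELS.index("acc_ap"), CHANNELS.index("acc_ml")
_PITCH, _ROLL = CHANNELS.index("gyr_pitch"), CHANNELS.index("gyr_roll")


def rotate_windows(windows: np.ndarray, degrees: int) -> np.ndarray:
    """Rotate the sensor frame about the vertical axis by 90 or 180 degrees."""
    if degrees not in (90, 180):
        raise ValueError("only 90 and 180 degree rotations are defined")
    out = windows.copy()
    for a, b in ((_AP, _ML), (_PITCH, _ROLL)):
        if degrees == 90:
            # (x, y) -> (-y, x)
            out[..., a] = -windows[..., b]
            out[..., b] = windows[..., a]
        else:
            out[..., a] = -windows[..., a]
            out[..., b] = -windows[..., b]
    return out


def augment_rotations(window_set: WindowSet) -> WindowSet:
    """Original + 90- and 180-degree rotated copies (3x size, labels copied)."""
    rotated = [window_set.windows,
               rotate_windows(window_set.windows, 90),
               rotate_windows(window_set.windows, 180)]
    reps = 3
    return WindowSet(
        windows=np.concatenate(rotated),
        starts=np.tile(window_set.starts, reps),
        subject_ids=np.tile(window_set.subject_ids, reps),
        stride=window_set.stride,
        phase_labels=None if window_set.phase_labels is None
        else np.tile(window_set.phase_labels, (reps, 1)),
        stage_labels=None if window_set.stage_labels is None
        else np.tile(window_set.stage_labels, reps),
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(true_stages, predicted_stages) -> dict:
    """Confusion matrix (rows = true), accuracy %, macro-F1 %, G-mean.

    G-mean is the geometric mean of the per-class recalls; classes absent
    from the truth are excluded from both averages with a warning.
    """
    y_true = np.asarray(true_stages, dtype=object)
    y_pred = np.asarray(predicted_stages, dtype=object)
    if y_true.size == 0:
        raise ValueError("empty label lists")
    if y_true.shape != y_pred.shape:
        raise ValueError("true/predicted label lists differ in length")
    cm = _sk_confusion(y_true, y_pred, labels=list(STAGES))
    present = cm.sum(axis=1) > 0
    if not present.all():
        absent = [s for s, p in zip(STAGES, present) if not p]
        warnings.warn(f"classes absent from truth excluded from recall: {absent}")
    recalls = cm.diagonal()[present] / cm.sum(axis=1)[present]
    precisions = np.divide(
        cm.diagonal(), cm.sum(axis=0),
        out=np.zeros(len(STAGES)), where=cm.sum(axis=0) > 0)[present]
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(recalls + precisions > 0,
                      2 * recalls * precisions / (recalls + precisions), 0.0)
    return {
        "confusion_matrix": cm.tolist(),
        "accuracy_pct": 100.0 * cm.diagonal().sum() / cm.sum(),
        "macro_f1_pct": 100.0 * float(f1.mean()),
        "g_mean": float(np.prod(recalls) ** (1.0 / recalls.size)),
    }


# ---------------------------------------------------------------------------
# Per-subject model data
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """Everything the stage-2 classifier needs for one subject."""

    subject_id: str
    stage: str
    windows: np.ndarray        # (n, 64, 6) normalized, classification stride
    spectrograms: np.ndarray   # (n, 183, 11)
    features: np.ndarray       # (11,) raw biomech variables
    aug_windows: np.ndarray = field(repr=False, default=None)
    aug_spectrograms: np.ndarray = field(repr=False, default=None)

    def ensure_augmented(self):
        if self.aug_windows is None:
            ws = WindowSet(windows=self.windows,
                           starts=np.zeros(len(self.windows), dtype=int),
                           subject_ids=np.full(len(self.windows), self.subject_id,
                                               dtype=object),
                           stride=CLASSIFICATION_STRIDE)
            aug = augment_rotations(ws)
            self.aug_windows = np.asarray(aug.windows, dtype=DTYPE)
            self.aug_spectrograms = windows_to_spectrograms(aug.windows)
        return self


def build_subject_data(pre, segmentation, clip_negative_rtime: bool = True,
                       missing_policy: str = "raise") -> SubjectData:
    """Assemble classifier inputs from a preprocessed + segmented recording.

    ``missing_policy`` governs feature-extraction failures (a phase absent
    from the segmentation): ``"raise"`` propagates; ``"zero"`` substitutes a
    zero biomechanical vector — the classifier then runs on its signal
    branches alone, mirroring the zero-input sensitivity semantics.
    """
    rec = pre.recording
    try:
        feats = extract_features(rec, segmentation,
                                 clip_negative_rtime=clip_negative_rtime)
        vector = feats.as_vector()
    except ValueError:
        if missing_policy != "zero":
            raise
        warnings.warn(f"{rec.subject_id}: feature extraction failed; "
                      f"feeding a zero biomechanical vector")
        vector = np.zeros(len(FEATURE_NAMES))
    ws = make_windows(pre.normalized, stride=CLASSIFICATION_STRIDE,
                      subject_id=rec.subject_id)
    windows = np.asarray(ws.windows, dtype=DTYPE)
    return SubjectData(
        subject_id=rec.subject_id,
        stage=rec.stage,
        windows=windows,
        spectrograms=windows_to_spectrograms(windows),
        features=vector,
    )


def _training_arrays(subjects: list[SubjectData], scaler: FeatureScaler,
                     config: ClassifierConfig, seed: int, use_smote: bool = True,
                     augment: bool = True):
    """(windows, spectrograms, biomech, targets) for a training fold.

    SMOTE balances classes at subject level: each synthetic biomech row is
    paired with a copy of its base subject's (augmented) windows.
    """
    feats = np.stack([s.features for s in subjects])
    labels = np.array([s.stage for s in subjects], dtype=object)
    scaled = scaler.transform(feats)
    if use_smote and len(np.unique(labels)) > 1:
        bal_feats, bal_labels, base = smote_balance(
            scaled, labels, seed=seed, return_base=True)
    else:
        bal_feats, bal_labels, base = scaled, labels, np.arange(len(subjects))
    xs, ss, bs, ys = [], [], [], []
    for row, stage, b in zip(bal_feats, bal_labels, base):
        subj = subjects[int(b)]
        if augment:
            subj.ensure_augmented()
            w, sp = subj.aug_windows, subj.aug_spectrograms
        else:
            w, sp = subj.windows, subj.spectrograms
        xs.append(w)
        ss.append(sp)
        bs.append(np.repeat(row[None], len(w), axis=0))
        ys.append(np.full(len(w), encode_stage(stage, config), dtype=DTYPE))
    return (np.concatenate(xs), np.concatenate(ss),
            np.concatenate(bs).astype(DTYPE), np.concatenate(ys))


def _model_inputs(model: StagingModel, windows, specs, biomech):
    return {
        "two_stage": (windows, specs, biomech),
        "cnn_lstm": (windows,),
        "cnn_biomech": (windows, biomech),
    }[model.kind]


def predict_subjects(model: StagingModel, subjects: list[SubjectData],
                     scaler: FeatureScaler, config: ClassifierConfig,
                     zero_input: int | None = None):
    """(scores, stages) per subject: mean window score, discretized."""
    scores, stages = [], []
    for s in subjects:
        scaled = scaler.transform(s.features[None])[0]
        biomech = np.repeat(scaled[None], len(s.windows), axis=0).astype(DTYPE)
        inputs = _model_inputs(model, s.windows, s.spectrograms, biomech)
        sc = model.predict_scores(inputs, zero_input=zero_input)
        scores.append(float(sc.mean()))
        stages.append(discretize(scores[-1], config))
    return np.array(scores), np.array(stages, dtype=object)


def sensitivity_zero_inputs(model: StagingModel, subjects: list[SubjectData],
                            scaler: FeatureScaler,
                            config: ClassifierConfig) -> list[dict]:
    """Per-branch accuracy with that branch zeroed, and the delta vs all inputs."""
    if model.n_inputs < 2:
        raise ValueError("sensitivity analysis needs a model with >= 2 inputs")
    truth = np.array([s.stage for s in subjects], dtype=object)
    _, base_pred = predict_subjects(model, subjects, scaler, config)
    base_acc = 100.0 * float(np.mean(base_pred == truth))
    table = []
    for i, name in enumerate(model.input_names()):
        _, pred = predict_subjects(model, subjects, scaler, config, zero_input=i)
        acc = 100.0 * float(np.mean(pred == truth))
        table.append({"input": name, "accuracy_pct": acc,
                      "delta_pct": base_acc - acc})
    return table


# ---------------------------------------------------------------------------
# The full protocol
# ---------------------------------------------------------------------------

@dataclass
class ProtocolConfig:
    """Desk-scale settings for the end-to-end evaluation protocol."""

    per_class_holdout: int = 5
    segmenter: SegmenterConfig = field(
        default_factory=lambda: SegmenterConfig(epochs=3))
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seg_train_stride: int = 8
    seg_val_fraction: float = 0.2
    cv_epochs: int = 6
    final_epochs: int = 10
    models: tuple = ("two_stage",)
    use_ground_truth_segmentation: bool = False
    segmentation_stride: int = 1


@dataclass
class EvaluationReport:
    """Everything the protocol measures, serializable to JSON."""

    seed: int
    config: dict
    segmenter_history: dict
    results: dict  # per model kind

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"seed": self.seed, "config": self.config,
             "segmenter_history": self.segmenter_history,
             "results": self.results},
            indent=1, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def _derive_seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(master).generate_state(n) % (2 ** 31)]


def train_segmentation_stage(cohort, config: ProtocolConfig, seed: int):
    """Preprocess all recordings and train the stage-1 segmenter.

    The segmenter trains on the given (training) subjects only, with a
    subject-level validation split for the history.  Returns (preprocessed
    list aligned with cohort, trained model, history).
    """
    pres = [preprocess_recording(rec) for rec, _ in cohort]
    n_val = max(1, int(round(config.seg_val_fraction * len(cohort))))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    val_idx = set(int(i) for i in order[:n_val])
    sets = {"train": [], "val": []}
    for i, ((rec, gt), pre) in enumerate(zip(cohort, pres)):
        ws = make_windows(pre.normalized, stride=config.seg_train_stride,
                          subject_id=rec.subject_id,
                          sample_labels=gt.labels(pre.recording.n_samples))
        sets["val" if i in val_idx else "train"].append(ws)
    seg_cfg = SegmenterConfig(**{**config.segmenter.__dict__, "seed": seed})
    model = build_segmenter(seg_cfg)
    history = train_segmenter(
        model, WindowSet.concatenate(sets["train"]), seg_cfg,
        val_set=WindowSet.concatenate(sets["val"]))
    return pres, model, history


def _subject_data_for(cohort, pres, seg_model, config: ProtocolConfig,
                      on_error: str = "raise"):
    out = []
    for (rec, gt), pre in zip(cohort, pres):
        if config.use_ground_truth_segmentation:
            from .segmenter import PhaseSegmentation
            seg = PhaseSegmentation(intervals=gt.intervals,
                                    recording_id=rec.subject_id)
        else:
            seg = segment_recording(seg_model, pre.normalized, rec.subject_id,
                                    stride=config.segmentation_stride)
        try:
            out.append(build_subject_data(
                pre, seg,
                missing_policy="zero" if on_error == "zero_features" else "raise"))
        except ValueError as exc:
            if on_error == "drop":
                warnings.warn(
                    f"dropping training subject {rec.subject_id}: {exc}")
                continue
            raise
    return out


def run_protocol(cohort, config: ProtocolConfig | None = None,
                 seed: int = 0, artifacts: dict | None = None) -> EvaluationReport:
    """Hold-out split, stage-1 training, 3-fold CV, final fit, test metrics.

    Per requested model kind the results carry: per-fold subject- and
    window-level CV accuracies, the final training history, hold-out
    confusion matrix / accuracy / macro-F1 / G-mean, and (for multi-input
    models) the zero-input sensitivity table.

    When an ``artifacts`` dict is passed, the trained stage-1 segmenter and
    the per-model final classifiers and feature scalers are stored in it for
    later single-subject inference.
    """
    config = config or ProtocolConfig()
    seeds = _derive_seeds(seed, 6)
    train_cohort, test_cohort = holdout_split(
        cohort, per_class=config.per_class_holdout, seed=seeds[0])

    # Stage 1 trains on training subjects only: the hold-out subjects'
    # windows never reach any optimizer.
    pres_train, seg_model, seg_history = train_segmentation_stage(
        train_cohort, config, seeds[1])
    pres_test = [preprocess_recording(rec) for rec, _ in test_cohort]

    train_data = _subject_data_for(train_cohort, pres_train, seg_model, config,
                                   on_error="drop")
    test_data = _subject_data_for(test_cohort, pres_test, seg_model, config,
                                  on_error="zero_features")

    train_ids = {s.subject_id for s in train_data}
    test_ids = {s.subject_id for s in test_data}
    assert not train_ids & test_ids, "subject leakage between train and test"
    if artifacts is not None:
        artifacts["segmenter"] = seg_model
        artifacts["models"] = {}
        artifacts["scalers"] = {}

    folds = stratified_threefold(train_data, seed=seeds[2])
    results = {}
    for kind in config.models:
        clf_seed_base = seeds[3]
        cv_subject_acc, cv_window_acc = [], []
        for f, val_idx in enumerate(folds):
            val_set = set(val_idx)
            tr = [train_data[i] for i in range(len(train_data))
                  if i not in val_set]
            va = [train_data[i] for i in val_idx]
            cfg = ClassifierConfig(**{**config.classifier.__dict__,
                                      "epochs": config.cv_epochs,
                                      "seed": clf_seed_base + f})
            scaler = FeatureScaler().fit(np.stack([s.features for s in tr]))
            arrays = _training_arrays(tr, scaler, cfg, seed=clf_seed_base + f)
            model = (build_classifier(cfg) if kind == "two_stage"
                     else build_baseline(kind, cfg))
            train_classifier(
                model, _model_inputs(model, *arrays[:3]), arrays[3], cfg)
            _, pred = predict_subjects(model, va, scaler, cfg)
            truth = np.array([s.stage for s in va], dtype=object)
            cv_subject_acc.append(100.0 * float(np.mean(pred == truth)))
            # window-level accuracy on the validation fold
            w_correct = w_total = 0
            for s in va:
                scaled = scaler.transform(s.features[None])[0]
                bio = np.repeat(scaled[None], len(s.windows), axis=0)
                inputs = _model_inputs(model, s.windows, s.spectrograms,
                                       bio.astype(DTYPE))
                w_pred = discretize(model.predict_scores(inputs), cfg)
                w_correct += int(np.sum(w_pred == s.stage))
                w_total += len(w_pred)
            cv_window_acc.append(100.0 * w_correct / max(w_total, 1))

        # final model on all training subjects, evaluated on the hold-out
        cfg = ClassifierConfig(**{**config.classifier.__dict__,
                                  "epochs": config.final_epochs,
                                  "seed": seeds[4]})
        scaler = FeatureScaler().fit(np.stack([s.features for s in train_data]))
        arrays = _training_arrays(train_data, scaler, cfg, seed=seeds[4])
        model = (build_classifier(cfg) if kind == "two_stage"
                 else build_baseline(kind, cfg))
        history = train_classifier(
            model, _model_inputs(model, *arrays[:3]), arrays[3], cfg,
            eval_train_accuracy=True)
        if artifacts is not None:
            artifacts["models"][kind] = model
            artifacts["scalers"][kind] = scaler
        scores, pred = predict_subjects(model, test_data, scaler, cfg)
        truth = np.array([s.stage for s in test_data], dtype=object)
        metrics = compute_metrics(truth, pred)
        sensitivity = (sensitivity_zero_inputs(model, test_data, scaler, cfg)
                       if model.n_inputs >= 2 else [])
        results[kind] = {
            "cv_subject_accuracies_pct": cv_subject_acc,
            "cv_window_accuracies_pct": cv_window_acc,
            "cv_mean_accuracy_pct": float(np.mean(cv_subject_acc)),
            "training_history": history,
            "holdout": {
                **metrics,
                "subjects": [
                    {"subject_id": s.subject_id, "stage": s.stage,
                     "score": float(sc), "predicted": str(p)}
                    for s, sc, p in zip(test_data, scores, pred)
                ],
            },
            "sensitivity": sensitivity,
        }

    snapshot = {
        "per_class_holdout": config.per_class_holdout,
        "segmenter": dict(config.segmenter.__dict__),
        "classifier": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in config.classifier.__dict__.items()
                       if k != "spectrogram"},
        "seg_train_stride": config.seg_train_stride,
        "cv_epochs": config.cv_epochs,
        "final_epochs": config.final_epochs,
        "models": list(config.models),
        "seeds": seeds,
    }
    return EvaluationReport(seed=seed, config=snapshot,
                            segmenter_history=seg_history, results=results)
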