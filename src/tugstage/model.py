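"""Model/Results front door for the two-stage staging pipeline.

``TwoStageModel`` is constructed from a cohort (in memory or from a trial
directory), ``fit`` runs the full evaluation protocol, and the returned
``StagingResults`` carries the metrics, trained artifacts, a text
``summary()`` and per-recording ``predict``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .evaluation import (
    ProtocolConfig,
    build_subject_data,
    predict_subjects,
    run_protocol,
)
from .preprocess import preprocess_recording
from .recording import Recording
from .segmenter import segment_recording
from .synthetic import CohortSpec, generate_cohort, read_cohort


class TwoStageModel:
    """Two-stage Hoehn-Yahr staging model over a modified-TUG cohort.

    Parameters
    ----------
    cohort : list of (Recording, GroundTruth)
        Labelled trials; ground-truth phase intervals are required to train
        the stage-1 segmenter.
    config : ProtocolConfig, optional
        Protocol settings (hold-out size, architectures, epochs).
    """

    def __init__(self, cohort, config: ProtocolConfig | None = None):
        self.cohort = list(cohort)
        self.config = config or ProtocolConfig()

    @classmethod
    def from_directory(cls, path, config: ProtocolConfig | None = None):
        """Build from a directory of CSV/JSON trials."""
        cohort = read_cohort(path)
        missing = [rec.subject_id for rec, gt in cohort if gt is None]
        if missing:
            raise ValueError(
                f"trials without ground-truth intervals cannot train the "
                f"segmenter: {missing[:5]}")
        return cls(cohort, config)

    @classmethod
    def from_synthetic(cls, spec: CohortSpec | None = None,
                       config: ProtocolConfig | None = None):
        """Build from a freshly generated synthetic cohort."""
        return cls(generate_cohort(spec or CohortSpec()), config)

    def fit(self, seed: int = 0) -> "StagingResults":
        """Run hold-out split, stage-1 training, 3-fold CV and final fit."""
        artifacts: dict = {}
        report = run_protocol(self.cohort, self.config, seed=seed,
                              artifacts=artifacts)
        return StagingResults(self, report, artifacts)


class StagingResults:
    """Fitted-pipeline results: metrics, histories, and trained artifacts."""

    def __init__(self, model: TwoStageModel, report, artifacts: dict):
        self.model = model
        self.report = report
        self.artifacts = artifacts

    @property
    def segmenter(self):
        return self.artifacts["segmenter"]

    def classifier(self, kind: str = "two_stage"):
        return self.artifacts["models"][kind]

    def predict(self, recording: Recording, kind: str = "two_stage"):
        """(score, stage) for a new recording via the trained artifacts."""
        pre = preprocess_recording(recording)
        seg = segment_recording(self.segmenter, pre.normalized,
                                recording.subject_id)
        subject = build_subject_data(pre, seg, missing_policy="zero")
        clf = self.artifacts["models"][kind]
        scaler = self.artifacts["scalers"][kind]
        scores, stages = predict_subjects(clf, [subject], scaler, clf.config)
        return float(scores[0]), str(stages[0])

    def summary(self) -> str:
        """Human-readable account of the fitted pipeline."""
        rep = self.report
        lines = []
        w = lines.append
        w("Two-stage Hoehn-Yahr staging pipeline")
        w("=" * 54)
        hist = rep.segmenter_history
        if hist.get("val_accuracy"):
            w(f"Stage 1 (1D U-Net segmenter): "
              f"val per-timestamp accuracy {100 * hist['val_accuracy'][-1]:.1f}% "
              f"after {len(hist['val_accuracy'])} epochs")
        for kind, res in rep.results.items():
            w("")
            w(f"Model: {kind}")
            w(f"  3-fold CV subject accuracy: "
              f"{res['cv_mean_accuracy_pct']:.2f}% "
              f"(folds: {', '.join(f'{a:.1f}' for a in res['cv_subject_accuracies_pct'])})")
            hold = res["holdout"]
            w(f"  Hold-out: accuracy {hold['accuracy_pct']:.1f}%  "
              f"macro-F1 {hold['macro_f1_pct']:.1f}%  "
              f"G-mean {hold['g_mean']:.2f}")
            w("  Confusion matrix (rows = true I/II/III):")
            for row in hold["confusion_matrix"]:
                w("    " + "  ".join(f"{int(v):3d}" for v in row))
            if res["sensitivity"]:
                w("  Zero-input sensitivity (accuracy when zeroed / delta):")
                for entry in res["sensitivity"]:
                    w(f"    {entry['input']:<10} {entry['accuracy_pct']:6.1f}%  "
                      f"delta {entry['delta_pct']:+.1f}")
        return "\n".join(lines)
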