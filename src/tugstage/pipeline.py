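"""End-to-end orchestration: generate -> preprocess -> segment -> features
-> train -> evaluate -> predict, with on-disk artifacts and a manifest.

One master seed deterministically derives every module seed (via numpy's
SeedSequence), so a rerun with the same configuration reproduces every
artifact; the manifest records seeds and SHA-256 hashes of the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .biomech import FEATURE_NAMES, FeatureScaler, extract_features, features_table
from .classifier import ClassifierConfig, StagingModel
from .evaluation import (
    ProtocolConfig,
    EvaluationReport,
    build_subject_data,
    predict_subjects,
    run_protocol,
)
from .preprocess import preprocess_recording
from .segmenter import SegmenterConfig, UNet1D, segment_recording
from .synthetic import CohortSpec, generate_cohort, read_trial, write_trial

log = logging.getLogger("tugstage")


@dataclass
class PipelineConfig:
    """Top-level configuration tying all module configs together."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortSpec(**raw.get("cohort", {}))
        proto_raw = dict(raw.get("protocol", {}))
        if "segmenter" in proto_raw:
            proto_raw["segmenter"] = SegmenterConfig(**proto_raw["segmenter"])
        if "classifier" in proto_raw:
            clf = dict(proto_raw["classifier"])
            for key in ("time_conv_filters", "lstm_units", "time_dense",
                        "freq_conv_filters", "biomech_dense", "top_dense",
                        "cutoffs", "encodings"):
                if key in clf:
                    clf[key] = tuple(clf[key])
            proto_raw["classifier"] = ClassifierConfig(**clf)
        if "models" in proto_raw:
            proto_raw["models"] = tuple(proto_raw["models"])
        return cls(seed=int(raw.get("seed", 0)), cohort=cohort,
                   protocol=ProtocolConfig(**proto_raw))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(spec: CohortSpec, out_dir) -> list:
    """Generate and persist a cohort in the CSV/JSON trial format."""
    out_dir = Path(out_dir)
    cohort = generate_cohort(spec)
    for rec, gt in cohort:
        write_trial(out_dir, rec, gt)
    log.info("wrote %d trials to %s", len(cohort), out_dir)
    return cohort


def run_end_to_end(config: PipelineConfig, workdir) -> EvaluationReport:
    """Execute the full data flow and leave artifacts + manifest on disk.

    Artifacts: the generated cohort (``cohort/``), the biomechanical feature
    table (``features.csv``), trained stage-1 and stage-2 weights, the
    evaluation report and a ``manifest.json`` of seeds and file hashes.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    cohort_dir = workdir / "cohort"
    cohort = write_cohort(config.cohort, cohort_dir)

    artifacts: dict = {}
    report = run_protocol(cohort, config.protocol, seed=config.seed,
                          artifacts=artifacts)

    seg_model: UNet1D = artifacts["segmenter"]
    seg_model.save(workdir / "segmenter.npz")
    for kind, model in artifacts["models"].items():
        model.save(workdir / f"classifier_{kind}.npz")
        scaler: FeatureScaler = artifacts["scalers"][kind]
        np.savez(workdir / f"scaler_{kind}.npz",
                 mins=scaler.mins, maxs=scaler.maxs)

    # feature table over the whole cohort via the trained segmenter
    rows = []
    for rec, _ in cohort:
        pre = preprocess_recording(rec)
        seg = segment_recording(seg_model, pre.normalized, rec.subject_id,
                                stride=config.protocol.segmentation_stride)
        try:
            feats = extract_features(pre.recording, seg,
                                     clip_negative_rtime=True)
        except ValueError as exc:
            log.warning("%s: no feature row (%s)", rec.subject_id, exc)
            continue
        rows.append((rec.subject_id, rec.stage, feats))
    features_table(rows).to_csv(workdir / "features.csv", index=False)

    report.to_json(workdir / "report.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "module_seeds": report.config["seeds"],
        "windowing": {"segmentation_stride": 1,
                      "segmenter_training_stride": config.protocol.seg_train_stride,
                      "classification_stride": 32},
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(workdir.glob("*.npz"))
        } | {"report.json": _sha256(workdir / "report.json"),
             "features.csv": _sha256(workdir / "features.csv")},
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    noise_warn(report)
    return report


def noise_warn(report: EvaluationReport) -> None:
    for kind, res in report.results.items():
        accs = res["cv_subject_accuracies_pct"]
        if min(accs) < 70:
            log.warning("%s: low CV fold accuracy %s", kind, accs)


def load_artifacts(artifact_dir, kind: str = "two_stage") -> dict:
    artifact_dir = Path(artifact_dir)
    seg = UNet1D.load(artifact_dir / "segmenter.npz")
    model = StagingModel.load(artifact_dir / f"classifier_{kind}.npz")
    with np.load(artifact_dir / f"scaler_{kind}.npz") as z:
        scaler = FeatureScaler()
        scaler.mins, scaler.maxs = z["mins"], z["maxs"]
    return {"segmenter": seg, "model": model, "scaler": scaler}


def predict_one(trial_csv, artifact_dir, kind: str = "two_stage") -> dict:
    """Single-subject end-to-end inference from a trial CSV + trained artifacts.

    Returns the predicted stage, the continuous score, the detected phase
    intervals and the 11 biomechanical variables.
    """
    rec, _ = read_trial(trial_csv)
    arts = load_artifacts(artifact_dir, kind)
    pre = preprocess_recording(rec)
    seg = segment_recording(arts["segmenter"], pre.normalized, rec.subject_id)
    subject = build_subject_data(pre, seg, missing_policy="zero")
    scores, stages = predict_subjects(
        arts["model"], [subject], arts["scaler"], arts["model"].config)
    return {
        "subject_id": rec.subject_id,
        "stage": str(stages[0]),
        "score": float(scores[0]),
        "segmentation": [(lab.name, int(s), int(e))
                         for lab, s, e in seg.intervals],
        "features": dict(zip(FEATURE_NAMES, map(float, subject.features))),
    }
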