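"""Evaluation protocol components: splits, SMOTE, rotations, metrics,
sensitivity — each against closed forms or brute-force oracles."""

import numpy as np
import pytest

from tugstage.evaluation import (
    augment_rotations,
    compute_metrics,
    holdout_split,
    rotate_windows,
    sensitivity_zero_inputs,
    smote_balance,
    stratified_threefold,
)
from tugstage.preprocess import WindowSet
from tugstage.recording import CHANNELS


class _FakeRec:
    def __init__(self, sid, stage):
        self.subject_id, self.stage = sid, stage


def _cohort(n1, n2, n3):
    out = []
    for stage, n in zip(("I", "II", "III"), (n1, n2, n3)):
        for i in range(n):
            out.append((_FakeRec(f"{stage}{i}", stage), None))
    return out


class TestHoldout:
    def test_sizes_match_protocol(self):
        train, test = holdout_split(_cohort(21, 30, 36), per_class=5, seed=0)
        assert len(test) == 15 and len(train) == 72
        stages = [rec.stage for rec, _ in test]
        assert all(stages.count(s) == 5 for s in ("I", "II", "III"))

    def test_subject_disjoint(self):
        cohort = _cohort(8, 8, 8)
        train, test = holdout_split(cohort, per_class=2, seed=1)
        train_ids = {rec.subject_id for rec, _ in train}
        test_ids = {rec.subject_id for rec, _ in test}
        assert not train_ids & test_ids
        assert len(train_ids) + len(test_ids) == 24

    def test_zero_per_class_keeps_everything(self):
        train, test = holdout_split(_cohort(3, 3, 3), per_class=0)
        assert test == [] and len(train) == 9

    def test_insufficient_class_errors(self):
        with pytest.raises(ValueError):
            holdout_split(_cohort(21, 30, 36), per_class=22)


class TestThreefold:
    def test_balanced_partition(self):
        subjects = [s for s, _ in _cohort(16, 25, 31)]
        folds = stratified_threefold(subjects, seed=0)
        assert sorted(i for f in folds for i in f) == list(range(72))
        sizes = sorted(len(f) for f in folds)
        assert sizes == [24, 24, 24]
        for stage, total in (("I", 16), ("II", 25), ("III", 31)):
            per_fold = [sum(subjects[i].stage == stage for i in f) for f in folds]
            assert max(per_fold) - min(per_fold) <= 1

    def test_minimum_three_per_class(self):
        subjects = [s for s, _ in _cohort(3, 3, 3)]
        folds = stratified_threefold(subjects, seed=5)
        for f in folds:
            assert sorted(subjects[i].stage for i in f) == ["I", "II", "III"]

    def test_deterministic(self):
        subjects = [s for s, _ in _cohort(6, 7, 8)]
        assert stratified_threefold(subjects, seed=3) == \
            stratified_threefold(subjects, seed=3)

    def test_too_small_class_errors(self):
        with pytest.raises(ValueError):
            stratified_threefold([s for s, _ in _cohort(2, 4, 4)], seed=0)


class TestSmote:
    def test_balances_to_majority(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 1, (16, 4)),
                            rng.normal(5, 1, (25, 4)),
                            rng.normal(10, 1, (31, 4))])
        y = np.array(["I"] * 16 + ["II"] * 25 + ["III"] * 31, dtype=object)
        Xb, yb = smote_balance(X, y, seed=1)
        _, counts = np.unique(yb, return_counts=True)
        assert counts.tolist() == [31, 31, 31]

    def test_originals_preserved_and_synthetic_within_class_hull(self):
        rng = np.random.default_rng(2)
        X = np.concatenate([rng.uniform(0, 1, (5, 3)), rng.uniform(9, 10, (12, 3))])
        y = np.array(["a"] * 5 + ["b"] * 12, dtype=object)
        Xb, yb = smote_balance(X, y, seed=3)
        np.testing.assert_array_equal(Xb[:17], X)
        synth = Xb[17:]
        assert (yb[17:] == "a").all()
        cls = X[:5]
        assert (synth >= cls.min(axis=0) - 1e-12).all()
        assert (synth <= cls.max(axis=0) + 1e-12).all()

    def test_already_balanced_unchanged(self):
        X = np.arange(12.0).reshape(6, 2)
        y = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        Xb, yb = smote_balance(X, y, seed=0)
        np.testing.assert_array_equal(Xb, X)

    def test_singleton_class_errors_naming_it(self):
        X = np.zeros((4, 2))
        y = np.array(["a", "b", "b", "b"], dtype=object)
        with pytest.raises(ValueError, match="'a'"):
            smote_balance(X, y)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        y = np.array(["a"] * 3 + ["b"] * 7, dtype=object)
        a, _ = smote_balance(X, y, seed=9)
        b, _ = smote_balance(X, y, seed=9)
        np.testing.assert_array_equal(a, b)


class TestRotations:
    def _ws(self, windows):
        n = windows.shape[0]
        return WindowSet(windows=windows, starts=np.zeros(n, dtype=int),
                         subject_ids=np.full(n, "S", dtype=object), stride=32,
                         stage_labels=np.full(n, 0.5))

    def test_triples_count_and_copies_labels(self):
        rng = np.random.default_rng(0)
        ws = self._ws(rng.normal(size=(100, 64, 6)))
        aug = augment_rotations(ws)
        assert len(aug) == 300
        assert (aug.stage_labels == 0.5).all()

    def test_horizontal_norm_preserved(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=(10, 64, 6))
        ap, ml = CHANNELS.index("acc_ap"), CHANNELS.index("acc_ml")
        for deg in (90, 180):
            r = rotate_windows(w, deg)
            np.testing.assert_allclose(
                np.hypot(r[..., ap], r[..., ml]),
                np.hypot(w[..., ap], w[..., ml]), atol=1e-9)

    def test_90_degrees_maps_ap_onto_ml(self):
        w = np.zeros((1, 64, 6))
        w[..., CHANNELS.index("acc_ap")] = 1.0
        r = rotate_windows(w, 90)
        np.testing.assert_allclose(r[..., CHANNELS.index("acc_ml")], 1.0)
        np.testing.assert_allclose(r[..., CHANNELS.index("acc_ap")], 0.0)

    def test_180_degrees_is_sign_flip_of_horizontal(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=(4, 64, 6))
        r = rotate_windows(w, 180)
        for name in ("acc_ap", "acc_ml", "gyr_pitch", "gyr_roll"):
            i = CHANNELS.index(name)
            np.testing.assert_allclose(r[..., i], -w[..., i])
        for name in ("acc_v", "gyr_yaw"):
            i = CHANNELS.index(name)
            np.testing.assert_allclose(r[..., i], w[..., i])


def _brute_metrics(y_true, y_pred, classes=("I", "II", "III")):
    recalls, f1s = [], []
    for c in classes:
        tp = sum(t == c and p == c for t, p in zip(y_true, y_pred))
        fn = sum(t == c and p != c for t, p in zip(y_true, y_pred))
        fp = sum(t != c and p == c for t, p in zip(y_true, y_pred))
        if tp + fn == 0:
            continue
        rec = tp / (tp + fn)
        prec = tp / (tp + fp) if tp + fp else 0.0
        recalls.append(rec)
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    gmean = float(np.prod(recalls) ** (1 / len(recalls)))
    return 100 * float(np.mean(f1s)), gmean


class TestMetrics:
    def test_perfect_predictions(self):
        y = ["I", "II", "III"] * 5
        m = compute_metrics(y, y)
        assert m["accuracy_pct"] == 100.0
        assert m["macro_f1_pct"] == 100.0
        assert m["g_mean"] == 1.0

    def test_gmean_closed_form(self):
        # recalls (0.5, 1, 1) -> G-mean = 0.5^(1/3)
        y_true = ["I", "I", "II", "III"]
        y_pred = ["I", "II", "II", "III"]
        m = compute_metrics(y_true, y_pred)
        assert m["g_mean"] == pytest.approx(0.5 ** (1 / 3))

    def test_fully_missed_class_zeroes_gmean(self):
        y_true = ["I", "I", "II", "III"]
        y_pred = ["II", "II", "II", "III"]
        assert compute_metrics(y_true, y_pred)["g_mean"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_labels(self, seed):
        rng = np.random.default_rng(seed)
        stages = np.array(["I", "II", "III"], dtype=object)
        y_true = stages[rng.integers(0, 3, 30)]
        y_pred = stages[rng.integers(0, 3, 30)]
        m = compute_metrics(y_true, y_pred)
        f1, gmean = _brute_metrics(y_true, y_pred)
        assert m["macro_f1_pct"] == pytest.approx(f1)
        assert m["g_mean"] == pytest.approx(gmean)
        cm = np.array(m["confusion_matrix"])
        assert cm.sum() == 30

    def test_absent_class_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="III"):
            m = compute_metrics(["I", "II"], ["I", "II"])
        assert m["g_mean"] == 1.0

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])
        with pytest.raises(ValueError):
            compute_metrics(["I"], ["I", "II"])


class TestSensitivity:
    def test_branch_ignored_by_weights_has_zero_delta(self):
        from tugstage.biomech import FeatureScaler
        from tugstage.classifier import ClassifierConfig, build_classifier
        from tugstage.evaluation import SubjectData

        cfg = ClassifierConfig(time_conv_filters=(2, 2, 2), lstm_units=(4, 4),
                               time_dense=(4,), freq_conv_filters=(2, 2, 2),
                               biomech_dense=(4,), top_dense=(8, 4), seed=0)
        model = build_classifier(cfg)
        # silence the frequency branch by zeroing its conv kernels
        for conv in model.freq_convs:
            conv.w.data[:] = 0.0
            conv.b.data[:] = 0.0
        rng = np.random.default_rng(0)
        subjects = []
        for i, stage in enumerate(("I", "II", "III")):
            subjects.append(SubjectData(
                subject_id=f"S{i}", stage=stage,
                windows=rng.normal(size=(4, 64, 6)).astype(np.float32),
                spectrograms=rng.normal(size=(4, 183, 11)).astype(np.float32),
                features=rng.uniform(size=11)))
        scaler = FeatureScaler().fit(np.stack([s.features for s in subjects]))
        table = sensitivity_zero_inputs(model, subjects, scaler, cfg)
        assert len(table) == 3
        by_name = {row["input"]: row for row in table}
        assert by_name["frequency"]["delta_pct"] == 0.0

    def test_single_input_model_rejected(self):
        from tugstage.classifier import build_baseline
        from tugstage.biomech import FeatureScaler

        model = build_baseline("cnn_lstm", None)
        with pytest.raises(ValueError):
            sensitivity_zero_inputs(model, [], FeatureScaler(), model.config)


class TestProtocolInvariants:
    @pytest.fixture(scope="class")
    @staticmethod
    def tiny_cohort():
        from tugstage.synthetic import CohortSpec, generate_cohort
        return generate_cohort(CohortSpec(counts=(4, 4, 4), seed=33))

    def _protocol(self, **over):
        from tugstage.evaluation import ProtocolConfig
        from tugstage.segmenter import SegmenterConfig
        from tugstage.classifier import ClassifierConfig
        defaults = dict(
            per_class_holdout=1,
            use_ground_truth_segmentation=True,
            segmenter=SegmenterConfig(base_filters=4, epochs=1),
            classifier=ClassifierConfig(
                time_conv_filters=(8, 16, 16), lstm_units=(16, 8),
                time_dense=(16,), freq_conv_filters=(4, 8, 8),
                biomech_dense=(16,), top_dense=(32, 16)),
            cv_epochs=1, final_epochs=4,
        )
        defaults.update(over)
        return ProtocolConfig(**defaults)

    def test_smote_and_augmentation_never_see_heldout_subjects(
            self, tiny_cohort, monkeypatch):
        """SMOTE and rotation augmentation must only touch training-fold
        subjects; hold-out and validation subjects stay untouched."""
        import tugstage.evaluation as ev

        seen_ids = []
        orig = ev._training_arrays

        def spy(subjects, *args, **kwargs):
            seen_ids.append({s.subject_id for s in subjects})
            return orig(subjects, *args, **kwargs)

        monkeypatch.setattr(ev, "_training_arrays", spy)
        report = ev.run_protocol(tiny_cohort, self._protocol(), seed=2)
        holdout_ids = {s["subject_id"]
                       for s in report.results["two_stage"]["holdout"]["subjects"]}
        assert holdout_ids and seen_ids
        for ids in seen_ids:
            assert not ids & holdout_ids

    def test_mixed_model_not_worse_than_baselines_on_average(self, tiny_cohort):
        """Hold-out accuracy tendency over 3 seeds: the three-branch model is
        at least as accurate as each single/dual-input baseline."""
        from tugstage.biomech import FeatureScaler
        from tugstage.classifier import (build_baseline, build_classifier,
                                         train_classifier)
        from tugstage.evaluation import (_model_inputs, _subject_data_for,
                                         _training_arrays, holdout_split,
                                         predict_subjects)
        from tugstage.preprocess import preprocess_recording

        cfg = self._protocol()
        train_c, test_c = holdout_split(tiny_cohort, per_class=1, seed=0)
        tr = _subject_data_for(
            train_c, [preprocess_recording(r) for r, _ in train_c], None, cfg)
        te = _subject_data_for(
            test_c, [preprocess_recording(r) for r, _ in test_c], None, cfg)
        truth = np.array([s.stage for s in te], dtype=object)
        acc = {"two_stage": [], "cnn_lstm": [], "cnn_biomech": []}
        for seed in (1, 2, 3):
            from dataclasses import replace
            ccfg = replace(cfg.classifier, epochs=4, seed=seed)
            scaler = FeatureScaler().fit(np.stack([s.features for s in tr]))
            arrays = _training_arrays(tr, scaler, ccfg, seed=seed)
            for kind in acc:
                model = (build_classifier(ccfg) if kind == "two_stage"
                         else build_baseline(kind, ccfg))
                train_classifier(model, _model_inputs(model, *arrays[:3]),
                                 arrays[3], ccfg)
                _, pred = predict_subjects(model, te, scaler, ccfg)
                acc[kind].append(float(np.mean(pred == truth)))
        mixed = np.mean(acc["two_stage"])
        assert mixed >= np.mean(acc["cnn_lstm"]) - 1e-9
        assert mixed >= np.mean(acc["cnn_biomech"]) - 1e-9
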