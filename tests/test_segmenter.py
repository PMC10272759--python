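"""Segmenter mechanics: architecture contract, voting, boundary bookkeeping,
and a small perfectly-separable oracle fit."""

import numpy as np
import pytest

from tugstage.phases import N_PHASES, PhaseLabel
from tugstage.preprocess import WindowSet, make_windows
from tugstage.segmenter import (
    NoPhasesDetected,
    PhaseSegmentation,
    SegmenterConfig,
    build_segmenter,
    clean_label_runs,
    label_window,
    samplewise_labels,
    segment_recording,
    train_segmenter,
)


@pytest.fixture(scope="module")
def small_model():
    return build_segmenter(SegmenterConfig(base_filters=4, epochs=1, seed=0))


class TestArchitecture:
    def test_probabilities_normalized(self, small_model):
        rng = np.random.default_rng(0)
        proba = small_model.predict_proba(rng.normal(size=(3, 64, 6)))
        assert proba.shape == (3, 64, N_PHASES)
        np.testing.assert_allclose(proba.sum(axis=-1), 1.0, atol=1e-6)
        assert (proba >= 0).all()

    def test_four_encoder_and_decoder_blocks(self):
        model = build_segmenter(SegmenterConfig(depth=4))
        assert len(model.enc_blocks) == 4 and len(model.dec_blocks) == 4

    def test_same_seed_same_initial_predictions(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 64, 6))
        a = build_segmenter(SegmenterConfig(seed=5)).predict_proba(x)
        b = build_segmenter(SegmenterConfig(seed=5)).predict_proba(x)
        np.testing.assert_array_equal(a, b)

    def test_incompatible_depth_rejected_before_training(self):
        with pytest.raises(ValueError):
            SegmenterConfig(depth=7)  # 64 not divisible by 2^7

    def test_save_load_roundtrip(self, small_model, tmp_path):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 64, 6))
        small_model.save(tmp_path / "m.npz")
        from tugstage.segmenter import UNet1D
        clone = UNet1D.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(small_model.predict_proba(x),
                                      clone.predict_proba(x))


class TestLabelWindow:
    def test_majority(self):
        labels = [int(PhaseLabel.WALK)] * 40 + [int(PhaseLabel.TURN_AND_SIT)] * 24
        assert label_window(np.array(labels)) is PhaseLabel.WALK

    def test_unanimous(self):
        assert label_window(np.full(64, int(PhaseLabel.SIT))) is PhaseLabel.SIT

    def test_tie_breaks_to_lowest_code(self):
        labels = [int(PhaseLabel.WALK)] * 32 + [int(PhaseLabel.SIT)] * 32
        assert label_window(np.array(labels)) is PhaseLabel.WALK

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            label_window(np.zeros(10, dtype=int))


class TestRunCleanup:
    def test_change_point_bookkeeping(self):
        seq = np.concatenate([
            np.full(300, int(PhaseLabel.BALANCE)),
            np.full(200, int(PhaseLabel.WALK)),
            np.full(150, int(PhaseLabel.TURN_AND_SIT)),
            np.full(100, int(PhaseLabel.GET_UP)),
            np.full(200, int(PhaseLabel.WALK)),
        ])
        runs = clean_label_runs(seq, min_samples=50)
        assert [s for _, s, _ in runs] == [0, 300, 500, 650, 750]
        assert len(runs) == 5

    def test_short_blip_merged_into_longer_neighbour(self):
        seq = np.full(600, int(PhaseLabel.BALANCE))
        seq[200:203] = int(PhaseLabel.WALK)
        runs = clean_label_runs(seq, min_samples=50)
        assert runs == [(int(PhaseLabel.BALANCE), 0, 600)]

    def test_no_adjacent_duplicates_after_cleanup(self):
        rng = np.random.default_rng(3)
        seq = rng.integers(0, 3, size=500)
        runs = clean_label_runs(seq, min_samples=20)
        labels = [lab for lab, _, _ in runs]
        assert all(a != b for a, b in zip(labels, labels[1:]))
        assert runs[0][1] == 0 and runs[-1][2] == 500


class TestSamplewise:
    def test_stride1_interior_uses_nearest_center(self):
        n = 200
        win_labels = np.zeros((n - 63, 64), dtype=int)
        win_labels[50:, :] = 1  # windows starting at >= 50 vote class 1
        starts = np.arange(n - 63)
        labels = samplewise_labels(win_labels, starts, n, stride=1)
        # sample i reads window starting at i-31: switch at i = 81
        assert labels[80] == 0 and labels[82] == 1


class TestTrainingOracle:
    def test_separable_constant_phases_reach_perfect_windows(self):
        """Distinct constant value per phase on one channel: the net must
        reach 100% window-label accuracy (oracle equivalence)."""
        rng = np.random.default_rng(0)
        segments = []
        labels = []
        for lab, level in [(PhaseLabel.BALANCE, -1.0), (PhaseLabel.WALK, 1.0),
                           (PhaseLabel.SIT, 0.4)]:
            for _ in range(30):
                x = np.zeros((64, 6))
                x[:, 0] = level + 0.01 * rng.normal(size=64)
                segments.append(x)
                labels.append(np.full(64, int(lab)))
        ws = WindowSet(windows=np.array(segments), starts=np.zeros(90, dtype=int),
                       subject_ids=np.full(90, "S", dtype=object), stride=1,
                       phase_labels=np.array(labels))
        cfg = SegmenterConfig(base_filters=4, epochs=40, seed=1, batch_size=8)
        model = build_segmenter(cfg)
        hist = train_segmenter(model, ws, cfg)
        assert np.all(np.isfinite(hist["loss"]))
        pred = model.predict_labels(ws.windows)
        window_votes = [label_window(p) for p in pred]
        truth = [label_window(t) for t in ws.phase_labels]
        assert window_votes == truth

    def test_single_class_warns_but_trains(self):
        ws = WindowSet(windows=np.zeros((8, 64, 6)), starts=np.zeros(8, dtype=int),
                       subject_ids=np.full(8, "S", dtype=object), stride=1,
                       phase_labels=np.full((8, 64), int(PhaseLabel.BALANCE)))
        cfg = SegmenterConfig(base_filters=4, epochs=2, seed=0, batch_size=8)
        model = build_segmenter(cfg)
        with pytest.warns(UserWarning, match="single class"):
            hist = train_segmenter(model, ws, cfg)
        pred = model.predict_labels(ws.windows)
        assert (pred == int(PhaseLabel.BALANCE)).all()


class TestSegmentRecording:
    def test_too_short_recording_rejected(self, small_model):
        with pytest.raises(ValueError):
            segment_recording(small_model, np.zeros((32, 6)))

    def test_tiling_and_no_adjacent_duplicates(self):
        # train a tiny model on two separable phases, segment a long signal
        rng = np.random.default_rng(4)
        n = 1500
        signal = np.zeros((n, 6))
        signal[:900, 0] = -0.8
        signal[900:, 0] = 0.8
        labels = np.where(np.arange(n) < 900, int(PhaseLabel.BALANCE),
                          int(PhaseLabel.WALK))
        ws = make_windows(signal + 0.01 * rng.normal(size=(n, 6)), stride=8,
                          sample_labels=labels)
        cfg = SegmenterConfig(base_filters=4, epochs=15, seed=2, batch_size=32)
        model = build_segmenter(cfg)
        train_segmenter(model, ws, cfg)
        seg = segment_recording(model, signal, "rec")
        assert seg.intervals[0][1] == 0 and seg.intervals[-1][2] == n
        labs = [lab for lab, _, _ in seg.intervals]
        assert all(a != b for a, b in zip(labs, labs[1:]))
        # boundary near the true change point
        assert len(seg.intervals) == 2
        assert abs(seg.intervals[0][2] - 900) <= 50


def test_segmentation_export_formats(tmp_path):
    seg = PhaseSegmentation(
        intervals=[(PhaseLabel.BALANCE, 0, 10), (PhaseLabel.WALK, 10, 30)],
        recording_id="S9")
    seg.to_json(tmp_path / "seg.json")
    seg.to_tsv(tmp_path / "seg.tsv")
    import json
    data = json.loads((tmp_path / "seg.json").read_text())
    assert data["intervals"][1] == {"label": "WALK", "start": 10, "end": 30}
    lines = (tmp_path / "seg.tsv").read_text().splitlines()
    assert lines[0].split("\t") == ["recording_id", "start_sample",
                                    "end_sample", "label"]
    assert lines[2].split("\t") == ["S9", "10", "30", "WALK"]


def test_all_noise_prediction_raises():
    class AllNoiseStub:
        def predict_labels(self, windows, batch_size=1024):
            return np.full((windows.shape[0], 64), int(PhaseLabel.NOISE))

    with pytest.raises(NoPhasesDetected):
        segment_recording(AllNoiseStub(), np.zeros((200, 6)), "rec")
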