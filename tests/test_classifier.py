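"""Stage-2 classifier: spectrogram oracle, encode/discretize, architecture
contracts, and small training behaviours."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import get_window

from tugstage.classifier import (
    ClassifierConfig,
    SpectrogramConfig,
    build_baseline,
    build_classifier,
    discretize,
    encode_stage,
    predict_subject,
    train_classifier,
    window_to_spectrogram,
    windows_to_spectrograms,
)


def _dft_oracle(signal, frame_length, frame_step, window="hann"):
    """Brute-force sliding DFT magnitude frames."""
    taper = get_window(window, frame_length, fftbins=True)
    frames = []
    for start in range(0, len(signal) - frame_length + 1, frame_step):
        seg = signal[start : start + frame_length] * taper
        bins = [sum(seg[n] * np.exp(-2j * np.pi * k * n / frame_length)
                    for n in range(frame_length))
                for k in range(frame_length // 2 + 1)]
        frames.append(np.abs(bins))
    return np.array(frames)


class TestSpectrogram:
    def test_shape_is_183_by_11(self):
        rng = np.random.default_rng(0)
        img = window_to_spectrogram(rng.normal(size=(64, 6)))
        assert img.shape == (183, 11)

    def test_concatenation_length_384(self):
        cfg = SpectrogramConfig()
        assert cfg.n_frames(64 * 6) == (384 - 20) // 2 + 1 == 183
        assert cfg.n_bins == 11

    def test_all_zero_window_hits_log_floor(self):
        cfg = SpectrogramConfig()
        img = window_to_spectrogram(np.zeros((64, 6)), cfg)
        np.testing.assert_allclose(img, np.log(cfg.log_floor), atol=1e-6)

    def test_matches_dft_oracle(self):
        rng = np.random.default_rng(1)
        win = rng.normal(size=(64, 6))
        cfg = SpectrogramConfig()
        img = window_to_spectrogram(win, cfg)
        oracle = np.log(_dft_oracle(win.T.ravel(), 20, 2) + cfg.log_floor)
        np.testing.assert_allclose(img, oracle, atol=1e-4)

    @given(frame_length=st.integers(4, 32), frame_step=st.integers(1, 8))
    @settings(max_examples=20, deadline=None)
    def test_frame_and_bin_counts_vs_bruteforce(self, frame_length, frame_step):
        cfg = SpectrogramConfig(frame_length=frame_length, frame_step=frame_step)
        sig = np.sin(np.arange(384) * 0.1)
        oracle = _dft_oracle(sig, frame_length, frame_step)
        assert cfg.n_frames(384) == oracle.shape[0]
        assert cfg.n_bins == oracle.shape[1]

    def test_sinusoid_at_bin_center_peaks_at_matching_bin(self):
        # channel 0 carries cos(2 pi * 4 k / 20): bin 4 of a 20-point frame
        win = np.zeros((64, 6))
        win[:, 0] = np.cos(2 * np.pi * 4 * np.arange(64) / 20)
        img = window_to_spectrogram(win)
        # frames fully inside channel 0's span: starts 0..44 -> indices 0..22
        for frame in img[:22]:
            assert int(np.argmax(frame)) == 4

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            window_to_spectrogram(np.zeros((32, 6)))


class TestEncodeDiscretize:
    @pytest.mark.parametrize("stage,enc", [("I", 0.0), ("II", 0.5), ("III", 1.0)])
    def test_encode(self, stage, enc):
        assert encode_stage(stage) == enc

    def test_encode_rejects_unknown(self):
        with pytest.raises(ValueError):
            encode_stage("IV")

    @pytest.mark.parametrize("y,stage", [
        (0.10, "I"), (0.50, "II"), (1.20, "III"),  # clamp above
        (-0.3, "I"),                               # clamp below
        (0.33, "II"), (0.66, "III"),               # boundary -> higher bin
    ])
    def test_discretize(self, y, stage):
        assert discretize(y) == stage

    def test_roundtrip_identity(self):
        for stage in ("I", "II", "III"):
            assert discretize(encode_stage(stage)) == stage

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(cutoffs=(0.7, 0.3))
        with pytest.raises(ValueError):
            ClassifierConfig(encodings=(0.5, 0.5, 1.0))


def _tiny_config(**over):
    defaults = dict(
        time_conv_filters=(4, 8, 8), lstm_units=(8, 8), time_dense=(8,),
        freq_conv_filters=(2, 4, 4), biomech_dense=(8,), top_dense=(16, 8),
        epochs=3, batch_size=16, seed=0)
    defaults.update(over)
    return ClassifierConfig(**defaults)


def _random_inputs(rng, n):
    return (rng.normal(size=(n, 64, 6)).astype(np.float32),
            rng.normal(size=(n, 183, 11)).astype(np.float32),
            rng.uniform(size=(n, 11)).astype(np.float32))


class TestArchitecture:
    def test_three_inputs_one_output(self):
        model = build_classifier(_tiny_config())
        assert model.n_inputs == 3
        rng = np.random.default_rng(0)
        scores = model.predict_scores(_random_inputs(rng, 4))
        assert scores.shape == (4,) and np.all(np.isfinite(scores))

    def test_zero_inputs_give_finite_scalar(self):
        model = build_classifier(_tiny_config())
        s = model.predict_scores((np.zeros((1, 64, 6)), np.zeros((1, 183, 11)),
                                  np.zeros((1, 11))))
        assert np.isfinite(s[0])

    def test_same_seed_identical_outputs(self):
        rng = np.random.default_rng(1)
        inputs = _random_inputs(rng, 3)
        a = build_classifier(_tiny_config(seed=9)).predict_scores(inputs)
        b = build_classifier(_tiny_config(seed=9)).predict_scores(inputs)
        np.testing.assert_array_equal(a, b)

    def test_baseline_input_counts(self):
        assert build_baseline("cnn_lstm", _tiny_config()).n_inputs == 1
        assert build_baseline("cnn_biomech", _tiny_config()).n_inputs == 2
        with pytest.raises(ValueError):
            build_baseline("spectro_only", _tiny_config())

    def test_wrong_input_count_rejected(self):
        model = build_baseline("cnn_lstm", _tiny_config())
        with pytest.raises(ValueError):
            model.predict_scores(_random_inputs(np.random.default_rng(0), 2))

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        inputs = _random_inputs(rng, 3)
        model = build_classifier(_tiny_config())
        model.save(tmp_path / "clf.npz")
        from tugstage.classifier import StagingModel
        clone = StagingModel.load(tmp_path / "clf.npz")
        np.testing.assert_array_equal(model.predict_scores(inputs),
                                      clone.predict_scores(inputs))


class TestTraining:
    def test_history_length_and_finiteness(self):
        rng = np.random.default_rng(3)
        inputs = _random_inputs(rng, 32)
        targets = np.repeat([0.0, 1.0], 16)
        cfg = _tiny_config(epochs=4)
        model = build_classifier(cfg)
        hist = train_classifier(model, inputs, targets, cfg)
        assert len(hist["loss"]) == len(hist["accuracy"]) == 4
        assert np.all(np.isfinite(hist["loss"]))

    def test_constant_targets_converge_to_that_class(self):
        rng = np.random.default_rng(4)
        inputs = _random_inputs(rng, 24)
        cfg = _tiny_config(epochs=25)
        model = build_classifier(cfg)
        train_classifier(model, inputs, np.full(24, 1.0), cfg)
        assert all(discretize(s) == "III"
                   for s in model.predict_scores(inputs))

    def test_separable_set_reaches_perfect_window_accuracy(self):
        # biomech vector alone separates the classes
        rng = np.random.default_rng(5)
        n = 60
        windows = rng.normal(size=(n, 64, 6)).astype(np.float32) * 0.1
        specs = rng.normal(size=(n, 183, 11)).astype(np.float32) * 0.1
        bio = np.zeros((n, 11), dtype=np.float32)
        targets = np.tile([0.0, 0.5, 1.0], n // 3)
        bio[:, 0] = targets
        cfg = _tiny_config(epochs=60, batch_size=8, input_dropout=0.0,
                           biomech_noise_sd=0.0)
        model = build_classifier(cfg)
        hist = train_classifier(model, (windows, specs, bio), targets, cfg)
        assert hist["accuracy"][-1] == 1.0

    def test_empty_training_set_rejected(self):
        cfg = _tiny_config()
        model = build_classifier(cfg)
        with pytest.raises(ValueError):
            train_classifier(model, _random_inputs(np.random.default_rng(0), 0),
                             np.empty(0), cfg)


class TestPredictSubject:
    def test_mean_score_discretized(self):
        class Fake:
            config = ClassifierConfig()
            def predict_scores(self, inputs):
                return np.array([0.2, 0.4])
        score, stage = predict_subject(Fake(), (np.zeros((2, 64, 6)),))
        assert score == pytest.approx(0.3)
        assert stage == "I"

    def test_no_windows_rejected(self):
        class Fake:
            config = ClassifierConfig()
            def predict_scores(self, inputs):
                return np.empty(0)
        with pytest.raises(ValueError):
            predict_subject(Fake(), (np.zeros((0, 64, 6)),))
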