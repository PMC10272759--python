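"""Stage 2: mixed-input staging network and its simplified baselines.

Three branches characterize one 64x6 window of the test:

* **time branch** — the raw (normalized) window through a stack of 1D
  convolutions with max pooling, two LSTM layers, and three dense layers;
* **frequency branch** — the six channels concatenated into one 384-sample
  sequence, short-time Fourier transformed (frame 20, step 2) into a
  183x11 log-magnitude spectrogram image, then three 3x3 2D convolutions
  with 2x2 pooling;
* **biomechanics branch** — the subject's 11 scaled clinical variables
  (repeated for each of the subject's windows) through dense layers.

The branch outputs are concatenated into a top model (dense 128 -> 64 -> 1,
linear) trained as a regression against stage encodings 0.0/0.5/1.0 with
mean squared error; continuous outputs discretize to Hoehn-Yahr stages at
the 0.33/0.66 cut-offs.  Subject-level stage = discretized mean of the
subject's window scores.

Baselines: ``cnn_lstm`` keeps only the time branch; ``cnn_biomech`` keeps a
convolution-only time branch plus the biomechanics branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from .nn import Adam, autograd as ag
from .nn.autograd import DTYPE, Tensor
from .nn.layers import LSTM, Conv1D, Conv2D, Dense, collect_parameters

STAGES = ("I", "II", "III")
SPECTROGRAM_SHAPE = (183, 11)


@dataclass
class SpectrogramConfig:
    """STFT settings for the frequency branch."""

    frame_length: int = 20
    frame_step: int = 2
    log_floor: float = 1e-6
    window: str = "hann"  # periodic, as in common STFT implementations

    def __post_init__(self):
        if self.frame_step < 1:
            raise ValueError("frame_step must be >= 1")

    def n_frames(self, n_samples: int) -> int:
        if self.frame_length > n_samples:
            raise ValueError("frame_length exceeds the concatenated signal length")
        return (n_samples - self.frame_length) // self.frame_step + 1

    @property
    def n_bins(self) -> int:
        return self.frame_length // 2 + 1


def window_to_spectrogram(window: np.ndarray,
                          config: SpectrogramConfig | None = None) -> np.ndarray:
    """Log-magnitude STFT image of one 64x6 window.

    Channels are concatenated in channel order into a single 384-sample
    sequence (seam frames between channels are kept, not masked), framed
    with the configured length/step, windowed, and Fourier transformed;
    the output is log(|STFT| + floor) with shape (frames, bins) = (183, 11)
    at the defaults.
    """
    window = np.asarray(window, dtype=float)
    if window.shape != (64, 6):
        raise ValueError(f"expected a (64, 6) window, got {window.shape}")
    return windows_to_spectrograms(window[None], config)[0]


def windows_to_spectrograms(windows: np.ndarray,
                            config: SpectrogramConfig | None = None) -> np.ndarray:
    """Vectorized spectrograms for a (n, 64, 6) stack -> (n, frames, bins)."""
    config = config or SpectrogramConfig()
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3 or windows.shape[1:] != (64, 6):
        raise ValueError(f"expected (n, 64, 6) windows, got {windows.shape}")
    n = windows.shape[0]
    # channel-order concatenation: (n, 6, 64) -> (n, 384)
    sig = windows.transpose(0, 2, 1).reshape(n, -1)
    n_frames = config.n_frames(sig.shape[1])
    frames = np.lib.stride_tricks.sliding_window_view(
        sig, config.frame_length, axis=1)[:, :: config.frame_step]
    frames = frames[:, :n_frames]
    taper = get_window(config.window, config.frame_length, fftbins=True)
    spec = np.abs(np.fft.rfft(frames * taper, axis=-1))
    return np.log(spec + config.log_floor).astype(DTYPE)


@dataclass
class ClassifierConfig:
    """Architecture and training settings for the staging network.

    Published settings: top dense 128/64, one linear output unit, cut-offs
    0.33/0.66, MSE loss, Adam, batch 32, 50 epochs.  Branch layer sizes are
    package defaults (the source figure shows topology only) and
    configurable.
    """

    time_conv_filters: tuple = (32, 64, 64)
    time_conv_kernel: int = 3
    lstm_units: tuple = (64, 32)
    time_dense: tuple = (64, 32, 16)
    freq_conv_filters: tuple = (8, 16, 32)
    freq_first_stride: int = 2  # frame-axis stride of the first 2D conv
    biomech_dense: tuple = (32, 16)
    top_dense: tuple = (128, 64)
    cutoffs: tuple = (0.33, 0.66)
    encodings: tuple = (0.0, 0.5, 1.0)
    loss: str = "mse"
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 50
    input_dropout: float = 0.3
    biomech_noise_sd: float = 0.1
    seed: int = 0
    spectrogram: SpectrogramConfig = field(default_factory=SpectrogramConfig)

    def __post_init__(self):
        lo, hi = self.cutoffs
        if not (0 < lo < hi < 1):
            raise ValueError("cutoffs must be strictly increasing within (0, 1)")
        bins = [(-np.inf, lo), (lo, hi), (hi, np.inf)]
        for enc, (a, b) in zip(self.encodings, bins):
            if not (a <= enc < b or (b is np.inf and enc >= a)):
                raise ValueError(f"encoding {enc} falls outside its stage bin")
        if self.loss != "mse":
            raise ValueError(f"unsupported loss {self.loss!r}")


def encode_stage(stage: str, config: ClassifierConfig | None = None) -> float:
    """Map a Hoehn-Yahr stage to its regression target (I/II/III -> 0/0.5/1)."""
    encodings = (config or ClassifierConfig()).encodings
    try:
        return float(encodings[STAGES.index(stage)])
    except ValueError:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}") from None


def discretize(y: float | np.ndarray, config: ClassifierConfig | None = None):
    """Continuous score(s) -> stage label(s) at the configured cut-offs.

    Out-of-range scores clamp into [0, 1]; a score exactly at a cut-off is
    assigned the higher bin.
    """
    lo, hi = (config or ClassifierConfig()).cutoffs
    arr = np.clip(np.atleast_1d(np.asarray(y, dtype=float)), 0.0, 1.0)
    idx = np.where(arr < lo, 0, np.where(arr < hi, 1, 2))
    stages = np.array(STAGES, dtype=object)[idx]
    if np.isscalar(y) or np.ndim(y) == 0:
        return str(stages[0])
    return stages


_KINDS = ("two_stage", "cnn_lstm", "cnn_biomech")


class StagingModel:
    """Mixed-input staging network (or one of its ablated baselines).

    Input order is fixed: (time window, spectrogram image, biomech vector),
    restricted to the branches the ``kind`` uses.
    """

    def __init__(self, config: ClassifierConfig, kind: str = "two_stage"):
        if kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
        self.config = config
        self.kind = kind
        rng = np.random.default_rng(config.seed)
        layers = []

        # --- time branch (all kinds) ---
        self.time_convs = []
        in_ch = 6
        t_len = 64
        for filt in config.time_conv_filters:
            self.time_convs.append(Conv1D(rng, in_ch, filt, config.time_conv_kernel))
            in_ch = filt
            t_len //= 2
        layers.extend(self.time_convs)
        self._t_len, self._t_ch = t_len, in_ch
        if kind in ("two_stage", "cnn_lstm"):
            self.lstms = []
            lstm_in = in_ch
            for i, units in enumerate(config.lstm_units):
                last = i == len(config.lstm_units) - 1
                self.lstms.append(LSTM(rng, lstm_in, units, return_sequences=not last))
                lstm_in = units
            layers.extend(self.lstms)
            self.time_dense = []
            d_in = lstm_in
            for units in config.time_dense:
                self.time_dense.append(Dense(rng, d_in, units))
                d_in = units
            layers.extend(self.time_dense)
            time_out = d_in
        else:  # cnn_biomech: convolution-only time branch, flattened
            self.lstms = []
            self.time_dense = []
            time_out = t_len * in_ch
        top_in = time_out

        # --- frequency branch ---
        if kind == "two_stage":
            self.freq_convs = []
            fh, fw = SPECTROGRAM_SHAPE
            in_ch2 = 1
            for k, filt in enumerate(config.freq_conv_filters):
                sh = config.freq_first_stride if k == 0 else 1
                self.freq_convs.append(Conv2D(rng, in_ch2, filt, 3,
                                              stride=(sh, 1)))
                in_ch2 = filt
                fh = (fh + sh - 1) // sh
                fh, fw = fh // 2, fw // 2
            layers.extend(self.freq_convs)
            self._f_out = fh * fw * in_ch2
            top_in += self._f_out
        else:
            self.freq_convs = []

        # --- biomechanics branch ---
        if kind in ("two_stage", "cnn_biomech"):
            self.biomech_dense = []
            b_in = 11
            for units in config.biomech_dense:
                self.biomech_dense.append(Dense(rng, b_in, units))
                b_in = units
            layers.extend(self.biomech_dense)
            top_in += b_in
        else:
            self.biomech_dense = []

        # --- top model ---
        self.top = []
        d_in = top_in
        for units in config.top_dense:
            self.top.append(Dense(rng, d_in, units))
            d_in = units
        self.out = Dense(rng, d_in, 1, activation=None)
        layers.extend([*self.top, self.out])
        self.params = collect_parameters(layers)

    @property
    def n_inputs(self) -> int:
        return {"two_stage": 3, "cnn_lstm": 1, "cnn_biomech": 2}[self.kind]

    def input_names(self) -> tuple:
        return {
            "two_stage": ("time", "frequency", "biomech"),
            "cnn_lstm": ("time",),
            "cnn_biomech": ("time", "biomech"),
        }[self.kind]

    def _time_features(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.time_convs:
            h = ag.maxpool1d(conv(h), 2)
        if self.kind == "cnn_biomech":
            return ag.reshape(h, (h.shape[0], self._t_len * self._t_ch))
        for lstm in self.lstms:
            h = lstm(h)
        for dense in self.time_dense:
            h = dense(h)
        return h

    def forward(self, inputs: tuple) -> Tensor:
        """Graph forward pass; inputs are Tensors in ``input_names`` order."""
        if len(inputs) != self.n_inputs:
            raise ValueError(
                f"{self.kind} expects {self.n_inputs} inputs, got {len(inputs)}")
        feats = [self._time_features(inputs[0])]
        if self.kind == "two_stage":
            h = ag.reshape(inputs[1],
                           (inputs[1].shape[0], *SPECTROGRAM_SHAPE, 1))
            for conv in self.freq_convs:
                h = ag.maxpool2d(conv(h), 2)
            feats.append(ag.reshape(h, (h.shape[0], self._f_out)))
        if self.kind in ("two_stage", "cnn_biomech"):
            b = inputs[-1]
            for dense in self.biomech_dense:
                b = dense(b)
            feats.append(b)
        h = feats[0] if len(feats) == 1 else ag.concat(feats, axis=1)
        for dense in self.top:
            h = dense(h)
        return self.out(h)

    def predict_scores(self, inputs: tuple, batch_size: int = 256,
                       zero_input: int | None = None) -> np.ndarray:
        """Continuous scores for numpy inputs; optionally zero one branch."""
        arrays = [np.asarray(a, dtype=DTYPE) for a in inputs]
        if zero_input is not None:
            if not 0 <= zero_input < self.n_inputs:
                raise ValueError(f"no input branch {zero_input} on {self.kind}")
            arrays[zero_input] = np.zeros_like(arrays[zero_input])
        n = arrays[0].shape[0]
        out = []
        for i in range(0, n, batch_size):
            batch = tuple(Tensor(a[i : i + batch_size]) for a in arrays)
            out.append(self.forward(batch).data[:, 0])
        return np.concatenate(out) if out else np.empty(0)

    # --- weight persistence -------------------------------------------------
    def save(self, path) -> None:
        cfg = dict(self.config.__dict__)
        cfg["spectrogram"] = self.config.spectrogram.__dict__
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params)}
        np.savez(path, kind=self.kind, config=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "StagingModel":
        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["config"]))
            cfg["spectrogram"] = SpectrogramConfig(**cfg["spectrogram"])
            for key in ("time_conv_filters", "lstm_units", "time_dense",
                        "freq_conv_filters", "biomech_dense", "top_dense",
                        "cutoffs", "encodings"):
                cfg[key] = tuple(cfg[key])
            model = cls(ClassifierConfig(**cfg), kind=str(z["kind"]))
            for i, p in enumerate(model.params):
                p.data = z[f"p{i}"].astype(DTYPE)
        return model


def build_classifier(config: ClassifierConfig | None = None) -> StagingModel:
    """The full three-branch mixed-input model."""
    return StagingModel(config or ClassifierConfig(), kind="two_stage")


def build_baseline(kind: str, config: ClassifierConfig | None = None) -> StagingModel:
    """A simplified comparison model: ``cnn_lstm`` or ``cnn_biomech``."""
    if kind not in ("cnn_lstm", "cnn_biomech"):
        raise ValueError(f"unknown baseline kind {kind!r}")
    return StagingModel(config or ClassifierConfig(), kind=kind)


def train_classifier(model: StagingModel, inputs: tuple, targets: np.ndarray,
                     config: ClassifierConfig | None = None,
                     eval_train_accuracy: bool = False) -> dict:
    """MSE/Adam training; history records per-epoch loss and window accuracy.

    ``inputs`` are numpy arrays in the model's input order; ``targets`` are
    stage encodings (0.0/0.5/1.0).  Window accuracy discretizes predictions
    and targets at the configured cut-offs.  Reproducible for a fixed seed.

    With ``input_dropout`` > 0 and a multi-input model, each training sample
    has that probability of one randomly chosen input branch being zeroed
    for the step (modality dropout).  This keeps any single branch from
    shortcutting the regression — a per-subject-constant input can otherwise
    be memorized within an epoch or two, starving the signal branches of
    gradient — and makes predictions degrade gracefully when one input is
    missing or zeroed at inference time.  ``biomech_noise_sd`` adds Gaussian
    jitter to the scaled biomechanical vector during training only, so the
    fusion learns that branch's real (imperfect) reliability instead of
    memorizing per-subject constants.

    ``history["accuracy_online"]`` is computed on the (possibly corrupted)
    training batches; with ``eval_train_accuracy`` the reported
    ``history["accuracy"]`` is instead a clean epoch-end evaluation over the
    training set, which is the quantity "training window accuracy" usually
    refers to when regularization corrupts the batches.
    """
    config = config or model.config
    arrays = [np.ascontiguousarray(a, dtype=DTYPE) for a in inputs]
    targets = np.asarray(targets, dtype=DTYPE).reshape(-1, 1)
    n = targets.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    true_stage = discretize(targets[:, 0], config)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.params, lr=config.learning_rate)
    p_drop = config.input_dropout if model.n_inputs > 1 else 0.0
    history = {"loss": [], "accuracy": [], "accuracy_online": []}
    for _ in range(config.epochs):
        order = rng.permutation(n)
        sq_sum, correct = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            batch_arrays = [a[idx] for a in arrays]
            if config.biomech_noise_sd > 0 and "biomech" in model.input_names():
                k = model.input_names().index("biomech")
                noisy = batch_arrays[k] + rng.normal(
                    0.0, config.biomech_noise_sd,
                    size=batch_arrays[k].shape).astype(DTYPE)
                batch_arrays[k] = np.clip(noisy, 0.0, 1.0)
            if p_drop > 0.0:
                dropped = rng.random(idx.size) < p_drop
                which = rng.integers(0, model.n_inputs, size=idx.size)
                for k in range(model.n_inputs):
                    rows = dropped & (which == k)
                    if rows.any():
                        batch_arrays[k] = batch_arrays[k].copy()
                        batch_arrays[k][rows] = 0.0
            batch = tuple(Tensor(a) for a in batch_arrays)
            pred = model.forward(batch)
            loss = ag.mse_loss(pred, targets[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            sq_sum += float(loss.data) * idx.size
            correct += int(np.sum(discretize(pred.data[:, 0], config)
                                  == true_stage[idx]))
        history["loss"].append(sq_sum / n)
        history["accuracy_online"].append(correct / n)
        if eval_train_accuracy:
            pred = model.predict_scores(tuple(arrays), batch_size=512)
            history["accuracy"].append(
                float(np.mean(discretize(pred, config) == true_stage)))
        else:
            history["accuracy"].append(correct / n)
    return history


def predict_subject(model: StagingModel, inputs: tuple,
                    config: ClassifierConfig | None = None) -> tuple[float, str]:
    """(mean window score, discretized stage) for one recording's windows."""
    config = config or model.config
    scores = model.predict_scores(inputs)
    if scores.size == 0:
        raise ValueError("no windows to predict from")
    mean = float(scores.mean())
    return mean, discretize(mean, config)
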