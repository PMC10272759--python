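"""Stage 1: semantic segmentation of the test phases with a 1D U-Net.

The network maps a (64, 6) window of normalized signals to per-timestamp
probabilities over the six phase categories.  An encoder of ``depth`` blocks
(two same-padded 1D convolutions + channel normalization, then 2x max
pooling) feeds a bridge, and a mirrored decoder (2x nearest-neighbour
upsampling + skip concatenation + two convolutions) restores the input
resolution; a kernel-1 convolution emits the class logits.

Whole-recording segmentation slides stride-1 windows over the trial, labels
every sample from the window whose center is nearest, removes label runs
shorter than a minimum duration by merging them into the longer neighbour,
and reports the change points as phase boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Adam, autograd as ag
from .nn.autograd import DTYPE, Tensor
from .nn.layers import ChannelNorm, Conv1D, collect_parameters
from .phases import N_PHASES, PhaseLabel
from .preprocess import WINDOW_LENGTH, WindowSet, make_windows


class NoPhasesDetected(RuntimeError):
    """The segmenter labelled the entire recording as noise."""


@dataclass
class SegmenterConfig:
    """Hyper-parameters of the 1D U-Net and its training loop.

    ``base_filters`` doubles at each of ``depth`` encoder levels (default 8,
    so the bridge carries 128 channels; the published figure fixes the
    topology but not the filter counts).  64 timestamps support at most
    depth 6 with pool 2.
    """

    depth: int = 4
    base_filters: int = 8
    kernel_size: int = 3
    pool_size: int = 2
    learning_rate: float = 0.001
    loss: str = "categorical_crossentropy"
    epochs: int = 3
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if WINDOW_LENGTH % (self.pool_size ** self.depth):
            raise ValueError(
                f"window length {WINDOW_LENGTH} not divisible by "
                f"pool {self.pool_size}^depth {self.depth}")
        if self.loss != "categorical_crossentropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


@dataclass
class PhaseSegmentation:
    """Ordered, contiguous half-open labelled intervals over one recording."""

    intervals: list  # (PhaseLabel, start, end)
    recording_id: str = ""

    def labels(self, n_samples: int | None = None) -> np.ndarray:
        n = n_samples if n_samples is not None else self.intervals[-1][2]
        out = np.full(n, int(PhaseLabel.NOISE), dtype=np.int64)
        for lab, s, e in self.intervals:
            out[s:e] = int(lab)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "recording_id": self.recording_id,
                    "intervals": [
                        {"label": PhaseLabel(l).name, "start": int(s), "end": int(e)}
                        for l, s, e in self.intervals
                    ],
                },
                fh, indent=1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("recording_id\tstart_sample\tend_sample\tlabel\n")
            for lab, s, e in self.intervals:
                fh.write(f"{self.recording_id}\t{s}\t{e}\t{PhaseLabel(lab).name}\n")


class UNet1D:
    """The segmentation network; ``build_segmenter`` is the public constructor."""

    def __init__(self, config: SegmenterConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel_size
        f = config.base_filters
        self.enc_blocks = []
        in_ch = 6
        for d in range(config.depth):
            filters = f * (2 ** d)
            self.enc_blocks.append(
                (Conv1D(rng, in_ch, filters, k), Conv1D(rng, filters, filters, k),
                 ChannelNorm(filters)))
            in_ch = filters
        bridge_f = f * (2 ** config.depth)
        self.bridge = (Conv1D(rng, in_ch, bridge_f, k),
                       Conv1D(rng, bridge_f, bridge_f, k), ChannelNorm(bridge_f))
        self.dec_blocks = []
        up_ch = bridge_f
        for d in reversed(range(config.depth)):
            filters = f * (2 ** d)
            self.dec_blocks.append(
                (Conv1D(rng, up_ch + filters, filters, k),
                 Conv1D(rng, filters, filters, k), ChannelNorm(filters)))
            up_ch = filters
        self.head = Conv1D(rng, up_ch, N_PHASES, kernel=1, activation=None)
        layers = []
        for blk in (*self.enc_blocks, self.bridge, *self.dec_blocks):
            layers.extend(blk)
        layers.append(self.head)
        self.params = collect_parameters(layers)

    def logits(self, x: Tensor) -> Tensor:
        """(B, 64, 6) windows -> (B, 64, n_phases) class logits."""
        skips = []
        h = x
        for c1, c2, norm in self.enc_blocks:
            h = norm(c2(c1(h)))
            skips.append(h)
            h = ag.maxpool1d(h, self.config.pool_size)
        c1, c2, norm = self.bridge
        h = norm(c2(c1(h)))
        for (c1, c2, norm), skip in zip(self.dec_blocks, reversed(skips)):
            h = ag.upsample1d(h, self.config.pool_size)
            h = ag.concat([h, skip], axis=2)
            h = norm(c2(c1(h)))
        return self.head(h)

    def predict_proba(self, windows: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Per-timestamp phase probabilities, rows summing to 1."""
        windows = np.asarray(windows, dtype=DTYPE)
        out = []
        for i in range(0, windows.shape[0], batch_size):
            logits = self.logits(Tensor(windows[i : i + batch_size]))
            out.append(ag.softmax(logits.data))
        return np.concatenate(out) if out else np.empty((0, WINDOW_LENGTH, N_PHASES))

    def predict_labels(self, windows: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        windows = np.asarray(windows, dtype=DTYPE)
        out = []
        for i in range(0, windows.shape[0], batch_size):
            logits = self.logits(Tensor(windows[i : i + batch_size]))
            out.append(logits.data.argmax(axis=-1))
        return (np.concatenate(out) if out
                else np.empty((0, WINDOW_LENGTH), dtype=np.int64))

    # --- weight persistence -------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params)}
        np.savez(path, n_params=len(self.params),
                 config=json.dumps(self.config.__dict__), **arrays)

    @classmethod
    def load(cls, path) -> "UNet1D":
        with np.load(path, allow_pickle=False) as z:
            config = SegmenterConfig(**json.loads(str(z["config"])))
            model = cls(config)
            for i, p in enumerate(model.params):
                p.data = z[f"p{i}"].astype(DTYPE)
        return model


def build_segmenter(config: SegmenterConfig | None = None) -> UNet1D:
    """Construct an untrained U-Net; raises on incompatible depth/pool."""
    return UNet1D(config or SegmenterConfig())


def _one_hot(labels: np.ndarray) -> np.ndarray:
    return np.eye(N_PHASES, dtype=DTYPE)[labels]


def train_segmenter(model: UNet1D, train_set: WindowSet,
                    config: SegmenterConfig | None = None,
                    val_set: WindowSet | None = None) -> dict:
    """Train with Adam + categorical cross-entropy; returns the history.

    History lists per-epoch training loss/accuracy and, when a validation
    WindowSet is given, validation loss and per-timestamp accuracy.
    Reproducible for a fixed config seed.
    """
    import warnings

    config = config or model.config
    if train_set.phase_labels is None:
        raise ValueError("training WindowSet needs per-timestamp phase labels")
    x = np.asarray(train_set.windows, dtype=DTYPE)
    y = np.asarray(train_set.phase_labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        warnings.warn("training labels contain a single class; degenerate fit")
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.params, lr=config.learning_rate)
    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    n = x.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses, correct, total = [], 0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.logits(Tensor(xb))
            loss, proba = ag.softmax_cross_entropy(logits, _one_hot(yb))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * yb.size)
            correct += int((proba.argmax(-1) == yb).sum())
            total += yb.size
        history["loss"].append(float(np.sum(losses) / total))
        history["accuracy"].append(correct / total)
        if val_set is not None:
            vl, va = evaluate_segmenter(model, val_set)
            history["val_loss"].append(vl)
            history["val_accuracy"].append(va)
    return history


def evaluate_segmenter(model: UNet1D, window_set: WindowSet,
                       batch_size: int = 1024) -> tuple[float, float]:
    """(mean cross-entropy, per-timestamp accuracy) on a labelled WindowSet."""
    if window_set.phase_labels is None:
        raise ValueError("WindowSet needs per-timestamp phase labels")
    x = np.asarray(window_set.windows, dtype=DTYPE)
    y = np.asarray(window_set.phase_labels, dtype=np.int64)
    losses, correct = 0.0, 0
    for i in range(0, x.shape[0], batch_size):
        logits = model.logits(Tensor(x[i : i + batch_size]))
        loss, proba = ag.softmax_cross_entropy(logits, _one_hot(y[i : i + batch_size]))
        losses += float(loss.data) * y[i : i + batch_size].size
        correct += int((proba.argmax(-1) == y[i : i + batch_size]).sum())
    return losses / y.size, correct / y.size


def label_window(timestamp_labels: np.ndarray) -> PhaseLabel:
    """Majority vote over the 64 per-timestamp labels; ties -> lowest code."""
    labels = np.asarray(timestamp_labels, dtype=np.int64)
    if labels.shape != (WINDOW_LENGTH,):
        raise ValueError(f"expected {WINDOW_LENGTH} labels, got {labels.shape}")
    return PhaseLabel(int(np.bincount(labels, minlength=N_PHASES).argmax()))


def _runs(labels: np.ndarray) -> list:
    """Run-length encode to (label, start, end) half-open intervals."""
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate([[0], change, [labels.shape[0]]])
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(bounds[:-1], bounds[1:])]


def clean_label_runs(labels: np.ndarray, min_samples: int) -> list:
    """Merge runs shorter than ``min_samples`` into their longer neighbour."""
    runs = _runs(labels)
    while len(runs) > 1:
        lengths = [e - s for _, s, e in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_samples:
            break
        left = runs[shortest - 1] if shortest > 0 else None
        right = runs[shortest + 1] if shortest < len(runs) - 1 else None
        if right is None or (left is not None and
                             (left[2] - left[1]) >= (right[2] - right[1])):
            absorb = left[0]
        else:
            absorb = right[0]
        lab, s, e = runs[shortest]
        runs[shortest] = (absorb, s, e)
        merged = []
        for r in runs:  # coalesce adjacent equal labels
            if merged and merged[-1][0] == r[0]:
                merged[-1] = (r[0], merged[-1][1], r[2])
            else:
                merged.append(r)
        runs = merged
    return runs


def samplewise_labels(window_labels: np.ndarray, starts: np.ndarray,
                      n_samples: int, stride: int = 1) -> np.ndarray:
    """Per-sample labels from per-window predictions.

    Each sample takes the label of the window whose center is nearest
    (ties resolved toward the later window), read at the sample's offset
    within that window.
    """
    n_win = window_labels.shape[0]
    idx = np.arange(n_samples)
    half = WINDOW_LENGTH // 2 - 1  # center ~ start+31.5; nearest start = i-31
    win = np.clip(np.round((idx - half) / stride).astype(int), 0, n_win - 1)
    offs = np.clip(idx - starts[win], 0, WINDOW_LENGTH - 1)
    return window_labels[win, offs]


def segment_recording(model: UNet1D, normalized: np.ndarray,
                      recording_id: str = "", min_duration_s: float = 0.5,
                      sample_rate: float = 100.0,
                      stride: int = 1) -> PhaseSegmentation:
    """Segment a preprocessed (normalized) recording into phase intervals."""
    n = normalized.shape[0]
    if n < WINDOW_LENGTH:
        raise ValueError(f"recording shorter than one window ({n} < {WINDOW_LENGTH})")
    ws = make_windows(normalized, stride=stride)
    win_labels = model.predict_labels(ws.windows)
    labels = samplewise_labels(win_labels, ws.starts, n, stride=stride)
    if np.all(labels == int(PhaseLabel.NOISE)):
        raise NoPhasesDetected(f"recording {recording_id!r}: all samples noise")
    runs = clean_label_runs(labels, int(round(min_duration_s * sample_rate)))
    intervals = [(PhaseLabel(lab), s, e) for lab, s, e in runs]
    return PhaseSegmentation(intervals=intervals, recording_id=recording_id)
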