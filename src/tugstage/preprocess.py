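"""Signal conditioning and windowing ahead of the two model stages.

Conditioning standardizes every trial to 100 Hz (linear interpolation),
applies a 4th-order zero-lag (forward-backward) Butterworth low-pass at
20 Hz, and min-max normalizes each channel into [-1, 1].  Two windowing
schemes cut the conditioned matrix into 64-timestamp windows: stride 1
(63-sample overlap) for semantic segmentation and stride 32 (50% overlap)
for the stage classifier.

Normalization statistics are fit per recording and per channel; features in
the biomechanics module are computed from the *physical-unit* filtered
signals, never the normalized ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import Recording

TARGET_RATE = 100.0
WINDOW_LENGTH = 64
SEGMENTATION_STRIDE = 1
CLASSIFICATION_STRIDE = 32

_FILTER_ORDER = 4
_CUTOFF_HZ = 20.0
# scipy filtfilt default pad length for a 4th-order (5-coefficient) design
_MIN_FILTER_LEN = 3 * _FILTER_ORDER + 1


def resample_to_100hz(data: np.ndarray, source_rate: float) -> np.ndarray:
    """Linearly interpolate an (N, C) channel matrix onto a uniform 100 Hz grid.

    The grid runs t = 0, 0.01, ... up to and including the original last
    sample time (N-1)/source_rate, so endpoints are preserved and an input
    already at 100 Hz is returned unchanged.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if source_rate <= 0:
        raise ValueError("source_rate must be positive")
    n = data.shape[0]
    if n < 2:
        raise ValueError("cannot interpolate a signal with fewer than 2 samples")
    t_src = np.arange(n) / source_rate
    n_out = int(np.floor(t_src[-1] * TARGET_RATE + 1e-9)) + 1
    t_out = np.arange(n_out) / TARGET_RATE
    out = np.empty((n_out, data.shape[1]))
    for c in range(data.shape[1]):
        out[:, c] = np.interp(t_out, t_src, data[:, c])
    return out


def lowpass_20hz(data: np.ndarray, sample_rate: float = TARGET_RATE) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass at 20 Hz, column-wise.

    Forward-backward application squares the magnitude response, giving the
    zero-lag behaviour required for timing features.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n <= _MIN_FILTER_LEN:
        raise ValueError(
            f"signal too short to filter: need more than {_MIN_FILTER_LEN} "
            f"samples, got {n}")
    b, a = sps.butter(_FILTER_ORDER, _CUTOFF_HZ / (sample_rate / 2.0))
    return sps.filtfilt(b, a, data, axis=0)


def minmax_norm(data: np.ndarray, feature_range: tuple = (-1.0, 1.0)) -> np.ndarray:
    """Per-channel affine map of min/max onto ``feature_range``.

    Constant channels map to the midpoint of the target range.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    lo, hi = feature_range
    mins = data.min(axis=0)
    maxs = data.max(axis=0)
    span = maxs - mins
    out = np.empty_like(data)
    const = span == 0
    nz = ~const
    out[:, nz] = (data[:, nz] - mins[nz]) / span[nz] * (hi - lo) + lo
    out[:, const] = (lo + hi) / 2.0
    return out


@dataclass
class WindowSet:
    """A stack of 64x6 windows with per-window provenance.

    ``windows`` has shape (n_windows, 64, n_channels); ``starts`` are the
    window start indices in the source matrix (constant stride);
    ``subject_ids`` tags every window with its source recording.  Optional
    per-timestamp ``phase_labels`` (n_windows, 64) support segmentation
    training and a window-level ``stage_labels`` vector supports staging.
    """

    windows: np.ndarray
    starts: np.ndarray
    subject_ids: np.ndarray
    stride: int
    phase_labels: np.ndarray | None = None
    stage_labels: np.ndarray | None = None

    def __len__(self):
        return self.windows.shape[0]

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        if not sets:
            raise ValueError("cannot concatenate zero WindowSets")
        phase = None
        if all(s.phase_labels is not None for s in sets):
            phase = np.concatenate([s.phase_labels for s in sets])
        stage = None
        if all(s.stage_labels is not None for s in sets):
            stage = np.concatenate([s.stage_labels for s in sets])
        return WindowSet(
            windows=np.concatenate([s.windows for s in sets]),
            starts=np.concatenate([s.starts for s in sets]),
            subject_ids=np.concatenate([s.subject_ids for s in sets]),
            stride=sets[0].stride,
            phase_labels=phase,
            stage_labels=stage,
        )

    def for_subjects(self, subject_ids) -> "WindowSet":
        mask = np.isin(self.subject_ids, list(subject_ids))
        return WindowSet(
            windows=self.windows[mask],
            starts=self.starts[mask],
            subject_ids=self.subject_ids[mask],
            stride=self.stride,
            phase_labels=None if self.phase_labels is None else self.phase_labels[mask],
            stage_labels=None if self.stage_labels is None else self.stage_labels[mask],
        )


def make_windows(data: np.ndarray, stride: int, length: int = WINDOW_LENGTH,
                 subject_id: str = "", sample_labels: np.ndarray | None = None,
                 stage_label: float | None = None) -> WindowSet:
    """Cut an (N, C) matrix into overlapping windows of ``length`` timestamps.

    Yields floor((N - length)/stride) + 1 windows; trailing samples that do
    not fill a window are dropped.
    """
    data = np.asarray(data)
    n = data.shape[0]
    if n < length:
        raise ValueError(f"need at least {length} samples to window, got {n}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    view = np.lib.stride_tricks.sliding_window_view(data, length, axis=0)
    windows = view[::stride].transpose(0, 2, 1).copy()
    n_win = windows.shape[0]
    starts = np.arange(n_win) * stride
    phase = None
    if sample_labels is not None:
        lab_view = np.lib.stride_tricks.sliding_window_view(
            np.asarray(sample_labels), length, axis=0)
        phase = lab_view[::stride].copy()
    stage = None
    if stage_label is not None:
        stage = np.full(n_win, stage_label)
    return WindowSet(
        windows=windows,
        starts=starts,
        subject_ids=np.full(n_win, subject_id, dtype=object),
        stride=stride,
        phase_labels=phase,
        stage_labels=stage,
    )


@dataclass
class PreprocessedRecording:
    """A conditioned trial: physical-unit filtered signals + normalized copy."""

    recording: Recording  # filtered, physical units, 100 Hz
    normalized: np.ndarray = field(repr=False)  # same shape, per-channel [-1, 1]


def preprocess_recording(rec: Recording, source_rate: float | None = None
                         ) -> PreprocessedRecording:
    """Standardize to 100 Hz, low-pass, and attach the normalized matrix."""
    rate = source_rate if source_rate is not None else rec.sample_rate
    data = rec.data
    if rate != TARGET_RATE:
        data = resample_to_100hz(data, rate)
    filtered = lowpass_20hz(data)
    out = Recording(
        subject_id=rec.subject_id,
        data=filtered,
        sample_rate=TARGET_RATE,
        body_mass=rec.body_mass,
        stimulus_time=rec.stimulus_time,
        stage=rec.stage,
        channel_names=rec.channel_names,
    )
    return PreprocessedRecording(recording=out, normalized=minmax_norm(filtered))
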