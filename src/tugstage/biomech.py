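"""Biomechanical variables from a segmented trial.

Eleven scalar features summarize the four test phases, following the
trunk-accelerometry tradition of estimating center-of-mass (COM) kinematics
by integrating the acceleration at L4-L5:

* quiet stance: ML/AP COM displacement ranges and the swept area of the
  ML-AP trajectory (``MLDisp``, ``APDisp``, ``DispA``);
* gait: vertical and ML COM displacement ranges, averaged over the two
  3 m walks (``VRange``, ``MLRange``);
* chair transfers: peak mechanical power m*(a_v+g)*v during turn-to-sit and
  sit-to-stand (``PTurnSit``, ``PStand``) and the range of the jerk of the
  acceleration magnitude (``JerkSit``, ``JerkStand``);
* whole test: reaction time from the go stimulus to gait onset (``RTime``)
  and total time from stimulus to the end of the return walk (``TTime``).

Displacements are computed by trapezoidal double integration with a
zero-lag 0.2 Hz 4th-order Butterworth high-pass after each integration to
suppress drift.  All features are computed from *physical-unit* filtered
signals; the [-1, 1] normalization used by the networks would destroy the
mm/W/s units reported clinically.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .phases import PhaseLabel
from .recording import Recording

G = 9.81  # m/s^2

_HP_ORDER = 4
_HP_CUTOFF = 0.2  # Hz
_MIN_SEGMENT_S = 1.0

#: Canonical feature order for tables and model input vectors.
FEATURE_NAMES = (
    "MLDisp", "APDisp", "DispA", "VRange", "MLRange",
    "PTurnSit", "PStand", "JerkSit", "JerkStand", "TTime", "RTime",
)


class MissingPhase(ValueError):
    """A required phase is absent from the segmentation."""

    def __init__(self, phase: PhaseLabel):
        self.phase = phase
        super().__init__(f"segmentation has no {phase.name} interval")


class InvalidSegmentation(ValueError):
    """Segmentation is inconsistent with the test script (e.g. negative RTime)."""


@dataclass
class BiomechFeatures:
    """The 11 per-trial biomechanical variables (mm, mm^2, W, m/s^3, s)."""

    MLDisp: float
    APDisp: float
    DispA: float
    VRange: float
    MLRange: float
    PTurnSit: float
    PStand: float
    JerkSit: float
    JerkStand: float
    TTime: float
    RTime: float

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _intervals_of(segmentation, label: PhaseLabel):
    return [(s, e) for lab, s, e in segmentation.intervals if lab == label]


def _require(segmentation, label: PhaseLabel):
    ivs = _intervals_of(segmentation, label)
    if not ivs:
        raise MissingPhase(label)
    return ivs


def _highpass(x: np.ndarray, fs: float) -> np.ndarray:
    # Linear detrend + Gustafsson initial conditions: at 0.2 Hz the default
    # odd-reflection padding leaves multi-second edge transients that dominate
    # displacement ranges on short gait segments.
    b, a = sps.butter(_HP_ORDER, _HP_CUTOFF / (fs / 2.0), btype="highpass")
    if x.shape[0] <= 3 * max(len(a), len(b)):
        raise ValueError(f"segment too short for drift removal ({x.shape[0]} samples)")
    return sps.filtfilt(b, a, sps.detrend(x), method="gust")


def com_displacement(acceleration: np.ndarray, sample_rate: float) -> np.ndarray:
    """COM displacement (mm) from one acceleration axis (m/s^2).

    Trapezoidal integration to velocity, 0.2 Hz zero-lag high-pass, second
    integration to position, second high-pass.  The high-passes bound drift:
    constant acceleration offsets produce bounded output instead of
    quadratic growth.
    """
    a = np.asarray(acceleration, dtype=float)
    if a.shape[0] < int(_MIN_SEGMENT_S * sample_rate):
        raise ValueError(
            f"need at least {_MIN_SEGMENT_S} s of samples for COM integration")
    dt = 1.0 / sample_rate
    v = cumulative_trapezoid(a, dx=dt, initial=0.0)
    v = _highpass(v, sample_rate)
    d = cumulative_trapezoid(v, dx=dt, initial=0.0)
    d = _highpass(d, sample_rate)
    return d * 1000.0


def _swept_area(ml: np.ndarray, ap: np.ndarray) -> float:
    """Triangle-fan area (mm^2) of the ML-AP trajectory around its centroid."""
    cx, cy = ml.mean(), ap.mean()
    x, y = ml - cx, ap - cy
    cross = np.abs(x[:-1] * y[1:] - x[1:] * y[:-1])
    return float(0.5 * cross.sum())


def balance_features(rec: Recording, segmentation) -> tuple[float, float, float]:
    """(MLDisp, APDisp, DispA) over the BALANCE interval."""
    (s, e), *_ = _require(segmentation, PhaseLabel.BALANCE)
    fs = rec.sample_rate
    ml = com_displacement(rec.channel("acc_ml")[s:e], fs)
    ap = com_displacement(rec.channel("acc_ap")[s:e], fs)
    return (
        float(ml.max() - ml.min()),
        float(ap.max() - ap.min()),
        _swept_area(ml, ap),
    )


def gait_features(rec: Recording, segmentation) -> tuple[float, float]:
    """(VRange, MLRange): per-walk displacement ranges averaged over walks.

    Walk intervals shorter than the COM-integration minimum (1 s) are
    spurious segmentation fragments and are ignored.
    """
    walks = _require(segmentation, PhaseLabel.WALK)
    fs = rec.sample_rate
    walks = [(s, e) for s, e in walks if e - s >= int(_MIN_SEGMENT_S * fs)]
    if not walks:
        raise MissingPhase(PhaseLabel.WALK)
    vr, mr = [], []
    for s, e in walks:
        v = com_displacement(rec.channel("acc_v")[s:e], fs)
        m = com_displacement(rec.channel("acc_ml")[s:e], fs)
        vr.append(v.max() - v.min())
        mr.append(m.max() - m.min())
    return float(np.mean(vr)), float(np.mean(mr))


def _interval_velocity(a_v: np.ndarray, fs: float) -> np.ndarray:
    """Vertical velocity within a transfer interval.

    Single trapezoidal integration re-zeroed at the interval start, with a
    linear drift correction pinning the endpoint back to zero (transfers
    start and end at rest).
    """
    dt = 1.0 / fs
    v = cumulative_trapezoid(a_v, dx=dt, initial=0.0)
    n = v.shape[0]
    v = v - np.linspace(0.0, v[-1], n)
    return v


def _jerk_range(rec: Recording, s: int, e: int) -> float:
    """Max-min of the central-difference jerk of the acceleration magnitude."""
    acc = rec.data[s:e, :3]
    mag = np.linalg.norm(acc, axis=1)
    jerk = np.gradient(mag, 1.0 / rec.sample_rate)
    return float(jerk.max() - jerk.min())


def transfer_features(rec: Recording, segmentation, mass: float | None = None
                      ) -> tuple[float, float, float, float]:
    """(PTurnSit, PStand, JerkSit, JerkStand) from the chair transfers.

    Power is the Lindemann-style peak of instantaneous m*(a_v+g)*v within
    the interval, floored at zero; a_v is the gravity-free vertical
    acceleration.
    """
    m = rec.body_mass if mass is None else mass
    if m is None or m <= 0:
        raise ValueError("body mass must be positive for transfer power")
    (ts_s, ts_e), *_ = _require(segmentation, PhaseLabel.TURN_AND_SIT)
    (gu_s, gu_e), *_ = _require(segmentation, PhaseLabel.GET_UP)
    fs = rec.sample_rate
    a_v = rec.channel("acc_v")

    def peak_power(s, e):
        a = a_v[s:e]
        v = _interval_velocity(a, fs)
        p = m * (a + G) * v
        return float(max(p.max(), 0.0))

    return (
        peak_power(ts_s, ts_e),
        peak_power(gu_s, gu_e),
        _jerk_range(rec, ts_s, ts_e),
        _jerk_range(rec, gu_s, gu_e),
    )


def timing_features(rec: Recording, segmentation,
                    stimulus_time: float | None = None,
                    clip_negative_rtime: bool = False) -> tuple[float, float]:
    """(TTime, RTime) in seconds relative to the go stimulus.

    RTime is the onset of the first walk after the stimulus minus the
    stimulus time; TTime is the end of the final walk minus the stimulus
    time.  With ``clip_negative_rtime`` a slightly early predicted onset
    (boundary noise) is clipped to zero instead of raising.
    """
    stim = rec.stimulus_time if stimulus_time is None else stimulus_time
    if not (0 <= stim <= rec.duration):
        raise ValueError("stimulus time outside the recording")
    fs = rec.sample_rate
    walks = _require(segmentation, PhaseLabel.WALK)
    after = [(s, e) for s, e in walks if e / fs > stim]
    if not after:
        raise InvalidSegmentation("no WALK interval after the stimulus")
    first_start = after[0][0] / fs
    last_end = after[-1][1] / fs
    rtime = first_start - stim
    if rtime < 0:
        if clip_negative_rtime:
            rtime = 0.0
        else:
            raise InvalidSegmentation(
                f"first walk begins {-rtime:.2f} s before the stimulus")
    return float(last_end - stim), float(rtime)


def extract_features(rec: Recording, segmentation,
                     clip_negative_rtime: bool = False) -> BiomechFeatures:
    """All 11 variables from a filtered physical-unit recording + segmentation."""
    mldisp, apdisp, dispa = balance_features(rec, segmentation)
    vrange, mlrange = gait_features(rec, segmentation)
    pturnsit, pstand, jerksit, jerkstand = transfer_features(rec, segmentation)
    ttime, rtime = timing_features(
        rec, segmentation, clip_negative_rtime=clip_negative_rtime)
    return BiomechFeatures(
        MLDisp=mldisp, APDisp=apdisp, DispA=dispa,
        VRange=vrange, MLRange=mlrange,
        PTurnSit=pturnsit, PStand=pstand,
        JerkSit=jerksit, JerkStand=jerkstand,
        TTime=ttime, RTime=rtime,
    )


def features_table(rows: list[tuple[str, str | None, BiomechFeatures]]) -> pd.DataFrame:
    """One row per recording: subject_id, stage, then the 11 features."""
    records = []
    for sid, stage, feats in rows:
        rec = {"subject_id": sid, "stage": stage}
        rec.update({n: getattr(feats, n) for n in FEATURE_NAMES})
        records.append(rec)
    return pd.DataFrame.from_records(
        records, columns=["subject_id", "stage", *FEATURE_NAMES])


class FeatureScaler:
    """Min-max scaling of the feature table into [0, 1].

    Fit on training subjects only; out-of-range values at transform time
    clip to the unit interval.  Constant features map to 0.5.
    """

    def __init__(self):
        self.mins: np.ndarray | None = None
        self.maxs: np.ndarray | None = None

    def fit(self, table: np.ndarray) -> "FeatureScaler":
        table = np.asarray(table, dtype=float)
        self.mins = table.min(axis=0)
        self.maxs = table.max(axis=0)
        return self

    def transform(self, table: np.ndarray) -> np.ndarray:
        if self.mins is None:
            raise RuntimeError("FeatureScaler.transform before fit")
        table = np.asarray(table, dtype=float)
        span = self.maxs - self.mins
        out = np.empty_like(table)
        nz = span != 0
        out[:, nz] = (table[:, nz] - self.mins[nz]) / span[nz]
        out[:, ~nz] = 0.5
        return np.clip(out, 0.0, 1.0)

    def fit_transform(self, table: np.ndarray) -> np.ndarray:
        return self.fit(table).transform(table)


def scale_features(table: np.ndarray, scaler: FeatureScaler) -> np.ndarray:
    """Apply a fitted scaler (spec'd convenience wrapper)."""
    return scaler.transform(table)
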