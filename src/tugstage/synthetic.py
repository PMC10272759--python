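"""Synthetic modified-TUG cohort generator.

The clinical recordings behind the staging model are not publicly deposited,
so this module synthesizes phase-structured six-channel IMU trials with exact
ground-truth phase boundaries and Hoehn-Yahr stage labels.  Per-stage
parameter distributions (total time, reaction time, COM displacement ranges,
transfer powers, body mass) follow the published cohort statistics; the
waveform model itself is deliberately simple and *inverts the feature
definitions* of the biomechanics module:

* balance sway is band-limited (0.3-2 Hz) noise synthesized in the
  displacement domain and differentiated twice, so double integration
  recovers the drawn ML/AP displacement ranges;
* gait vertical motion is a sinusoidal COM displacement at the cadence
  frequency with peak-to-peak amplitude equal to the drawn vertical range;
* chair transfers carry half-sine vertical velocity pulses scaled so the
  peak of m*(a_v+g)*v matches the drawn transfer power;
* a 4-6 Hz tremor sinusoid with stage-increasing amplitude is added to the
  accelerometer channels;
* the turn carries a yaw-rate pulse, standing up a pitch-rate pulse, and
  quiet sitting a low-amplitude pitch wobble, giving every phase a signature
  a 0.64 s window can resolve.

Timing is constructed, not estimated: drawn total and reaction times are
quantized to the sample grid and the ground-truth boundaries are placed so
feature extraction recovers them exactly.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .phases import SCRIPTED_ORDER, PhaseLabel
from .recording import CHANNELS, Recording

G = 9.81  # m/s^2

STAGES = ("I", "II", "III")

#: Per-stage (mean, SD) parameter distributions of the reference cohort.
#: Units: times s, displacements mm, powers W, mass kg, tremor m/s^2 and Hz.
STAGE_DISTRIBUTIONS = {
    "I": {
        "ttime_s": (11.83, 1.52),
        "rtime_s": (1.03, 0.41),
        "vrange_mm": (28.34, 6.84),
        "mldisp_mm": (5.43, 2.65),
        "apdisp_mm": (18.44, 9.52),
        "mlrange_mm": (49.03, 16.81),
        "pturnsit_w": (111.66, 29.56),
        "pstand_w": (252.65, 97.75),
        "mass_kg": (72.36, 11.88),
        "tremor_amp": (0.05, 0.01),
        "tremor_hz": (5.0, 0.5),
    },
    "II": {
        "ttime_s": (14.34, 2.66),
        "rtime_s": (1.23, 0.49),
        "vrange_mm": (25.27, 6.58),
        "mldisp_mm": (8.86, 8.34),
        "apdisp_mm": (21.02, 8.57),
        "mlrange_mm": (45.12, 24.77),
        "pturnsit_w": (96.93, 50.27),
        "pstand_w": (236.76, 74.02),
        "mass_kg": (85.03, 18.72),
        "tremor_amp": (0.15, 0.03),
        "tremor_hz": (5.0, 0.5),
    },
    "III": {
        "ttime_s": (16.76, 4.24),
        "rtime_s": (1.23, 0.34),
        "vrange_mm": (21.22, 6.36),
        "mldisp_mm": (11.89, 8.81),
        "apdisp_mm": (27.07, 13.52),
        "mlrange_mm": (49.09, 26.60),
        "pturnsit_w": (65.33, 29.64),
        "pstand_w": (179.81, 76.59),
        "mass_kg": (66.75, 9.80),
        "tremor_amp": (0.30, 0.06),
        "tremor_hz": (5.0, 0.5),
    },
}

#: Fractions of the post-reaction active time allotted to each mobile phase.
PHASE_FRACTIONS = {
    PhaseLabel.WALK: 0.28,  # outbound walk
    PhaseLabel.TURN_AND_SIT: 0.22,
    PhaseLabel.SIT: 0.14,
    PhaseLabel.GET_UP: 0.12,
    # return walk receives the remainder (~0.24)
}

_MIN_PHASE_S = 0.7  # shortest admissible mobile phase; below the merge window would eat it
_MIN_ACTIVE_S = 6.5  # smallest stimulus-to-end span that fits five phases with jitter
_REDRAW_CAP = 100


@dataclass
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults reproduce the reference study's conditions: 21/30/36 subjects in
    stages I/II/III at 100 Hz with a 30 s balance phase, parameter
    distributions from the published per-stage statistics, cadence 2.0 Hz.
    ``difficulty`` scales every between-stage parameter gap around the grand
    mean (1.0 = published gaps) so separability can be varied explicitly.
    """

    counts: tuple = (21, 30, 36)
    sample_rate: float = 100.0
    balance_duration: float = 30.0
    cadence_hz: float = 2.0
    turn_yaw_peak: float = 1.5  # rad/s
    standup_pitch_peak: float = 1.0  # rad/s
    sit_pitch_wobble_sd: float = 0.08  # rad/s, quiet-sitting signature
    noise_sd: float = 0.005  # m/s^2 accelerometer white noise
    gyro_noise_sd: float = 0.01  # rad/s
    difficulty: float = 1.0
    include_gravity: bool = False
    seed: int = 0
    stage_params: dict = field(
        default_factory=lambda: copy.deepcopy(STAGE_DISTRIBUTIONS)
    )

    def __post_init__(self):
        if len(self.counts) != 3 or any(int(c) < 0 or c != int(c) for c in self.counts):
            raise ValueError("counts must be three non-negative integers")
        self.counts = tuple(int(c) for c in self.counts)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.balance_duration <= 0:
            raise ValueError("balance_duration must be positive")
        for stage, params in self.stage_params.items():
            for key, (mu, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {stage}/{key}")

    def effective_mean(self, stage: str, key: str) -> float:
        """Stage mean with the between-stage gap scaled by ``difficulty``."""
        grand = np.mean([self.stage_params[s][key][0] for s in STAGES])
        mu = self.stage_params[stage][key][0]
        return float(grand + self.difficulty * (mu - grand))


@dataclass
class GroundTruth:
    """Exact synthesis record for one trial.

    ``intervals`` are half-open (label, start, end) sample intervals tiling
    [0, N); ``stimulus_sample`` marks the auditory go cue (the BALANCE
    interval extends past it through the reaction gap, so it coincides with
    the end of balance only when the drawn reaction time is zero).
    """

    intervals: list
    stimulus_sample: int
    stage: str
    params: dict

    def labels(self, n_samples: int | None = None) -> np.ndarray:
        """Per-sample integer phase labels."""
        n = n_samples if n_samples is not None else self.intervals[-1][2]
        out = np.full(n, int(PhaseLabel.NOISE), dtype=np.int64)
        for label, start, end in self.intervals:
            out[start:end] = int(label)
        return out


def _draw_positive(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated below at 0.1*mean by rejection."""
    floor = 0.1 * mean
    for _ in range(_REDRAW_CAP):
        x = rng.normal(mean, sd)
        if x > floor:
            return float(x)
    raise RuntimeError(f"could not draw positive value for mean={mean}, sd={sd}")


def draw_subject_params(stage: str, spec: CohortSpec, rng: np.random.Generator) -> dict:
    """Draw one subject's generative parameters from the stage distributions.

    Times are quantized to the sample grid so that ground-truth boundaries
    reproduce them exactly.  Redraws (up to a cap) if the drawn timing leaves
    less than five minimum-length mobile phases after the reaction gap.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    fs = spec.sample_rate
    params = {}
    for key, (mu, sd) in spec.stage_params[stage].items():
        params[key] = _draw_positive(rng, spec.effective_mean(stage, key), sd)
    params["tremor_hz"] = float(np.clip(params["tremor_hz"], 4.0, 6.0))
    for _ in range(_REDRAW_CAP):
        ttime = _draw_positive(rng, spec.effective_mean(stage, "ttime_s"),
                               spec.stage_params[stage]["ttime_s"][1])
        rtime = _draw_positive(rng, spec.effective_mean(stage, "rtime_s"),
                               spec.stage_params[stage]["rtime_s"][1])
        ttime = round(ttime * fs) / fs
        rtime = round(rtime * fs) / fs
        if ttime - rtime >= _MIN_ACTIVE_S:
            params["ttime_s"] = ttime
            params["rtime_s"] = rtime
            break
    else:
        raise RuntimeError("could not draw an admissible (TTime, RTime) pair")
    return params


def _band_limited_displacement(rng, n, fs, target_range_mm, lo=0.3, hi=2.0):
    """Zero-mean displacement (m) with max-min equal to target_range_mm."""
    if target_range_mm <= 0 or n < 16:
        return np.zeros(n)
    x = rng.standard_normal(n + 400)
    nyq = fs / 2
    b, a = sps.butter(2, [lo / nyq, hi / nyq], btype="bandpass")
    d = sps.filtfilt(b, a, x)[200:-200]
    rng_now = d.max() - d.min()
    if rng_now <= 0:
        return np.zeros(n)
    d = d * (target_range_mm / 1000.0 / rng_now)
    # cosine taper so sway stops smoothly at the phase boundary
    t_len = min(50, n // 4)
    if t_len > 1:
        taper = 0.5 * (1 - np.cos(np.linspace(0, np.pi, t_len)))
        d[:t_len] *= taper
        d[-t_len:] *= taper[::-1]
    return d


def _second_derivative(d: np.ndarray, fs: float) -> np.ndarray:
    return np.gradient(np.gradient(d, 1.0 / fs), 1.0 / fs)


def _velocity_pulse_for_power(n, fs, target_w, mass):
    """Half-sine vertical velocity pulse whose Lindemann-style peak power
    max m*(dv/dt + g)*v matches target_w; returns (velocity, acceleration)."""
    t = np.arange(n) / fs
    vu = np.sin(np.pi * t / (n / fs))  # unit half-sine
    au = np.gradient(vu, 1.0 / fs)
    scale = target_w / (mass * G)  # g-dominated first guess
    for _ in range(3):  # fixed-point refinement of the a*v term
        p = mass * (au * scale + G) * (vu * scale)
        peak = p.max()
        if peak <= 0:
            break
        scale *= target_w / peak
    return vu * scale, au * scale


def generate_trial(stage: str, subject_params: dict, seed: int,
                   spec: CohortSpec | None = None,
                   subject_id: str = "S000") -> tuple[Recording, GroundTruth]:
    """Synthesize one trial; bit-reproducible given (stage, params, seed).

    ``subject_params`` must contain ``mass_kg`` plus the drawn per-subject
    parameters (see :func:`draw_subject_params`).
    """
    spec = spec or CohortSpec()
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    fs = spec.sample_rate
    rng = np.random.default_rng(seed)
    p = subject_params

    ttime, rtime = p["ttime_s"], p["rtime_s"]
    if ttime <= 0 or rtime < 0 or ttime <= rtime:
        raise ValueError("drawn durations must satisfy TTime > RTime >= 0")

    n_stim = round(spec.balance_duration * fs)
    n_rt = round(rtime * fs)
    n_active = round(ttime * fs) - n_rt
    if n_active < round(_MIN_ACTIVE_S * fs):
        raise ValueError("active time too short to script five phases")

    # carve the active span into the five mobile phases: jittered nominal
    # fractions, renormalized, rounded, minimum length enforced, and the
    # rounding residual absorbed by the longest phase
    n_min = round(_MIN_PHASE_S * fs)
    fracs = np.array([PHASE_FRACTIONS[PhaseLabel.WALK],
                      PHASE_FRACTIONS[PhaseLabel.TURN_AND_SIT],
                      PHASE_FRACTIONS[PhaseLabel.SIT],
                      PHASE_FRACTIONS[PhaseLabel.GET_UP],
                      1.0 - sum(PHASE_FRACTIONS.values())])
    fracs = fracs * rng.uniform(0.9, 1.1, size=5)
    fracs /= fracs.sum()
    lengths = np.maximum(np.round(fracs * n_active).astype(int), n_min)
    lengths[int(np.argmax(lengths))] += n_active - lengths.sum()
    if lengths.min() < n_min:
        raise ValueError("active time too short to script five phases")

    bounds = [0, n_stim + n_rt]
    for ln in lengths:
        bounds.append(bounds[-1] + int(ln))
    n_total = bounds[-1]
    intervals = [
        (lab, bounds[i], bounds[i + 1]) for i, lab in enumerate(SCRIPTED_ORDER)
    ]

    data = np.zeros((n_total, len(CHANNELS)), dtype=float)
    acc_ap, acc_ml, acc_v = (data[:, i] for i in range(3))
    gyr_yaw, gyr_pitch, gyr_roll = (data[:, i] for i in range(3, 6))
    t_all = np.arange(n_total) / fs

    # --- balance sway (covers stance through the reaction gap) ---
    b0, b1 = intervals[0][1], intervals[0][2]
    acc_ml[b0:b1] += _second_derivative(
        _band_limited_displacement(rng, b1 - b0, fs, p.get("mldisp_mm", 0.0)), fs)
    acc_ap[b0:b1] += _second_derivative(
        _band_limited_displacement(rng, b1 - b0, fs, p.get("apdisp_mm", 0.0)), fs)

    # --- the two walks: sinusoidal COM displacement at cadence ---
    # Amplitudes are calibrated against the double-integration operator the
    # feature extractor uses, so the drawn ranges are recovered unbiasedly
    # despite its short-segment filter response.
    from .biomech import com_displacement

    def _gait_component(n, freq, range_mm):
        if range_mm <= 0:
            return np.zeros(n)
        tr = np.arange(n) / fs
        a = -(range_mm / 2e3) * (2 * np.pi * freq) ** 2 * np.sin(
            2 * np.pi * freq * tr)
        recovered = np.ptp(com_displacement(a, fs))
        return a * (range_mm / recovered) if recovered > 0 else a

    for lab, s, e in intervals:
        if lab is not PhaseLabel.WALK:
            continue
        acc_v[s:e] += _gait_component(e - s, spec.cadence_hz,
                                      p.get("vrange_mm", 0.0))
        acc_ml[s:e] += _gait_component(e - s, spec.cadence_hz / 2.0,
                                       p.get("mlrange_mm", 0.0))

    # --- turn + sit-down: yaw pulse then a powered vertical transfer ---
    _, ts_s, ts_e = intervals[2]
    n_ts = ts_e - ts_s
    n_turn = int(0.6 * n_ts)
    tt = np.arange(n_turn) / fs
    gyr_yaw[ts_s:ts_s + n_turn] += spec.turn_yaw_peak * np.sin(
        np.pi * tt / (n_turn / fs))
    n_sitp = n_ts - n_turn
    if p.get("pturnsit_w", 0.0) > 0:
        _, a_pulse = _velocity_pulse_for_power(
            n_sitp, fs, p["pturnsit_w"], p["mass_kg"])
        acc_v[ts_s + n_turn:ts_e] += a_pulse

    # --- quiet sitting: pitch wobble signature ---
    _, si_s, si_e = intervals[3]
    if spec.sit_pitch_wobble_sd > 0 and si_e - si_s > 16:
        w = _band_limited_displacement(rng, si_e - si_s, fs, 1.0, lo=0.5, hi=3.0)
        w = w / max(w.std(), 1e-12) * spec.sit_pitch_wobble_sd
        gyr_pitch[si_s:si_e] += w

    # --- stand up: pitch pulse + powered vertical transfer ---
    _, gu_s, gu_e = intervals[4]
    n_gu = gu_e - gu_s
    tg = np.arange(n_gu) / fs
    gyr_pitch[gu_s:gu_e] += spec.standup_pitch_peak * np.sin(
        np.pi * tg / (n_gu / fs))
    if p.get("pstand_w", 0.0) > 0:
        _, a_pulse = _velocity_pulse_for_power(n_gu, fs, p["pstand_w"], p["mass_kg"])
        acc_v[gu_s:gu_e] += a_pulse

    # --- tremor on accelerometer channels, whole recording ---
    amp = p.get("tremor_amp", 0.0)
    if amp > 0:
        f_tr = p.get("tremor_hz", 5.0)
        for ch in (acc_ap, acc_ml, acc_v):
            ch += amp * np.sin(2 * np.pi * f_tr * t_all + rng.uniform(0, 2 * np.pi))

    # --- sensor noise ---
    if spec.noise_sd > 0:
        data[:, :3] += rng.normal(0, spec.noise_sd, size=(n_total, 3))
    if spec.gyro_noise_sd > 0:
        data[:, 3:] += rng.normal(0, spec.gyro_noise_sd, size=(n_total, 3))
    if spec.include_gravity:
        acc_v += G

    rec = Recording(
        subject_id=subject_id,
        data=data,
        sample_rate=fs,
        body_mass=p["mass_kg"],
        stimulus_time=n_stim / fs,
        stage=stage,
    )
    gt = GroundTruth(
        intervals=intervals,
        stimulus_sample=n_stim,
        stage=stage,
        params=dict(p),
    )
    return rec, gt


def generate_cohort(spec: CohortSpec) -> list[tuple[Recording, GroundTruth]]:
    """Generate the full cohort with per-stage counts from ``spec``.

    Subject seeds derive deterministically from the master seed, so equal
    specs yield byte-identical cohorts.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_subjects = sum(spec.counts)
    child_seeds = ss.generate_state(2 * n_subjects) % (2 ** 31)
    cohort = []
    idx = 0
    for stage, count in zip(STAGES, spec.counts):
        for _ in range(count):
            draw_rng = np.random.default_rng(int(child_seeds[2 * idx]))
            params = draw_subject_params(stage, spec, draw_rng)
            sid = f"S{idx + 1:03d}"
            rec, gt = generate_trial(
                stage, params, int(child_seeds[2 * idx + 1]), spec, subject_id=sid)
            cohort.append((rec, gt))
            idx += 1
    return cohort


# ---------------------------------------------------------------------------
# Trial exchange format: CSV signal matrix + JSON sidecar.
# ---------------------------------------------------------------------------

def write_trial(out_dir, rec: Recording, gt: GroundTruth | None = None) -> Path:
    """Write one trial as ``<subject_id>.csv`` (+ ``.json`` sidecar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{rec.subject_id}.csv"
    t = np.arange(rec.n_samples) / rec.sample_rate
    header = "time_s," + ",".join(rec.channel_names)
    np.savetxt(csv_path, np.column_stack([t, rec.data]), delimiter=",",
               header=header, comments="", fmt="%.6f")
    sidecar = {
        "subject_id": rec.subject_id,
        "stage": rec.stage,
        "mass_kg": rec.body_mass,
        "sample_rate": rec.sample_rate,
        "stimulus_time_s": rec.stimulus_time,
    }
    if gt is not None:
        sidecar["intervals"] = [
            {"label": PhaseLabel(lab).name, "start": int(s), "end": int(e)}
            for lab, s, e in gt.intervals
        ]
        sidecar["stimulus_sample"] = int(gt.stimulus_sample)
        sidecar["params"] = {k: float(v) for k, v in gt.params.items()}
    with open(out_dir / f"{rec.subject_id}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return csv_path


def read_trial(csv_path) -> tuple[Recording, GroundTruth | None]:
    """Read a trial written by :func:`write_trial` (or the same format)."""
    csv_path = Path(csv_path)
    try:
        arr = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    except ValueError as exc:
        raise ValueError(f"malformed trial CSV {csv_path.name}: {exc}") from exc
    if arr.ndim != 2 or arr.shape[1] != len(CHANNELS) + 1:
        raise ValueError(
            f"malformed trial CSV {csv_path.name}: expected {len(CHANNELS) + 1} "
            f"columns, got {arr.shape[1] if arr.ndim == 2 else 'ragged rows'}")
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {csv_path.name}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    rec = Recording(
        subject_id=meta["subject_id"],
        data=arr[:, 1:],
        sample_rate=float(meta["sample_rate"]),
        body_mass=float(meta["mass_kg"]),
        stimulus_time=float(meta["stimulus_time_s"]),
        stage=meta.get("stage"),
    )
    gt = None
    if "intervals" in meta:
        gt = GroundTruth(
            intervals=[(PhaseLabel[iv["label"]], iv["start"], iv["end"])
                       for iv in meta["intervals"]],
            stimulus_sample=int(meta["stimulus_sample"]),
            stage=meta.get("stage"),
            params=meta.get("params", {}),
        )
    return rec, gt


def read_cohort(directory) -> list[tuple[Recording, GroundTruth | None]]:
    directory = Path(directory)
    return [read_trial(p) for p in sorted(directory.glob("*.csv"))]
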