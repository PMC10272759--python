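"""The in-memory container for one subject's six-channel IMU trial."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed channel convention: accelerometer (anterior-posterior, medial-lateral,
#: vertical; m/s^2, V positive upward, gravity-free by default) followed by
#: gyroscope (yaw, pitch, roll; rad/s).
CHANNELS = ("acc_ap", "acc_ml", "acc_v", "gyr_yaw", "gyr_pitch", "gyr_roll")


@dataclass
class Recording:
    """One subject's trial: an (N, 6) signal matrix plus metadata.

    Parameters
    ----------
    subject_id : str
        Unique subject/trial identifier.
    data : ndarray, shape (N, 6)
        Channel matrix in the :data:`CHANNELS` order, physical units.
    sample_rate : float
        Sampling frequency in Hz (100 after standardization).
    body_mass : float
        Subject mass in kg, used by the transfer-power features.
    stimulus_time : float
        Time of the auditory go stimulus in seconds from recording start.
    stage : str or None
        Hoehn-Yahr stage label ("I", "II", "III") when known.
    """

    subject_id: str
    data: np.ndarray
    sample_rate: float
    body_mass: float
    stimulus_time: float
    stage: str | None = None
    channel_names: tuple = field(default=CHANNELS)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"expected (N, {len(self.channel_names)}) channel matrix, "
                f"got {self.data.shape}"
            )
        if np.isnan(self.data).any():
            raise ValueError("recording contains missing values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channel_names.index(name)]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(
            subject_id=self.subject_id,
            data=data,
            sample_rate=self.sample_rate,
            body_mass=self.body_mass,
            stimulus_time=self.stimulus_time,
            stage=self.stage,
            channel_names=self.channel_names,
        )
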