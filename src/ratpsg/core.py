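"""Core domain objects: vigilance states, the light/dark schedule,
hypnograms, and raw telemetry recordings.

Conventions used throughout the package:

* Vigilance states are integer-coded: 0 = wake, 1 = NREM, 2 = REM.
* The scoring epoch is fixed at 10 s.
* Zeitgeber time (ZT) is hours since lights-on, modulo the period;
  ZT [0, 12) is the light (rest) phase, [12, 24) the dark (active) phase.
* All intervals are half-open; epoch indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WAKE, NREM, REM = 0, 1, 2
STATE_NAMES = ("WAKE", "NREM", "REM")
STATE_CODES = {name: code for code, name in enumerate(STATE_NAMES)}
N_STATES = 3

#: Scoring epoch length in seconds.
EPOCH_S = 10.0
#: Epochs per hour on the 10-s grid.
EPOCHS_PER_HOUR = 360


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class LightDarkSchedule:
    """A rectangular light/dark cycle referenced to zeitgeber time.

    Lights-on defines ZT 0; ``lights_off_zt`` hours later the dark phase
    begins and lasts until the period wraps.
    """

    lights_on_zt: float = 0.0
    lights_off_zt: float = 12.0
    period: float = 24.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValidationError(f"period must be positive, got {self.period}")
        if not (0 <= self.lights_off_zt < self.period):
            raise ValidationError(
                f"lights_off_zt must lie in [0, {self.period}), got {self.lights_off_zt}"
            )

    def is_light(self, zt: np.ndarray | float) -> np.ndarray | bool:
        """True where ZT falls in the light phase [lights_on, lights_off)."""
        z = np.asarray(zt) % self.period
        return (z >= self.lights_on_zt) & (z < self.lights_off_zt)

    def phase_of(self, zt: np.ndarray | float):
        """'light' or 'dark' (elementwise for arrays)."""
        light = self.is_light(zt)
        if np.isscalar(light) or light.ndim == 0:
            return "light" if light else "dark"
        return np.where(light, "light", "dark")


def wrap_zt(zt, period: float = 24.0):
    """Reduce zeitgeber time into [0, period)."""
    return np.asarray(zt) % period


def zt_in_window(zt, start: float, end: float, period: float = 24.0):
    """Membership of ZT values in a possibly wrapping half-open ZT window."""
    z = np.asarray(zt) % period
    s, e = start % period, end % period
    if s == e:  # full-period window
        return np.ones_like(z, dtype=bool)
    if s < e:
        return (z >= s) & (z < e)
    return (z >= s) | (z < e)


@dataclass
class Hypnogram:
    """Per-epoch vigilance-state labels on the fixed 10-s grid."""

    labels: np.ndarray
    start_zt: float = 0.0
    epoch_s: float = EPOCH_S

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValidationError("hypnogram labels must be a nonempty 1-D sequence")
        if not np.isin(self.labels, (WAKE, NREM, REM)).all():
            bad = set(np.unique(self.labels)) - {WAKE, NREM, REM}
            raise ValidationError(f"unknown state codes in hypnogram: {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def duration_h(self) -> float:
        return self.labels.size * self.epoch_s / 3600.0

    def epoch_zt(self) -> np.ndarray:
        """ZT (hours, in [0, 24)) at the start of each epoch."""
        return (self.start_zt + np.arange(self.labels.size) * self.epoch_s / 3600.0) % 24.0

    def state_names(self) -> np.ndarray:
        return np.array(STATE_NAMES)[self.labels]


@dataclass
class Recording:
    """Raw multichannel telemetry with zeitgeber alignment.

    EEG and EMG are continuous µV traces at ``sampling_rate``; activity
    (counts) and core temperature (°C) are epoch-level side channels with
    one value per 10-s epoch. ``temperature`` may be None when the channel
    was not recorded.
    """

    eeg: np.ndarray
    emg: np.ndarray
    sampling_rate: float
    activity: np.ndarray
    temperature: np.ndarray | None = None
    start_zt: float = 0.0
    subject_id: str = "subject"
    treatment_label: str = "vehicle"
    prenatal_label: str = "control"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=np.float32)
        self.emg = np.asarray(self.emg, dtype=np.float32)
        if self.eeg.shape != self.emg.shape:
            raise ValidationError(
                f"EEG and EMG lengths differ: {self.eeg.size} vs {self.emg.size}"
            )
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        n_ep = int(self.eeg.size // (EPOCH_S * self.sampling_rate))
        self.activity = np.asarray(self.activity, dtype=np.float64)
        if self.activity.size != n_ep:
            raise ValidationError(
                f"activity has {self.activity.size} rows but the signals span "
                f"{n_ep} complete 10-s epochs"
            )
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=np.float64)
            if self.temperature.size != n_ep:
                raise ValidationError(
                    f"temperature has {self.temperature.size} rows but the signals "
                    f"span {n_ep} complete 10-s epochs"
                )

    @property
    def n_samples(self) -> int:
        return int(self.eeg.size)

    @property
    def duration_s(self) -> float:
        return self.eeg.size / self.sampling_rate

    @property
    def n_epochs(self) -> int:
        return int(self.duration_s // EPOCH_S)
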