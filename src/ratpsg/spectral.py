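"""State- and phase-resolved EEG power spectra and band powers.

Spectra are means, over the epochs of one vigilance state within one
light/dark phase, of the 40 normalized 0.5-Hz channel powers produced by
the featurizer — i.e. fractions of each epoch's total 0–20 Hz power, so
a profile's mass is <= 1 (the DC bin is excluded by default). The
conventional rodent EEG bands partition (0.5, 20) Hz:

    delta 0.5–4 Hz, theta 4–8 Hz, alpha 8–12 Hz, sigma 12–16 Hz,
    beta 16–20 Hz  (all half-open [lo, hi))

Band power is the sum of the channels whose centers fall in the band;
channel 0 ([0, 0.5) Hz) is the sub-delta residual. Treatment contrasts
are per-channel differences of matched profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ratpsg.core import (
    Hypnogram,
    LightDarkSchedule,
    ValidationError,
)
from ratpsg.features import CHANNEL_WIDTH_HZ, N_CHANNELS

#: 0.5-Hz channel centers (0.25, 0.75, ..., 19.75 Hz).
CHANNEL_CENTERS_HZ = (np.arange(N_CHANNELS) + 0.5) * CHANNEL_WIDTH_HZ


@dataclass(frozen=True)
class Band:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo_hz < self.hi_hz <= 20.0):
            raise ValidationError(
                f"band {self.name} [{self.lo_hz}, {self.hi_hz}) outside the "
                "0-20 Hz analysis range"
            )

    def channel_mask(self) -> np.ndarray:
        return (CHANNEL_CENTERS_HZ >= self.lo_hz) & (CHANNEL_CENTERS_HZ < self.hi_hz)


DELTA = Band("delta", 0.5, 4.0)
THETA = Band("theta", 4.0, 8.0)
ALPHA = Band("alpha", 8.0, 12.0)
SIGMA = Band("sigma", 12.0, 16.0)
BETA = Band("beta", 16.0, 20.0)
BANDS = (DELTA, THETA, ALPHA, SIGMA, BETA)
#: The sub-delta remainder, [0, 0.5) Hz.
RESIDUAL = Band("sub_delta", 0.0, 0.5)


@dataclass
class SpectralProfile:
    state: str
    phase: str
    bin_centers_hz: np.ndarray
    mean_power: np.ndarray
    n_epochs: int


def state_phase_spectrum(
    features: np.ndarray,
    hypnogram: Hypnogram,
    state: int,
    phase: str,
    schedule: LightDarkSchedule | None = None,
) -> SpectralProfile:
    """Mean normalized channel powers over epochs of ``state`` in ``phase``."""
    from ratpsg.core import STATE_NAMES

    schedule = schedule if schedule is not None else LightDarkSchedule()
    features = np.asarray(features, dtype=float)
    if features.shape[0] != hypnogram.n_epochs:
        raise ValidationError(
            f"features ({features.shape[0]} epochs) and hypnogram "
            f"({hypnogram.n_epochs}) are not aligned"
        )
    light = np.asarray(schedule.is_light(hypnogram.epoch_zt()))
    in_phase = light if phase == "light" else ~light
    mask = (hypnogram.labels == state) & in_phase
    if not mask.any():
        raise ValidationError(
            f"no {STATE_NAMES[state]} epochs in the {phase} phase"
        )
    return SpectralProfile(
        state=STATE_NAMES[state],
        phase=phase,
        bin_centers_hz=CHANNEL_CENTERS_HZ.copy(),
        mean_power=features[mask, :N_CHANNELS].mean(axis=0),
        n_epochs=int(mask.sum()),
    )


def band_power(profile: SpectralProfile, band: Band) -> float:
    """Sum of the profile's channels whose centers fall in the band."""
    return float(profile.mean_power[band.channel_mask()].sum())


def band_powers(profile: SpectralProfile) -> dict:
    """All five conventional bands plus the sub-0.5 Hz residual."""
    out = {b.name: band_power(profile, b) for b in BANDS}
    out[RESIDUAL.name] = band_power(profile, RESIDUAL)
    return out


def spectral_contrast(
    treated: SpectralProfile, vehicle: SpectralProfile
) -> pd.DataFrame:
    """Per-channel treated - vehicle difference of matched profiles."""
    if treated.state != vehicle.state or treated.phase != vehicle.phase:
        raise ValidationError(
            f"profiles differ in state/phase: {treated.state}/{treated.phase} "
            f"vs {vehicle.state}/{vehicle.phase}"
        )
    if not np.array_equal(treated.bin_centers_hz, vehicle.bin_centers_hz):
        raise ValidationError("profiles are on different frequency grids")
    return pd.DataFrame(
        {
            "bin_hz": treated.bin_centers_hz,
            "difference": treated.mean_power - vehicle.mean_power,
        }
    )


def profile_frame(
    profile: SpectralProfile,
    subject: str = "",
    treatment: str = "",
) -> pd.DataFrame:
    """Tidy one-row-per-channel table for a profile."""
    return pd.DataFrame(
        {
            "subject": subject,
            "treatment": treatment,
            "state": profile.state,
            "phase": profile.phase,
            "bin_hz": profile.bin_centers_hz,
            "power_fraction": profile.mean_power,
            "n_epochs": profile.n_epochs,
        }
    )
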