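"""Synthetic telemetry generator.

Vigilance-state dynamics are a first-order Markov chain on the 10-s epoch
grid with separate transition matrices for the light and dark phases, so
the simulated animal sleeps mostly in the light (rest) phase, as rats do.
Given a state sequence, the signal synthesizer emits:

* EEG: a sum of band-limited Gaussian noise components (delta, theta,
  alpha, sigma, beta), weighted per-epoch by the state's relative band
  powers and scaled to the state's RMS amplitude — wake is low-amplitude /
  high-frequency, NREM high-amplitude / delta-dominant, REM low-amplitude /
  theta-dominant;
* EMG: white noise at a state RMS with wake > NREM > REM (REM atonia);
* activity: a per-epoch Poisson count, nonzero only in wake;
* core temperature: a cosinor (mesor + circadian cosine) plus noise.

An optional treatment effect emulates a somnogenic drug inside a ZT
window: wake→sleep transition probabilities are multiplied up, NREM delta
weight is boosted, activity is scaled down, and temperature offset.

All default rates, dwell times, occupancies and amplitudes are this
package's own choices of realistic rat polysomnography values; they are
free parameters, not measurements (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from ratpsg.core import (
    EPOCH_S,
    EPOCHS_PER_HOUR,
    N_STATES,
    NREM,
    REM,
    WAKE,
    Hypnogram,
    LightDarkSchedule,
    Recording,
    ValidationError,
    zt_in_window,
)

BAND_EDGES_HZ = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 20.0),
}
BAND_ORDER = tuple(BAND_EDGES_HZ)

# Default per-epoch transition matrices (rows/cols: wake, NREM, REM).
# Built from mean dwell times of 2 min wake / 3 min NREM / 1.5 min REM in
# the light phase (stationary occupancy ≈ 35/55/10 %) and 5 min wake /
# 2 min NREM / 1.5 min REM in the dark (≈ 65/30/5 %). REM is entered only
# from NREM.
DEFAULT_LIGHT_MATRIX = np.array(
    [
        [1 - 1 / 12, 1 / 12, 0.0],
        [7 / 198, 1 - 1 / 18, 4 / 198],
        [7 / 72, 1 / 72, 1 - 1 / 9],
    ]
)
DEFAULT_DARK_MATRIX = np.array(
    [
        [1 - 1 / 30, 1 / 30, 0.0],
        [7 / 108, 1 - 1 / 12, 2 / 108],
        [2 / 45, 1 / 15, 1 - 1 / 9],
    ]
)


def _check_stochastic(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (N_STATES, N_STATES):
        raise ValidationError(f"{name} must be 3x3, got shape {m.shape}")
    if (m < 0).any():
        raise ValidationError(f"{name} has negative entries")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
        raise ValidationError(f"{name} rows must sum to 1 (got {m.sum(axis=1)})")
    return m


@dataclass
class StateTransitionModel:
    """Phase-dependent per-epoch Markov transition model."""

    light_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_LIGHT_MATRIX.copy())
    dark_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_DARK_MATRIX.copy())
    initial_state: int = WAKE

    def __post_init__(self) -> None:
        self.light_matrix = _check_stochastic(self.light_matrix, "light_matrix")
        self.dark_matrix = _check_stochastic(self.dark_matrix, "dark_matrix")
        if self.initial_state not in (WAKE, NREM, REM):
            raise ValidationError(f"unknown initial state {self.initial_state}")

    def mean_dwell_epochs(self, phase: str = "light") -> np.ndarray:
        """Geometric mean dwell time 1/(1-p_stay) per state, in epochs."""
        m = self.light_matrix if phase == "light" else self.dark_matrix
        return 1.0 / (1.0 - np.diag(m))


@dataclass
class SignalModel:
    """Per-state signal phenomenology for the synthesizer.

    Band weights are relative power fractions over (delta, theta, alpha,
    sigma, beta); amplitudes are µV RMS. Activity is a Poisson rate per
    10-s epoch, spent only in wake; temperature follows a cosinor with
    acrophase in the dark phase.
    """

    band_weights: dict = field(
        default_factory=lambda: {
            WAKE: np.array([0.15, 0.30, 0.25, 0.15, 0.15]),
            NREM: np.array([0.60, 0.18, 0.10, 0.07, 0.05]),
            REM: np.array([0.15, 0.55, 0.15, 0.10, 0.05]),
        }
    )
    eeg_amplitude_uv: dict = field(
        default_factory=lambda: {WAKE: 50.0, NREM: 120.0, REM: 60.0}
    )
    emg_amplitude_uv: dict = field(
        default_factory=lambda: {WAKE: 60.0, NREM: 20.0, REM: 5.0}
    )
    activity_rate_by_phase: dict = field(
        default_factory=lambda: {"light": 2.0, "dark": 6.0}
    )
    temperature_mesor_c: float = 37.2
    temperature_amplitude_c: float = 0.5
    temperature_acrophase_zt: float = 18.0
    temperature_noise_c: float = 0.1
    band_filter_order: int = 8

    def __post_init__(self) -> None:
        for s, w in self.band_weights.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (5,) or (w < 0).any():
                raise ValidationError(f"band weights for state {s} must be 5 nonnegative values")
            if not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
                raise ValidationError(f"band weights for state {s} must sum to 1, got {w.sum()}")
            self.band_weights[s] = w
        emg = self.emg_amplitude_uv
        if not (emg[REM] < emg[NREM] < emg[WAKE]):
            raise ValidationError(
                "EMG amplitudes must be ordered REM < NREM < WAKE "
                f"(got {emg[REM]}, {emg[NREM]}, {emg[WAKE]})"
            )


@dataclass
class TreatmentEffect:
    """Directional drug-effect knobs applied inside a ZT window."""

    sleep_propensity_multiplier: float = 2.0
    delta_power_multiplier: float = 1.3
    activity_multiplier: float = 0.7
    temperature_offset_c: float = -0.4
    effect_window_zt: tuple = (0.0, 12.0)

    def __post_init__(self) -> None:
        if self.sleep_propensity_multiplier < 0:
            raise ValidationError("sleep_propensity_multiplier must be >= 0")
        if self.delta_power_multiplier <= 0 or self.activity_multiplier <= 0:
            raise ValidationError("power/activity multipliers must be > 0")

    def applies_at(self, zt) -> np.ndarray:
        return zt_in_window(zt, *self.effect_window_zt)

    def modify_matrix(self, matrix: np.ndarray) -> np.ndarray:
        """Scale wake→sleep probabilities and renormalize the wake row."""
        m = matrix.astype(float).copy()
        m[WAKE, NREM] *= self.sleep_propensity_multiplier
        m[WAKE, REM] *= self.sleep_propensity_multiplier
        m[WAKE] /= m[WAKE].sum()
        return m


@dataclass
class SimulatedRecording:
    """A synthesized recording paired with its ground-truth hypnogram."""

    recording: Recording
    truth_hypnogram: Hypnogram
    seed: int


def simulate_state_sequence(
    model: StateTransitionModel | None = None,
    schedule: LightDarkSchedule | None = None,
    duration_h: float = 24.0,
    treatment: TreatmentEffect | None = None,
    seed: int = 0,
    start_zt: float = 0.0,
) -> Hypnogram:
    """Draw a vigilance-state sequence from the phase-dependent Markov chain.

    One state per 10-s epoch; ``duration_h`` must be a positive multiple of
    the epoch. Epochs whose ZT lies in the treatment effect window use the
    treatment-modified matrix. Sampling is by inverse CDF on a per-epoch
    uniform stream, so a treatment arm run with the same seed shares its
    random numbers with the untreated arm (common-random-number coupling).
    """
    model = model if model is not None else StateTransitionModel()
    schedule = schedule if schedule is not None else LightDarkSchedule()
    n_epochs_f = duration_h * 3600.0 / EPOCH_S
    if duration_h <= 0 or abs(n_epochs_f - round(n_epochs_f)) > 1e-9:
        raise ValidationError(
            f"duration must be a positive multiple of the {EPOCH_S:.0f}-s epoch, "
            f"got {duration_h} h"
        )
    n_epochs = int(round(n_epochs_f))

    zt = (start_zt + np.arange(n_epochs) * EPOCH_S / 3600.0) % schedule.period
    light = np.asarray(schedule.is_light(zt))
    treated = (
        np.asarray(treatment.applies_at(zt)) if treatment is not None
        else np.zeros(n_epochs, dtype=bool)
    )

    # 4 matrix variants: (phase, treated) -> cumulative rows
    variants = {}
    for is_light in (False, True):
        base = model.light_matrix if is_light else model.dark_matrix
        for is_treated in (False, True):
            m = treatment.modify_matrix(base) if (is_treated and treatment) else base
            variants[(is_light, is_treated)] = np.cumsum(m, axis=1)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    u = rng.random(n_epochs)
    labels = np.empty(n_epochs, dtype=np.int8)
    state = model.initial_state
    for i in range(n_epochs):
        cum = variants[(bool(light[i]), bool(treated[i]))]
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, N_STATES - 1)  # guard fp roundoff at u ~ 1
        labels[i] = state
    return Hypnogram(labels=labels, start_zt=start_zt)


def _band_sos(lo: float, hi: float, fs: float, order: int):
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def synthesize_signals(
    hypnogram: Hypnogram,
    signal_model: SignalModel | None = None,
    schedule: LightDarkSchedule | None = None,
    sampling_rate: float = 250.0,
    treatment: TreatmentEffect | None = None,
    seed: int = 0,
    subject_id: str = "sim",
    treatment_label: str | None = None,
    prenatal_label: str = "control",
) -> SimulatedRecording:
    """Render EEG/EMG/activity/temperature for a given hypnogram.

    Each of the five EEG bands is band-limited Gaussian noise (Butterworth
    filter on white noise, normalized to unit RMS); per epoch the bands are
    combined with sqrt(state band weight) coefficients and scaled to the
    state RMS amplitude. Inside the treatment window the NREM delta weight
    is multiplied by ``delta_power_multiplier`` (weights renormalized).
    """
    signal_model = signal_model if signal_model is not None else SignalModel()
    schedule = schedule if schedule is not None else LightDarkSchedule()
    if sampling_rate < 40.0:
        raise ValidationError(
            f"sampling_rate must be >= 40 Hz for the 20 Hz analysis ceiling, got {sampling_rate}"
        )
    spe_f = EPOCH_S * sampling_rate
    if abs(spe_f - round(spe_f)) > 1e-9:
        raise ValidationError("sampling_rate must give an integer number of samples per epoch")
    spe = int(round(spe_f))
    n_epochs = hypnogram.n_epochs
    n_samples = n_epochs * spe

    root = np.random.SeedSequence(seed)
    ss_eeg, ss_emg, ss_act, ss_temp = root.spawn(4)

    zt = hypnogram.epoch_zt()
    labels = hypnogram.labels
    treated = (
        np.asarray(treatment.applies_at(zt)) if treatment is not None
        else np.zeros(n_epochs, dtype=bool)
    )

    # Per-epoch band weights, with the delta boost inside the effect window.
    weights = np.stack([signal_model.band_weights[s] for s in (WAKE, NREM, REM)])
    w_epoch = weights[labels]  # (n_epochs, 5)
    if treatment is not None and treatment.delta_power_multiplier != 1.0:
        boost = treated & (labels == NREM)
        w = w_epoch[boost]
        w[:, 0] *= treatment.delta_power_multiplier
        w_epoch[boost] = w / w.sum(axis=1, keepdims=True)

    # EEG: five unit-RMS band-noise tracks mixed per epoch.
    rng_eeg = np.random.default_rng(ss_eeg)
    eeg = np.zeros(n_samples, dtype=np.float32)
    coef = np.sqrt(w_epoch).astype(np.float32)  # amplitude coefficients
    for b, name in enumerate(BAND_ORDER):
        lo, hi = BAND_EDGES_HZ[name]
        sos = _band_sos(lo, hi, sampling_rate, signal_model.band_filter_order)
        track = rng_eeg.standard_normal(n_samples, dtype=np.float32)
        track = sps.sosfilt(sos, track).astype(np.float32)
        track /= np.sqrt(np.mean(track**2))
        eeg += np.repeat(coef[:, b], spe) * track
    amp = np.array(
        [signal_model.eeg_amplitude_uv[s] for s in (WAKE, NREM, REM)], dtype=np.float32
    )
    eeg *= np.repeat(amp[labels], spe)

    # EMG: amplitude-scaled white noise.
    rng_emg = np.random.default_rng(ss_emg)
    emg_amp = np.array(
        [signal_model.emg_amplitude_uv[s] for s in (WAKE, NREM, REM)], dtype=np.float32
    )
    emg = rng_emg.standard_normal(n_samples, dtype=np.float32)
    emg *= np.repeat(emg_amp[labels], spe)

    # Activity: Poisson counts in wake epochs only, rate by phase.
    rng_act = np.random.default_rng(ss_act)
    light = np.asarray(schedule.is_light(zt))
    rate = np.where(
        light,
        signal_model.activity_rate_by_phase["light"],
        signal_model.activity_rate_by_phase["dark"],
    ).astype(float)
    if treatment is not None:
        rate = np.where(treated, rate * treatment.activity_multiplier, rate)
    activity = rng_act.poisson(rate).astype(float)
    activity[labels != WAKE] = 0.0

    # Temperature: cosinor + noise (+ treatment offset in window).
    rng_temp = np.random.default_rng(ss_temp)
    temp = (
        signal_model.temperature_mesor_c
        + signal_model.temperature_amplitude_c
        * np.cos(2 * np.pi * (zt - signal_model.temperature_acrophase_zt) / schedule.period)
        + rng_temp.normal(0.0, signal_model.temperature_noise_c, n_epochs)
    )
    if treatment is not None:
        temp = np.where(treated, temp + treatment.temperature_offset_c, temp)

    rec = Recording(
        eeg=eeg,
        emg=emg,
        sampling_rate=sampling_rate,
        activity=activity,
        temperature=temp,
        start_zt=hypnogram.start_zt,
        subject_id=subject_id,
        treatment_label=(
            treatment_label if treatment_label is not None
            else ("drug" if treatment is not None else "vehicle")
        ),
        prenatal_label=prenatal_label,
        metadata={"seed": seed},
    )
    return SimulatedRecording(recording=rec, truth_hypnogram=hypnogram, seed=seed)


def simulate_recording(
    duration_h: float = 24.0,
    seed: int = 0,
    transition_model: StateTransitionModel | None = None,
    signal_model: SignalModel | None = None,
    schedule: LightDarkSchedule | None = None,
    sampling_rate: float = 250.0,
    treatment: TreatmentEffect | None = None,
    start_zt: float = 0.0,
    subject_id: str = "sim",
    **kwargs,
) -> SimulatedRecording:
    """Convenience wrapper: state sequence + signal synthesis in one call.

    The state-chain and signal streams are derived deterministically from
    ``seed``, so identical parameters reproduce the recording bit for bit.
    """
    ss = np.random.SeedSequence(seed)
    chain_seed, signal_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    hyp = simulate_state_sequence(
        model=transition_model,
        schedule=schedule,
        duration_h=duration_h,
        treatment=treatment,
        seed=chain_seed,
        start_zt=start_zt,
    )
    sim = synthesize_signals(
        hyp,
        signal_model=signal_model,
        schedule=schedule,
        sampling_rate=sampling_rate,
        treatment=treatment,
        seed=signal_seed,
        subject_id=subject_id,
        **kwargs,
    )
    return replace(sim, seed=seed)
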