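"""Per-epoch spectral featurization and moving-window sample construction.

Each 10-s epoch of EEG is transformed with a single rectangular-window DFT
(no detrending, no tapering). Power is summed into 40 half-open channels
of 0.5 Hz width covering [0, 20) Hz and each channel is expressed as a
fraction of the total 0–20 Hz power — total power acts as the normalizer,
not as an extra feature. Together with the epoch's EMG RMS and its cage
activity count this gives the fixed 42-feature epoch vector; five
consecutive epochs concatenate to the 210-feature classifier input, whose
training label is the modal state of the window.

The DC (0 Hz) bin is excluded from channel 0 by default so a constant
offset cannot dominate the lowest channel; pass ``include_dc=True`` to
keep it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ratpsg.core import (
    EPOCH_S,
    Hypnogram,
    Recording,
    ValidationError,
)

logger = logging.getLogger(__name__)

N_CHANNELS = 40
CHANNEL_WIDTH_HZ = 0.5
ANALYSIS_CEILING_HZ = 20.0
N_EPOCH_FEATURES = N_CHANNELS + 2  # 40 spectral channels + EMG RMS + activity
WINDOW_EPOCHS = 5
N_WINDOW_FEATURES = WINDOW_EPOCHS * N_EPOCH_FEATURES


@dataclass(frozen=True)
class Epoch:
    """A 10-s scoring epoch located in the recording and in ZT."""

    index: int
    start_time_s: float
    duration_s: float
    zt: float


@dataclass
class EpochFeatures:
    """The 42-feature epoch vector: 40 channel-power fractions + EMG RMS + activity."""

    channel_powers: np.ndarray
    avg_emg: float
    activity: float

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.channel_powers, [self.avg_emg, self.activity]])


@dataclass
class WindowSample:
    """A 5-epoch, 210-feature classifier input centered on one epoch."""

    features: np.ndarray
    center_epoch: int
    label: int | None = None


def segment_epochs(recording: Recording) -> list[Epoch]:
    """Tile the recording into non-overlapping 10-s epochs.

    Trailing samples that do not fill an epoch are discarded (logged).
    Each epoch carries the ZT of its start, derived from the recording's
    start ZT.
    """
    n = recording.n_epochs
    if n < 1:
        raise ValidationError(
            f"recording of {recording.duration_s:.1f} s is shorter than one "
            f"{EPOCH_S:.0f}-s epoch"
        )
    dropped = recording.duration_s - n * EPOCH_S
    if dropped > 0:
        logger.info("dropping trailing %.1f s that do not fill an epoch", dropped)
    return [
        Epoch(
            index=i,
            start_time_s=i * EPOCH_S,
            duration_s=EPOCH_S,
            zt=(recording.start_zt + i * EPOCH_S / 3600.0) % 24.0,
        )
        for i in range(n)
    ]


def _channel_bin_index(fs: float, n: int, include_dc: bool):
    """Map rFFT bin -> spectral channel (or -1 for out-of-range bins)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    ch = np.floor(freqs / CHANNEL_WIDTH_HZ).astype(int)
    ch[(freqs >= ANALYSIS_CEILING_HZ)] = -1
    if not include_dc:
        ch[freqs == 0.0] = -1
    return ch


def _epoch_power_spectrum(eeg_epochs: np.ndarray) -> np.ndarray:
    """Per-epoch one-sided power spectrum of rectangular-windowed epochs.

    Scaled so that the sum over all one-sided bins equals mean squared
    signal power (Parseval).
    """
    n = eeg_epochs.shape[-1]
    spec = np.fft.rfft(eeg_epochs, axis=-1)
    power = (np.abs(spec) ** 2) / n**2
    # fold the negative frequencies onto positive bins
    if n % 2 == 0:
        power[..., 1:-1] *= 2.0
    else:
        power[..., 1:] *= 2.0
    return power


def compute_epoch_features(
    eeg_epoch: np.ndarray,
    emg_epoch: np.ndarray,
    activity: float,
    sampling_rate: float,
    include_dc: bool = False,
    epoch_index: int | None = None,
) -> EpochFeatures:
    """Featurize a single epoch (see :func:`featurize_recording` for batches)."""
    eeg_epoch = np.asarray(eeg_epoch, dtype=float)
    emg_epoch = np.asarray(emg_epoch, dtype=float)
    expected = int(round(EPOCH_S * sampling_rate))
    if eeg_epoch.size != expected or emg_epoch.size != expected:
        raise ValidationError(
            f"epoch must contain exactly {expected} samples at {sampling_rate} Hz "
            f"(got EEG {eeg_epoch.size}, EMG {emg_epoch.size})"
        )
    vec = _featurize_block(
        eeg_epoch[None, :], emg_epoch[None, :], np.array([activity], dtype=float),
        sampling_rate, include_dc, first_index=epoch_index or 0,
    )[0]
    return EpochFeatures(
        channel_powers=vec[:N_CHANNELS], avg_emg=float(vec[N_CHANNELS]),
        activity=float(vec[N_CHANNELS + 1]),
    )


def _featurize_block(
    eeg: np.ndarray, emg: np.ndarray, activity: np.ndarray,
    sampling_rate: float, include_dc: bool, first_index: int = 0,
) -> np.ndarray:
    """Vectorized featurization of shape-(n_epochs, samples) blocks."""
    if not np.isfinite(eeg).all() or not np.isfinite(emg).all():
        bad = np.where(
            ~(np.isfinite(eeg).all(axis=1) & np.isfinite(emg).all(axis=1))
        )[0]
        raise ValidationError(
            f"non-finite samples in epoch(s) {[int(b) + first_index for b in bad[:5]]}"
        )
    n = eeg.shape[-1]
    ch_of_bin = _channel_bin_index(sampling_rate, n, include_dc)
    power = _epoch_power_spectrum(eeg)
    keep = ch_of_bin >= 0
    channels = np.zeros((eeg.shape[0], N_CHANNELS))
    np.add.at(channels.T, ch_of_bin[keep], power[:, keep].T)
    total = channels.sum(axis=1)
    zero = total <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} epoch(s) with zero 0-20 Hz power; "
            "emitting all-zero channel vectors",
            stacklevel=2,
        )
    out = np.zeros((eeg.shape[0], N_EPOCH_FEATURES))
    out[:, :N_CHANNELS] = np.where(
        zero[:, None], 0.0, channels / np.where(zero, 1.0, total)[:, None]
    )
    out[:, N_CHANNELS] = np.sqrt(np.mean(emg.astype(float) ** 2, axis=1))
    out[:, N_CHANNELS + 1] = activity
    return out


def featurize_recording(
    recording: Recording, include_dc: bool = False
) -> tuple[np.ndarray, list[Epoch]]:
    """Featurize every complete epoch of a recording.

    Returns an (n_epochs, 42) array of feature vectors and the epoch grid.
    """
    epochs = segment_epochs(recording)
    spe = int(round(EPOCH_S * recording.sampling_rate))
    n = len(epochs)
    eeg = np.asarray(recording.eeg[: n * spe], dtype=float).reshape(n, spe)
    emg = np.asarray(recording.emg[: n * spe], dtype=float).reshape(n, spe)
    feats = _featurize_block(
        eeg, emg, recording.activity[:n], recording.sampling_rate, include_dc
    )
    return feats, epochs


def window_label(labels5: np.ndarray) -> int:
    """Modal state of a 5-epoch window; ties resolve toward the center epoch.

    With three classes and five votes the only possible tie is 2-2-1. If
    the center epoch's state is one of the tied leaders it wins; otherwise
    (the center is the singleton) the leader occurring earliest in the
    window is taken.
    """
    counts = np.bincount(labels5, minlength=3)
    top = counts.max()
    leaders = np.flatnonzero(counts == top)
    if len(leaders) == 1:
        return int(leaders[0])
    center = int(labels5[WINDOW_EPOCHS // 2])
    if center in leaders:
        return center
    for s in labels5:
        if s in leaders:
            return int(s)
    return int(leaders[0])  # unreachable


def build_window_samples(
    features: np.ndarray, labels: Hypnogram | np.ndarray | None = None
) -> list[WindowSample]:
    """Slide a 5-epoch window (stride 1) over the epoch features.

    From n epochs, n-4 samples are produced; each concatenates the five
    42-feature vectors in time order (210 features) and is indexed by its
    center (third) epoch. When a hypnogram is supplied, each sample gets
    the modal label of its window.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != N_EPOCH_FEATURES:
        raise ValidationError(
            f"features must be (n_epochs, {N_EPOCH_FEATURES}), got {features.shape}"
        )
    n = features.shape[0]
    if n < WINDOW_EPOCHS:
        raise ValidationError(f"need at least {WINDOW_EPOCHS} epochs, got {n}")
    lab = None
    if labels is not None:
        lab = labels.labels if isinstance(labels, Hypnogram) else np.asarray(labels)
        if lab.size != n:
            raise ValidationError(
                f"labels length {lab.size} does not match {n} epochs"
            )
    samples = []
    for i in range(n - WINDOW_EPOCHS + 1):
        win = features[i : i + WINDOW_EPOCHS].reshape(-1)
        label = window_label(lab[i : i + WINDOW_EPOCHS]) if lab is not None else None
        samples.append(WindowSample(features=win, center_epoch=i + WINDOW_EPOCHS // 2, label=label))
    return samples


def window_matrix(samples: list[WindowSample]):
    """Stack WindowSamples into (X, y, centers) arrays; y is None if unlabeled."""
    X = np.stack([s.features for s in samples])
    centers = np.array([s.center_epoch for s in samples])
    if samples and samples[0].label is not None:
        y = np.array([s.label for s in samples], dtype=np.int8)
    else:
        y = None
    return X, y, centers
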