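"""Standard-format I/O.

Raw signals travel as EDF (European Data Format, the ubiquitous
polysomnography container): one data record per second, channels EEG and
EMG in µV, 16-bit quantization. Epoch-level channels (activity counts,
core temperature, truth labels) fit EDF's fixed-rate records awkwardly at
their 0.1 Hz effective rate, so they ride in a delimited-text sidecar
with columns ``epoch_index, zt_start_s, activity, temperature_c, state``.

EDF files are written by a minimal encoder in this module and read back
through MNE, which serves as an independent decoder of the format.
Feature tables, hypnograms and summaries are CSV with a commented header
carrying the config hash and seed; model bundles are single ``.npz``
files holding weights, standardization constants and metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ratpsg.classifier import ClassifierConfig, TrainedClassifier
from ratpsg.core import (
    EPOCH_S,
    STATE_CODES,
    STATE_NAMES,
    Hypnogram,
    Recording,
    ValidationError,
)
from ratpsg.features import N_CHANNELS

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width].encode("ascii")
    return s + b" " * (width - len(s))


def _edf_phys_bound(value: float) -> float:
    """Round-trip a physical bound through its 8-char EDF header field."""
    return float(_edf_field(f"{value:.6g}", 8).decode())


def write_edf(path, signals: dict, sampling_rate: float) -> None:
    """Write named µV signals to EDF, one 1-s data record per second.

    All signals must share the sampling rate and a whole number of
    seconds; trailing sub-second samples are dropped.
    """
    fs = int(round(sampling_rate))
    if abs(sampling_rate - fs) > 1e-9:
        raise ValidationError("EDF export requires an integer sampling rate")
    labels = list(signals)
    n_sec = min(len(x) for x in signals.values()) // fs
    if n_sec < 1:
        raise ValidationError("signals shorter than one EDF record (1 s)")

    bounds = {}
    for lab in labels:
        m = float(np.max(np.abs(signals[lab]))) or 1.0
        bounds[lab] = (_edf_phys_bound(-m), _edf_phys_bound(m))

    ns = len(labels)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate 01-JAN-2000 X X X", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 + 256 * ns, 8),
            _edf_field("", 44),
            _edf_field(n_sec, 8),
            _edf_field("1", 8),
            _edf_field(ns, 4),
        ]
        + [_edf_field(lab, 16) for lab in labels]
        + [_edf_field("", 80) for _ in labels]
        + [_edf_field("uV", 8) for _ in labels]
        + [_edf_field(f"{bounds[lab][0]:.6g}", 8) for lab in labels]
        + [_edf_field(f"{bounds[lab][1]:.6g}", 8) for lab in labels]
        + [_edf_field(_EDF_DIG_MIN, 8) for _ in labels]
        + [_edf_field(_EDF_DIG_MAX, 8) for _ in labels]
        + [_edf_field("", 80) for _ in labels]
        + [_edf_field(fs, 8) for _ in labels]
        + [_edf_field("", 32) for _ in labels]
    )
    digital = {}
    for lab in labels:
        pmin, pmax = bounds[lab]
        x = np.asarray(signals[lab][: n_sec * fs], dtype=float)
        scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
        d = np.round((x - pmin) * scale + _EDF_DIG_MIN)
        digital[lab] = np.clip(d, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_sec):
            for lab in labels:
                fh.write(digital[lab][r * fs : (r + 1) * fs].tobytes())


def edf_quantization_step_uv(signal: np.ndarray) -> float:
    """The µV size of one 16-bit step for a signal's auto-chosen range."""
    m = float(np.max(np.abs(signal))) or 1.0
    pmin, pmax = _edf_phys_bound(-m), _edf_phys_bound(m)
    return (pmax - pmin) / (_EDF_DIG_MAX - _EDF_DIG_MIN)


def _sidecar_path(prefix) -> Path:
    return Path(str(prefix) + ".sidecar.csv")


def _edf_path(prefix) -> Path:
    return Path(str(prefix) + ".edf")


def write_recording(
    recording: Recording, prefix, truth: Hypnogram | None = None
) -> None:
    """Write an EDF (``<prefix>.edf``) plus epoch-level sidecar CSV.

    The sidecar carries activity, temperature and, when given, the truth
    hypnogram, one row per 10-s epoch.
    """
    write_edf(
        _edf_path(prefix),
        {"EEG": recording.eeg, "EMG": recording.emg},
        recording.sampling_rate,
    )
    n = recording.n_epochs
    if truth is not None and truth.n_epochs != n:
        raise ValidationError(
            f"truth hypnogram has {truth.n_epochs} epochs, recording has {n}"
        )
    zt_start_s = ((recording.start_zt * 3600.0 + np.arange(n) * EPOCH_S) % (24 * 3600.0))
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "zt_start_s": zt_start_s,
            "activity": recording.activity,
            "temperature_c": (
                recording.temperature if recording.temperature is not None else np.nan
            ),
            "state": (
                np.array(STATE_NAMES)[truth.labels] if truth is not None else ""
            ),
        }
    )
    meta = {
        "start_zt": recording.start_zt,
        "sampling_rate": recording.sampling_rate,
        "subject_id": recording.subject_id,
        "treatment_label": recording.treatment_label,
        "prenatal_label": recording.prenatal_label,
    }
    with open(_sidecar_path(prefix), "w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        df.to_csv(fh, index=False)


def read_recording(prefix) -> tuple[Recording, Hypnogram | None]:
    """Read an EDF + sidecar pair written by :func:`write_recording`.

    Returns the recording and the truth hypnogram (None when the sidecar
    has no state column filled).
    """
    import mne

    edf = _edf_path(prefix)
    if not edf.exists():
        raise ValidationError(f"missing EDF file {edf}")
    raw = mne.io.read_raw_edf(edf, preload=True, verbose="error")
    missing = {"EEG", "EMG"} - set(raw.ch_names)
    if missing:
        raise ValidationError(f"EDF lacks required channel(s): {sorted(missing)}")
    fs = float(raw.info["sfreq"])
    data = raw.get_data(picks=["EEG", "EMG"]) * 1e6  # MNE reads uV as volts

    side = _sidecar_path(prefix)
    if not side.exists():
        raise ValidationError(f"missing sidecar file {side}")
    with open(side) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
        df = pd.read_csv(fh)
    n_epochs_sig = int(data.shape[1] // (EPOCH_S * fs))
    if len(df) != n_epochs_sig:
        raise ValidationError(
            f"sidecar has {len(df)} epochs but the EDF signals span "
            f"{n_epochs_sig} epochs"
        )
    temperature = df["temperature_c"].to_numpy(float)
    if np.isnan(temperature).all():
        temperature = None
    rec = Recording(
        eeg=data[0],
        emg=data[1],
        sampling_rate=fs,
        activity=df["activity"].to_numpy(float),
        temperature=temperature,
        start_zt=float(meta.get("start_zt", 0.0)),
        subject_id=str(meta.get("subject_id", "subject")),
        treatment_label=str(meta.get("treatment_label", "vehicle")),
        prenatal_label=str(meta.get("prenatal_label", "control")),
    )
    truth = None
    states = df.get("state")
    if states is not None and states.notna().all() and (states != "").all():
        truth = Hypnogram(
            labels=np.array([STATE_CODES[s] for s in states]),
            start_zt=rec.start_zt,
        )
    return rec, truth


# ---------------------------------------------------------------------------
# delimited-text tables

def _header_comment(meta: dict) -> str:
    return "# " + json.dumps(meta, sort_keys=True) + "\n"


def write_features(
    path, features: np.ndarray, zt: np.ndarray,
    labels: Hypnogram | None = None, meta: dict | None = None,
) -> None:
    """Feature table: epoch_index, zt, ch00..ch39, avg_emg, activity[, state]."""
    cols = {"epoch_index": np.arange(features.shape[0]), "zt": zt}
    for k in range(N_CHANNELS):
        cols[f"ch{k:02d}"] = features[:, k]
    cols["avg_emg"] = features[:, N_CHANNELS]
    cols["activity"] = features[:, N_CHANNELS + 1]
    if labels is not None:
        cols["state"] = np.array(STATE_NAMES)[labels.labels]
    with open(path, "w") as fh:
        fh.write(_header_comment(meta or {}))
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_features(path):
    """Read a feature table back to (features, zt, hypnogram-or-None, meta)."""
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
        df = pd.read_csv(fh)
    chans = [f"ch{k:02d}" for k in range(N_CHANNELS)]
    feats = np.column_stack(
        [df[chans].to_numpy(float), df["avg_emg"], df["activity"]]
    )
    zt = df["zt"].to_numpy(float)
    hyp = None
    if "state" in df.columns and df["state"].notna().all():
        hyp = Hypnogram(
            labels=np.array([STATE_CODES[s] for s in df["state"]]),
            start_zt=float(zt[0]) if len(zt) else 0.0,
        )
    return feats, zt, hyp, meta


def write_hypnogram(path, hypnogram: Hypnogram, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(hypnogram.n_epochs),
            "zt": hypnogram.epoch_zt(),
            "state": hypnogram.state_names(),
        }
    )
    with open(path, "w") as fh:
        fh.write(_header_comment(meta or {}))
        df.to_csv(fh, index=False)


def read_hypnogram(path) -> Hypnogram:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            fh.seek(0)
        df = pd.read_csv(fh)
    return Hypnogram(
        labels=np.array([STATE_CODES[s] for s in df["state"]]),
        start_zt=float(df["zt"].iloc[0]) if len(df) else 0.0,
    )


# ---------------------------------------------------------------------------
# model bundle

def save_model(path, model: TrainedClassifier) -> None:
    np.savez(
        path,
        w_hidden=model.w_hidden,
        b_hidden=model.b_hidden,
        w_out=model.w_out,
        b_out=model.b_out,
        scaler_mean=model.scaler_mean,
        scaler_scale=model.scaler_scale,
        config=json.dumps(dataclasses.asdict(model.config)),
        history=json.dumps(model.history),
        feature_settings=json.dumps(model.feature_settings),
    )


def load_model(path) -> TrainedClassifier:
    with np.load(path, allow_pickle=False) as z:
        cfg = json.loads(str(z["config"]))
        cfg["split_fractions"] = tuple(cfg["split_fractions"])
        return TrainedClassifier(
            w_hidden=z["w_hidden"],
            b_hidden=z["b_hidden"],
            w_out=z["w_out"],
            b_out=z["b_out"],
            scaler_mean=z["scaler_mean"],
            scaler_scale=z["scaler_scale"],
            config=ClassifierConfig(**cfg),
            history=json.loads(str(z["history"])),
            feature_settings=json.loads(str(z["feature_settings"])),
        )


# ---------------------------------------------------------------------------
# run configuration

@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters with defaults, serializable as one mapping.

    Nested sections hold overrides for the simulator, featurizer,
    classifier and analysis stages; ``as_dict``/``from_dict`` round-trip
    identically.
    """

    seed: int = 0
    output_dir: str = "."
    duration_h: float = 24.0
    sampling_rate: float = 250.0
    start_zt: float = 0.0
    include_dc: bool = False
    bin_hours: int = 6
    simulator: dict = dataclasses.field(default_factory=dict)
    treatment: dict | None = None
    classifier: dict = dataclasses.field(default_factory=dict)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        return config_hash(self.as_dict())


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config file {path} must hold a mapping")
    return cfg


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
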