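"""End-to-end workflows: classifier benchmarking on synthetic recordings
and the two-arm (vehicle vs. drug) virtual experiment.

These functions glue the simulator, featurizer, classifier and analytics
together the way the command-line ``demo`` does, and are what the
acceptance checks drive.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ratpsg import architecture, spectral
from ratpsg.classifier import (
    ClassifierConfig,
    evaluate,
    oversample_training,
    predict,
    split_dataset,
    train,
)
from ratpsg.core import NREM, REM, WAKE, Hypnogram, LightDarkSchedule
from ratpsg.features import build_window_samples, featurize_recording, window_matrix
from ratpsg.io import config_hash, write_hypnogram
from ratpsg.simulate import SignalModel, StateTransitionModel, TreatmentEffect, simulate_recording


def simulate_and_featurize(
    seed: int,
    duration_h: float = 24.0,
    sampling_rate: float = 250.0,
    treatment: TreatmentEffect | None = None,
    **sim_kwargs,
):
    """One labeled synthetic recording, featurized.

    Returns (features, truth hypnogram, recording).
    """
    sim = simulate_recording(
        duration_h=duration_h,
        seed=seed,
        sampling_rate=sampling_rate,
        treatment=treatment,
        **sim_kwargs,
    )
    feats, _ = featurize_recording(sim.recording)
    return feats, sim.truth_hypnogram, sim.recording


def end_to_end_agreement(
    seeds=tuple(range(1, 11)),
    duration_h: float = 24.0,
    sampling_rate: float = 250.0,
    config: ClassifierConfig | None = None,
    split_seed: int | None = None,
) -> dict:
    """Simulate, featurize, train and score; report held-out agreement.

    Simulates one default-parameter recording per seed, pools the 5-epoch
    window samples, splits them 64/16/20 (stratified, seeded), oversamples
    the training classes to balance, trains the 210-512-3 MLP until the
    validation loss plateaus, and measures epoch-level agreement between
    the predicted and true vigilance states on the test split.
    """
    config = config if config is not None else ClassifierConfig()
    samples = []
    truth_by_sample = []
    for seed in seeds:
        feats, truth, _ = simulate_and_featurize(
            seed, duration_h=duration_h, sampling_rate=sampling_rate
        )
        wins = build_window_samples(feats, truth)
        samples.extend(wins)
        truth_by_sample.extend(int(truth.labels[w.center_epoch]) for w in wins)
    truth_by_sample = np.array(truth_by_sample, dtype=np.int8)

    split_seed = config.seed if split_seed is None else split_seed
    # remember each pooled sample's position so test windows can be traced
    # back to their true center-epoch state
    index_of = {id(s): i for i, s in enumerate(samples)}
    tr, va, te = split_dataset(samples, config.split_fractions, seed=split_seed)
    if config.oversample:
        tr = oversample_training(tr, seed=split_seed)
    model = train(tr, va, config)

    X_te, _, _ = window_matrix(te)
    pred = model.predict_classes(X_te)
    true_epoch = truth_by_sample[[index_of[id(s)] for s in te]]
    agreement = float(np.mean(pred == true_epoch))
    report = evaluate(model, te)
    return {
        "agreement": agreement,
        "agreement_pct": 100.0 * agreement,
        "n_test": len(te),
        "n_samples": len(samples),
        "window_accuracy": report.accuracy,
        "macro_f1": report.macro_f1,
        "confusion": report.confusion,
        "history": model.history,
        "model": model,
    }


def run_demo(
    seed: int = 1,
    out_dir=None,
    duration_h: float = 24.0,
    sampling_rate: float = 125.0,
    treatment: TreatmentEffect | None = None,
    config: ClassifierConfig | None = None,
    bin_hours: int = 6,
) -> dict:
    """Two-arm virtual experiment: vehicle vs. drug injected at ZT 0.

    Simulates both arms with a shared random stream (so the treatment is
    the only difference), trains a classifier on the pooled windows,
    scores both recordings, and derives the treatment summaries: per-bin
    vigilance-state durations, percent and absolute change from vehicle,
    and the light-phase NREM spectral contrast.
    """
    treatment = treatment if treatment is not None else TreatmentEffect()
    config = (
        config
        if config is not None
        else ClassifierConfig(max_iterations=25, patience=5, seed=seed % (2**31))
    )
    schedule = LightDarkSchedule()

    arms = {}
    for label, tr_effect in (("vehicle", None), ("drug", treatment)):
        feats, truth, rec = simulate_and_featurize(
            seed,
            duration_h=duration_h,
            sampling_rate=sampling_rate,
            treatment=tr_effect,
            treatment_label=label,
        )
        arms[label] = {"features": feats, "truth": truth, "recording": rec}

    samples = []
    for label in arms:
        samples.extend(build_window_samples(arms[label]["features"], arms[label]["truth"]))
    tr, va, te = split_dataset(samples, config.split_fractions, seed=config.seed)
    if config.oversample:
        tr = oversample_training(tr, seed=config.seed)
    model = train(tr, va, config)
    report = evaluate(model, te)

    for label in arms:
        arm = arms[label]
        wins = build_window_samples(arm["features"])
        arm["predicted"] = predict(
            model, wins, n_epochs=arm["truth"].n_epochs, start_zt=arm["truth"].start_zt
        )
        arm["bins"] = architecture.bin_durations(arm["predicted"], bin_hours, schedule)
        arm["spectrum_nrem_light"] = spectral.state_phase_spectrum(
            arm["features"], arm["predicted"], NREM, "light", schedule
        )

    pct = architecture.percent_change(arms["drug"]["bins"], arms["vehicle"]["bins"])
    absc = architecture.absolute_change(arms["drug"]["bins"], arms["vehicle"]["bins"])
    contrast = spectral.spectral_contrast(
        arms["drug"]["spectrum_nrem_light"], arms["vehicle"]["spectrum_nrem_light"]
    )
    delta_mask = spectral.DELTA.channel_mask()
    light_bins = arms["vehicle"]["bins"]["bin_start_zt"] < 12.0

    def _light_pct(state: str) -> float:
        rows = pct[(pct["state"] == state) & light_bins.to_numpy()]
        return float(rows["percent_change"].mean())

    summary = {
        "seed": seed,
        "classifier_test_accuracy": report.accuracy,
        "light_phase_percent_change": {
            "REM": _light_pct("REM"),
            "NREM": _light_pct("NREM"),
            "WAKE": _light_pct("WAKE"),
        },
        "nrem_delta_contrast_light": float(contrast["difference"][delta_mask].sum()),
        "config_hash": config_hash(
            {"seed": seed, "duration_h": duration_h, "sampling_rate": sampling_rate}
        ),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"seed": seed, "config_hash": summary["config_hash"]}
        for label in arms:
            write_hypnogram(out / f"hypnogram_{label}.csv", arms[label]["predicted"], meta)
            arms[label]["bins"].to_csv(out / f"architecture_{label}.csv", index=False)
            spectral.profile_frame(
                arms[label]["spectrum_nrem_light"], treatment=label
            ).to_csv(out / f"spectrum_nrem_light_{label}.csv", index=False)
        pct.to_csv(out / "percent_change.csv", index=False)
        absc.to_csv(out / "absolute_change.csv", index=False)
        contrast.to_csv(out / "nrem_delta_contrast_light.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    summary["percent_change_table"] = pct
    summary["absolute_change_table"] = absc
    summary["contrast_table"] = contrast
    summary["arms"] = arms
    return summary
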