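# Methods

## Overview

`ratpsg` reimplements, end to end, the analysis pipeline used for rodent
telemetric polysomnography: 10-s epochs of EEG/EMG are featurized with a
discrete Fourier transform, scored into wake / NREM / REM by a multilayer
perceptron, and summarized as sleep architecture (bouts, transitions,
onsets, binned durations) and state-resolved spectral power. Because no
public recordings accompany the study design this package targets, a
synthetic telemetry generator with known ground truth is a first-class
component: every downstream stage is validated against simulations whose
statistical structure is fully specified.

## Synthetic telemetry generator

**State dynamics.** Vigilance states follow a first-order Markov chain on
the 10-s epoch grid with separate per-epoch transition matrices for the
light (ZT 0–12) and dark (ZT 12–24) phases. Under a constant matrix the
dwell time in state *s* is geometric with mean 1/(1 − p_ss) epochs; this
closed form is the oracle for the simulator's dwell-time tests.

The default matrices are the package's own choice of realistic rat
values — the study design gives no quantitative occupancies — built from
two targets and solved exactly via stationary flow balance:

| phase | occupancy W/N/R | mean dwell W/N/R (min) |
|-------|-----------------|------------------------|
| light | 35 / 55 / 10 %  | 2 / 3 / 1.5            |
| dark  | 65 / 30 / 5 %   | 5 / 2 / 1.5            |

REM is entered only from NREM (wake→REM probability 0), matching rodent
physiology; all entries are overridable.

**Signals.** Per state, EEG is a mixture of five band-limited Gaussian
noise tracks (delta 0.5–4, theta 4–8, alpha 8–12, sigma 12–16, beta
16–20 Hz), each produced by Butterworth-filtering white noise and
normalizing to unit RMS, combined with √(band-weight) coefficients and
scaled to the state's RMS amplitude. Defaults: wake 50 µV, broadband with
a theta/alpha tilt; NREM 120 µV, 60 % delta; REM 60 µV, 55 % theta. EMG
is white noise at 60 / 20 / 5 µV RMS (wake / NREM / REM — REM atonia).
Activity is a per-epoch Poisson count, nonzero only in wake (rate 2
counts/epoch light, 6 dark); temperature is a cosinor (mesor 37.2 °C,
amplitude 0.5 °C, acrophase ZT 18) plus N(0, 0.1 °C) noise.

The band filter order defaults to 8. The generator is designed so that
featurizing a single-state simulation recovers the state's band weights
within ±0.05 per band (a tested property); a gentler order-4 rolloff
leaks too much power across the 4 Hz delta/theta edge to guarantee that
margin, while order 8 does, and remains numerically stable in
second-order sections.

**Treatment effects** are directional knobs active inside a ZT window
(default ZT 0–12, i.e. drug at lights-on): wake→sleep transition
probabilities multiplied (default ×2, wake row renormalized), NREM delta
weight multiplied (default ×1.3, weights renormalized), activity rate
scaled (×0.7) and temperature offset (−0.4 °C). They emulate the
qualitative signature of a somnogenic KAT II inhibitor — more REM/NREM
and less wake in the light phase, higher NREM delta power, lower activity
and temperature — not any quantitative pharmacology.

**Determinism.** Each recording derives chain, EEG, EMG, activity and
temperature streams from one seed via `SeedSequence.spawn`; identical
parameters and seed reproduce the recording bit for bit. State sampling
is inverse-CDF on a per-epoch uniform stream, so a treated arm run on the
same seed shares its random numbers with the vehicle arm (common random
numbers), making treatment contrasts low-variance.

## Featurization

Each 10-s epoch is transformed with a single rectangular-window DFT (no
detrending or tapering; 0.1 Hz resolution at 10 s). Power is summed into
40 half-open 0.5-Hz channels covering [0, 20) Hz, and each channel is
divided by the total 0–20 Hz power — total power is the normalizer, not a
separate feature, the only arithmetic consistent with a 42-feature epoch
vector (40 channels + EMG RMS + activity count). The DC bin is excluded
from channel 0 by default so constant offsets cannot dominate
(`include_dc=True` restores it). Normalization makes the channel vector
invariant to overall EEG amplitude scaling; the un-normalized channel sum
obeys Parseval against the signal's mean squared power.

Windows of five consecutive epochs (stride 1; n − 4 windows from n
epochs) concatenate to 210 features. A training window's label is the
modal state of its five epochs; with three classes the only possible tie
is 2-2-1, resolved in favor of the center epoch's state when it is among
the leaders, otherwise the earliest-occurring leader.

## Classifier

A fully connected 210-512-3 network, ReLU hidden activation, softmax
output, cross-entropy loss, Adam (learning rate 1e-3, batch 256). The
implementation runs scikit-learn's `MLPClassifier` one pass at a time and
monitors log-loss on an explicit validation split: training stops after
10 checks without ≥ 1e-4 improvement (or 60 passes), restoring the best
weights. Features are z-scored with training-split statistics — the
mixed units (power fractions, µV, counts) make this necessary. Scoring
is an explicit forward pass over the stored weights, so serialized
models predict identically; argmax ties resolve to the lowest class
index.

Splitting is seeded and stratified, 64/16/20 train/validation/test with
nearest-integer rounding per class and the remainder to training.
Training-class imbalance (REM is ~10 % of epochs) is corrected by random
oversampling with replacement to the majority count, training split only.
Per-epoch predictions come from the window centered on the epoch; the
first and last two epochs inherit the nearest window's label.

## Architecture metrics

A bout is a maximal run of one state (≥ 1 epoch). A transition is scored
only when the new state holds ≥ 2 epochs; single-epoch excursions are
bouts but never transitions and never update the scored state — the only
reading under which both definitions hold simultaneously. Onset latency
(NREM or REM) is the time from a phase start to the first ≥ 2-epoch run
of the state; absent runs give NaN. Durations, bout counts and mean bout
durations are tabulated in 1-h or 6-h bins anchored at the recording
start; a bout straddling a bin edge is counted once, with full duration,
in its starting bin (its epochs still contribute to each bin's duration
totals, so per-bin durations always sum to the bin length). Treatment
contrasts are per-bin percent change from vehicle (NaN-flagged where the
vehicle value is 0) or signed within-subject differences.

## Spectral analysis

State- and phase-resolved spectra are means of the featurizer's
normalized channel vectors over qualifying epochs, i.e. fractions of
per-epoch total 0–20 Hz power; profile mass is ≤ 1 (DC excluded). Band
powers sum the channels whose centers fall in delta/theta/alpha/sigma/
beta, which tile (0.5, 20) Hz; channel 0 is reported as a sub-delta
residual, so the six masses partition the profile exactly. Delta starts
at 0.5 Hz per the conventional definition. Contrasts are per-channel
differences of matched profiles. Because profiles are built from the
hypnogram under analysis, spectra can be conditioned on truth labels
(simulations) or predicted labels (end-to-end runs); outputs record
which.

## I/O

Signals travel as EDF (1-s records, 16-bit, channels EEG and EMG in µV;
round trip exact to one quantization step of the auto-chosen range).
Epoch-rate channels (activity, temperature, truth labels) use a CSV
sidecar — their 0.1 Hz effective rate fits EDF records awkwardly. The
EDF encoder is a minimal writer in `ratpsg.io`; reading goes through MNE,
which independently decodes the format. Feature tables, hypnograms and
summaries are CSV with a commented JSON header carrying seed and config
hash; models are single `.npz` bundles (weights + scaler + config).

## Problem sizes and what the tests show

The end-to-end recovery benchmark uses ten 24-h recordings at the default
250 Hz (≈ 86 000 labeled epochs; ≈ 6 min on one CPU); the two-arm demo
uses 24 h per arm at 125 Hz with a shortened training schedule (25
passes, patience 5). Dwell-law checks use 50 000 epochs under a constant
matrix, where the geometric closed form applies.

On these synthetic data the classifier reaches ≈ 99 % held-out epoch
agreement. The generator's states are spectrally well separated and
stationary within phase; real telemetry has artifacts, drift,
inter-animal variability and ambiguous transitional epochs, none of which
are modeled. Passing these tests therefore demonstrates that the
pipeline's machinery is correct and self-consistent — not that the
classifier would reach the same accuracy on recorded animals. Likewise
the treatment knobs reproduce directions of drug effects, not magnitudes.

## Known limitations

- The Markov chain has geometric dwell times; real bout-duration
  distributions are heavier-tailed, and sleep pressure (homeostasis) is
  not modeled beyond the phase-dependent matrices.
- EEG band mixtures are stationary within a state; no spindles, ripples,
  or artifacts.
- Epoch grids are anchored at recording start, assumed to begin on an
  integer ZT second; 24-h recordings starting at injection time (ZT 0 or
  ZT 12) are the intended use.
- The EDF writer emits the minimal subset of the format the pipeline
  needs (one fixed rate, µV, 1-s records); it is not a general exporter.
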