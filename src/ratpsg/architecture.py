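"""Sleep-architecture analytics on hypnograms.

Definitions (and how their edge cases interact):

* A **bout** is a maximal run of consecutive epochs in one state; a single
  epoch qualifies.
* A **transition** is scored only when the new state persists for two or
  more epochs. A single-epoch excursion therefore is a bout but neither
  scores a transition nor changes the currently scored state — the only
  reading under which both definitions hold at once.
* **Onset latency** of NREM or REM is the time from a phase start to the
  first run of >= 2 consecutive epochs of that state at or after the
  phase start; with no qualifying run the value is missing (NaN).
* Durations, bout counts and mean bout durations are reported per time
  bin (1 h or 6 h); a bout straddling a bin edge is counted once, with
  its full duration, in the bin containing its first epoch.

Treatment contrasts are computed bin-by-bin as percent change from
vehicle (undefined, NaN, where the vehicle value is 0) or as the signed
within-subject difference in native units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ratpsg.core import (
    EPOCH_S,
    EPOCHS_PER_HOUR,
    STATE_NAMES,
    Hypnogram,
    LightDarkSchedule,
    ValidationError,
)

#: Ordered state pairs reported for transition counts.
TRANSITION_PAIRS = (
    ("WAKE", "NREM"),
    ("NREM", "REM"),
    ("REM", "WAKE"),
    ("NREM", "WAKE"),
    ("REM", "NREM"),
    ("WAKE", "REM"),
)

MIN_TRANSITION_EPOCHS = 2  # epochs of the new state required to score


@dataclass(frozen=True)
class Bout:
    """A maximal single-state run."""

    state: int
    start_epoch: int
    length_epochs: int

    @property
    def duration_s(self) -> float:
        return self.length_epochs * EPOCH_S

    @property
    def state_name(self) -> str:
        return STATE_NAMES[self.state]


def _runs(labels: np.ndarray):
    """(state, start, length) for each maximal run, via change points."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_bouts(hypnogram: Hypnogram) -> list[Bout]:
    """Run-length encode the hypnogram; every epoch belongs to one bout."""
    return [Bout(state=s, start_epoch=st, length_epochs=ln) for s, st, ln in _runs(hypnogram.labels)]


def count_transitions(
    hypnogram: Hypnogram, schedule: LightDarkSchedule | None = None
) -> dict:
    """Count scored state transitions per light/dark phase.

    The scored state starts as the first run's state. Scanning runs in
    order, a run of >= 2 epochs whose state differs from the scored state
    scores one transition (scored -> run state) and becomes the new scored
    state; shorter runs are ignored entirely. Each transition is
    attributed to the phase of its first epoch.
    """
    schedule = schedule if schedule is not None else LightDarkSchedule()
    zt = hypnogram.epoch_zt()
    counts = {
        phase: {pair: 0 for pair in TRANSITION_PAIRS} for phase in ("light", "dark")
    }
    runs = _runs(hypnogram.labels)
    scored = runs[0][0]
    for state, start, length in runs[1:]:
        if length < MIN_TRANSITION_EPOCHS or state == scored:
            continue
        pair = (STATE_NAMES[scored], STATE_NAMES[state])
        phase = "light" if schedule.is_light(zt[start]) else "dark"
        counts[phase][pair] += 1
        scored = state
    return counts


def onset_latency(
    hypnogram: Hypnogram,
    state: int,
    phase_start_zt: float,
) -> float:
    """Minutes from a phase start to the first >=2-epoch run of ``state``.

    Returns NaN when no qualifying run occurs in the recording at or
    after the phase start.
    """
    offset_h = (phase_start_zt - hypnogram.start_zt) % 24.0
    start_epoch = int(round(offset_h * EPOCHS_PER_HOUR))
    if start_epoch >= hypnogram.n_epochs:
        raise ValidationError(
            f"phase start ZT {phase_start_zt} is {offset_h:.2f} h after the "
            f"recording start, beyond its {hypnogram.duration_h:.2f} h span"
        )
    labels = hypnogram.labels[start_epoch:]
    for run_state, run_start, run_len in _runs(labels):
        if run_state == state and run_len >= MIN_TRANSITION_EPOCHS:
            return run_start * EPOCH_S / 60.0
    return float("nan")


def bin_durations(
    hypnogram: Hypnogram,
    bin_hours: int = 1,
    schedule: LightDarkSchedule | None = None,
) -> pd.DataFrame:
    """Per-bin, per-state total duration, bout count and mean bout duration.

    Returns a tidy frame with one row per (bin, state): columns
    ``bin_index, bin_start_zt, state, minutes, bout_count, mean_bout_s``.
    A trailing partial bin is dropped. Bouts are attributed to the bin of
    their first epoch and contribute their full length to that bin's
    ``mean_bout_s``.
    """
    if bin_hours not in (1, 6):
        raise ValidationError(f"bin_hours must be 1 or 6, got {bin_hours}")
    schedule = schedule if schedule is not None else LightDarkSchedule()
    epb = bin_hours * EPOCHS_PER_HOUR
    n_bins = hypnogram.n_epochs // epb
    if n_bins == 0:
        raise ValidationError(
            f"hypnogram of {hypnogram.n_epochs} epochs is shorter than one "
            f"{bin_hours}-h bin"
        )
    labels = hypnogram.labels[: n_bins * epb]
    bins = np.arange(labels.size) // epb
    rows = []
    # durations: epoch counts per (bin, state)
    counts = np.zeros((n_bins, 3), dtype=int)
    np.add.at(counts, (bins, labels.astype(int)), 1)
    # bouts attributed by first epoch
    bout_count = np.zeros((n_bins, 3), dtype=int)
    bout_len_sum = np.zeros((n_bins, 3), dtype=float)
    for b in detect_bouts(Hypnogram(labels, start_zt=hypnogram.start_zt)):
        bi = b.start_epoch // epb
        bout_count[bi, b.state] += 1
        bout_len_sum[bi, b.state] += b.duration_s
    for bi in range(n_bins):
        zt0 = (hypnogram.start_zt + bi * bin_hours) % 24.0
        for s in range(3):
            n_bouts = int(bout_count[bi, s])
            rows.append(
                {
                    "bin_index": bi,
                    "bin_start_zt": zt0,
                    "state": STATE_NAMES[s],
                    "minutes": counts[bi, s] * EPOCH_S / 60.0,
                    "bout_count": n_bouts,
                    "mean_bout_s": (bout_len_sum[bi, s] / n_bouts) if n_bouts else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def percent_change(
    treated: pd.DataFrame,
    vehicle: pd.DataFrame,
    metric: str = "minutes",
) -> pd.DataFrame:
    """Per-bin percent change from vehicle: 100 * (treated - vehicle)/vehicle.

    Bins where the vehicle value is 0 are flagged (``defined`` False) and
    carry NaN rather than an infinity.
    """
    keys = ["bin_index", "state"]
    t = treated.reset_index(drop=True)
    v = vehicle.reset_index(drop=True)
    if len(t) != len(v) or not t[keys].equals(v[keys]):
        raise ValidationError("treated and vehicle summaries have mismatched bins/states")
    out = t[keys + ["bin_start_zt"] if "bin_start_zt" in t else keys].copy()
    tv, vv = t[metric].to_numpy(float), v[metric].to_numpy(float)
    defined = vv != 0
    pct = np.full(len(out), np.nan)
    pct[defined] = 100.0 * (tv[defined] - vv[defined]) / vv[defined]
    out["percent_change"] = pct
    out["defined"] = defined
    return out


def absolute_change(
    treated: pd.DataFrame,
    vehicle: pd.DataFrame,
    metric: str = "minutes",
) -> pd.DataFrame:
    """Per-bin within-subject difference, treated - vehicle, in native units."""
    keys = ["bin_index", "state"]
    t = treated.reset_index(drop=True)
    v = vehicle.reset_index(drop=True)
    if len(t) != len(v) or not t[keys].equals(v[keys]):
        raise ValidationError("treated and vehicle summaries have mismatched bins/states")
    out = t[keys + ["bin_start_zt"] if "bin_start_zt" in t else keys].copy()
    out["absolute_change"] = t[metric].to_numpy(float) - v[metric].to_numpy(float)
    return out


def architecture_summary(
    hypnogram: Hypnogram,
    schedule: LightDarkSchedule | None = None,
    bin_hours: int = 6,
) -> dict:
    """Binned durations plus per-phase onsets and transition counts."""
    schedule = schedule if schedule is not None else LightDarkSchedule()
    from ratpsg.core import NREM, REM  # local import to avoid cycles in docs

    onsets = {}
    zt0 = hypnogram.start_zt % 24.0
    for phase_start in np.unique([zt0, (zt0 + 12.0) % 24.0]):
        key = "light" if schedule.is_light(phase_start) else "dark"
        try:
            onsets[key] = {
                "nrem_onset_min": onset_latency(hypnogram, NREM, phase_start),
                "rem_onset_min": onset_latency(hypnogram, REM, phase_start),
            }
        except ValidationError:
            continue
    return {
        "bins": bin_durations(hypnogram, bin_hours, schedule),
        "onsets": onsets,
        "transitions": count_transitions(hypnogram, schedule),
    }
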