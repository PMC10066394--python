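"""Hypnogram architecture: bouts, transitions, onsets, bins, contrasts.

Bout and transition counters are checked against an independent
brute-force scanner over randomized label sequences.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratpsg import (
    LightDarkSchedule,
    absolute_change,
    bin_durations,
    count_transitions,
    detect_bouts,
    onset_latency,
    percent_change,
)
from ratpsg.architecture import TRANSITION_PAIRS
from ratpsg.core import NREM, REM, STATE_NAMES, WAKE, ValidationError
from tests.conftest import make_hypnogram

W, N, R = WAKE, NREM, REM


# --- independent oracles (epoch-by-epoch scan, no run-length encoding) ---

def brute_force_bouts(labels):
    bouts = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            bouts.append((labels[start], start, i - start))
            start = i
    return bouts


def brute_force_transitions(labels):
    """Scored-state scan: a change counts when the new state holds >= 2
    epochs; singles neither count nor change the scored state."""
    bouts = brute_force_bouts(labels)
    scored = bouts[0][0]
    events = []
    for state, start, length in bouts[1:]:
        if length >= 2 and state != scored:
            events.append((scored, state, start))
            scored = state
    return events


class TestBouts:
    def test_worked_example(self):
        """[W,W,N,N,N,R,R,W] -> bouts W(2), N(3), R(2), W(1)."""
        bouts = detect_bouts(make_hypnogram([W, W, N, N, N, R, R, W]))
        assert [(b.state, b.length_epochs) for b in bouts] == [
            (W, 2), (N, 3), (R, 2), (W, 1),
        ]
        counts = {s: sum(1 for b in bouts if b.state == s) for s in (W, N, R)}
        assert counts == {W: 2, N: 1, R: 1}

    def test_single_state_is_one_bout(self):
        bouts = detect_bouts(make_hypnogram([N] * 17))
        assert len(bouts) == 1 and bouts[0].length_epochs == 17
        assert bouts[0].duration_s == 170.0

    def test_alternating_sequence_all_singletons(self):
        bouts = detect_bouts(make_hypnogram([W, N, W, N]))
        assert [b.length_epochs for b in bouts] == [1, 1, 1, 1]

    def test_every_epoch_in_exactly_one_bout(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, 200)
        bouts = detect_bouts(make_hypnogram(labels))
        covered = np.concatenate(
            [np.arange(b.start_epoch, b.start_epoch + b.length_epochs) for b in bouts]
        )
        np.testing.assert_array_equal(covered, np.arange(200))

    def test_oracle_equivalence_random_sequences(self):
        """1000 seeded random sequences: run-length encoder agrees with the
        brute-force epoch scanner on bouts and transitions."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(1, 501))
            labels = rng.integers(0, 3, n)
            hyp = make_hypnogram(labels)
            got = [(b.state, b.start_epoch, b.length_epochs) for b in detect_bouts(hyp)]
            assert got == brute_force_bouts(list(labels))
            trans = count_transitions(hyp)
            total_got = {}
            for phase in trans:
                for pair, c in trans[phase].items():
                    total_got[pair] = total_got.get(pair, 0) + c
            expected = {}
            for a, b, _ in brute_force_transitions(list(labels)):
                pair = (STATE_NAMES[a], STATE_NAMES[b])
                expected[pair] = expected.get(pair, 0) + 1
            assert {k: v for k, v in total_got.items() if v} == expected


class TestTransitions:
    def test_worked_example(self):
        """[W,W,N,N,N,R,R,W]: W->N and N->R score; the final single W does not."""
        trans = count_transitions(make_hypnogram([W, W, N, N, N, R, R, W]))
        light = trans["light"]
        assert light[("WAKE", "NREM")] == 1
        assert light[("NREM", "REM")] == 1
        assert light[("REM", "WAKE")] == 0
        assert sum(light.values()) == 2

    def test_single_epoch_excursion_ignored(self):
        """[N,N,W,N,N]: the lone W is a bout but no transition, and N is
        never 'new' again afterwards."""
        trans = count_transitions(make_hypnogram([N, N, W, N, N]))
        assert sum(trans["light"].values()) + sum(trans["dark"].values()) == 0

    def test_single_state_no_transitions(self):
        trans = count_transitions(make_hypnogram([R] * 50))
        assert sum(trans["light"].values()) + sum(trans["dark"].values()) == 0

    def test_phase_attribution_of_transition(self):
        # transition's first epoch right at the dark boundary
        labels = [W] * 4319 + [W, N, N, N]
        hyp = make_hypnogram(labels, start_zt=0.0)  # epoch 4320 = ZT 12
        trans = count_transitions(hyp)
        assert trans["dark"][("WAKE", "NREM")] == 1
        assert trans["light"][("WAKE", "NREM")] == 0

    def test_transitions_bounded_by_destination_bouts(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 3, 2000)
        hyp = make_hypnogram(labels)
        bouts = detect_bouts(hyp)
        trans = count_transitions(hyp)
        for a, b in TRANSITION_PAIRS:
            total = trans["light"][(a, b)] + trans["dark"][(a, b)]
            dest_bouts = sum(1 for bt in bouts if bt.state_name == b)
            assert total <= dest_bouts


class TestOnsets:
    def test_paper_style_latency(self):
        """A 2-epoch NREM run starting 114 epochs after phase start gives
        19.0 min, the construction behind a typical light-phase NREM onset."""
        labels = [W] * 114 + [N, N] + [W] * 10
        assert onset_latency(make_hypnogram(labels), NREM, 0.0) == 19.0

    def test_onset_at_phase_start_is_zero(self):
        labels = [N, N] + [W] * 10
        assert onset_latency(make_hypnogram(labels), NREM, 0.0) == 0.0

    def test_isolated_singles_give_missing(self):
        labels = [W, R, W, W, R, W, W, W]
        assert np.isnan(onset_latency(make_hypnogram(labels), REM, 0.0))

    def test_run_before_phase_start_not_counted(self):
        labels = [N] * 360 + [W] * 300 + [N, N] + [W] * 58
        hyp = make_hypnogram(labels, start_zt=11.0)
        # phase starts at ZT 12 = epoch 360; first qualifying run at 660
        assert onset_latency(hyp, NREM, 12.0) == (660 - 360) * 10 / 60
        assert onset_latency(hyp, NREM, 11.0) == 0.0

    def test_phase_start_outside_recording_errors(self):
        with pytest.raises(ValidationError, match="beyond"):
            onset_latency(make_hypnogram([W] * 360), NREM, 13.0)


class TestBins:
    def test_all_rem_hour(self):
        df = bin_durations(make_hypnogram([R] * 360), 1)
        by_state = df.set_index("state")["minutes"]
        assert by_state["REM"] == 60.0
        assert by_state["WAKE"] == 0.0 and by_state["NREM"] == 0.0

    def test_durations_conserve_bin_length(self, day_hypnogram):
        for bh in (1, 6):
            df = bin_durations(day_hypnogram, bh)
            sums = df.groupby("bin_index")["minutes"].sum()
            np.testing.assert_allclose(sums, bh * 60.0, atol=1e-9)

    def test_worked_example_counts(self):
        labels = [W] * 180 + [N] * 120 + [R] * 60
        df = bin_durations(make_hypnogram(labels), 1).set_index("state")
        assert df.loc["WAKE", "minutes"] == 30.0 and df.loc["WAKE", "bout_count"] == 1
        assert df.loc["NREM", "minutes"] == 20.0 and df.loc["NREM", "bout_count"] == 1
        assert df.loc["REM", "minutes"] == 10.0 and df.loc["REM", "bout_count"] == 1
        assert df.loc["NREM", "mean_bout_s"] == 1200.0

    def test_straddling_bout_counted_once_in_start_bin(self):
        labels = [W] * 300 + [N] * 120 + [W] * 300  # NREM spans the 1-h edge
        df = bin_durations(make_hypnogram(labels), 1)
        nrem = df[df["state"] == "NREM"]
        assert nrem["bout_count"].tolist() == [1, 0]
        # full bout length credited to its starting bin
        assert nrem["mean_bout_s"].iloc[0] == 1200.0
        # but per-bin durations still split by epochs actually inside
        assert nrem["minutes"].tolist() == [10.0, 10.0]

    def test_trailing_partial_bin_dropped(self):
        df = bin_durations(make_hypnogram([W] * 400), 1)
        assert df["bin_index"].nunique() == 1

    def test_bad_bin_size_rejected(self):
        with pytest.raises(ValidationError, match="bin_hours"):
            bin_durations(make_hypnogram([W] * 720), 2)

    def test_total_bouts_equal_runs(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 3, 720)
        df = bin_durations(make_hypnogram(labels), 1)
        assert df["bout_count"].sum() == len(brute_force_bouts(list(labels)))

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_merging_singleton_never_increases_bouts(self, seed):
        """Relabeling a single epoch between two same-state bouts merges
        them: total bout count never increases."""
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, 100)
        runs = brute_force_bouts(list(labels))
        singles = [
            (i, s)
            for k, (s, i, ln) in enumerate(runs[1:-1], start=1)
            if ln == 1 and runs[k - 1][0] == runs[k + 1][0]
        ]
        before = len(runs)
        for idx, _ in singles:
            merged = labels.copy()
            merged[idx] = labels[idx - 1]
            after = len(brute_force_bouts(list(merged)))
            assert after <= before


class TestContrasts:
    @pytest.fixture()
    def pair(self):
        v = bin_durations(make_hypnogram([W] * 180 + [N] * 120 + [R] * 60), 1)
        t = v.copy()
        t.loc[t["state"] == "REM", "minutes"] = 71 / 6  # REM 10 -> 11.833 min
        return t, v

    def test_percent_change_arithmetic(self):
        v = bin_durations(make_hypnogram([N] * 360), 1)
        t = v.copy()
        t.loc[t["state"] == "NREM", "minutes"] = 71.0
        v.loc[v["state"] == "NREM", "minutes"] = 60.0
        out = percent_change(t, v)
        got = out[out["state"] == "NREM"]["percent_change"].iloc[0]
        assert got == pytest.approx(100 * 11 / 60, abs=1e-9)  # +18.3%

    def test_identical_inputs_zero(self, pair):
        _, v = pair
        out = percent_change(v, v)
        assert (out["percent_change"].dropna() == 0).all()
        out_abs = absolute_change(v, v)
        assert (out_abs["absolute_change"] == 0).all()

    def test_zero_vehicle_flagged_not_infinite(self):
        v = bin_durations(make_hypnogram([W] * 360), 1)
        t = bin_durations(make_hypnogram([W] * 300 + [N] * 60), 1)
        out = percent_change(t, v)
        nrem = out[out["state"] == "NREM"]
        assert not nrem["defined"].iloc[0]
        assert np.isnan(nrem["percent_change"].iloc[0])
        assert np.isfinite(out["percent_change"].dropna()).all()

    def test_absolute_change_antisymmetric(self, pair):
        t, v = pair
        fwd = absolute_change(t, v)["absolute_change"].to_numpy()
        rev = absolute_change(v, t)["absolute_change"].to_numpy()
        np.testing.assert_allclose(fwd, -rev)

    def test_mismatched_bins_rejected(self, pair):
        t, v = pair
        with pytest.raises(ValidationError, match="mismatch"):
            percent_change(t.iloc[:-3], v)
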