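"""Sleep-architecture metrics from a hypnogram.

Computes bouts, scored transitions, onset latencies and 6-h binned
durations for one simulated day and prints them the way a sleep study
would tabulate them.
"""

import numpy as np

from ratpsg import (
    LightDarkSchedule,
    bin_durations,
    count_transitions,
    detect_bouts,
    onset_latency,
    simulate_state_sequence,
)
from ratpsg.core import NREM, REM

hyp = simulate_state_sequence(duration_h=24.0, seed=5)
schedule = LightDarkSchedule()

bouts = detect_bouts(hyp)
for name in ("WAKE", "NREM", "REM"):
    ln = [b.duration_s for b in bouts if b.state_name == name]
    print(f"{name:>5}: {len(ln):4d} bouts, mean {np.mean(ln) / 60:.1f} min")

print("\nonset latency from phase start (first run of >= 2 epochs):")
print(f"  NREM, light: {onset_latency(hyp, NREM, 0.0):.1f} min")
print(f"  REM,  light: {onset_latency(hyp, REM, 0.0):.1f} min")
print(f"  NREM, dark:  {onset_latency(hyp, NREM, 12.0):.1f} min")

trans = count_transitions(hyp, schedule)
print("\nscored transitions (new state held >= 2 epochs):")
for phase in ("light", "dark"):
    top = {f"{a}->{b}": n for (a, b), n in trans[phase].items() if n}
    print(f"  {phase}: {top}")

print("\n6-h binned state durations (minutes):")
bins = bin_durations(hyp, bin_hours=6, schedule=schedule)
print(bins.pivot(index="bin_start_zt", columns="state", values="minutes"))

# Durations per bin sum to 360 min; the light bins carry most NREM/REM,
# the dark bins most wake — the rodent rest/active rhythm.
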