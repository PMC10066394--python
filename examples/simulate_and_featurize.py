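"""Simulate one virtual rat-day of telemetry and featurize it.

Prints the per-phase state occupancies of the generated hypnogram and a
few epoch feature vectors, showing how wake/NREM/REM differ spectrally.
"""

import numpy as np

from ratpsg import STATE_NAMES, featurize_recording, simulate_recording
from ratpsg.spectral import BANDS

sim = simulate_recording(duration_h=24.0, seed=7, sampling_rate=250.0)
hyp = sim.truth_hypnogram

zt = hyp.epoch_zt()
for phase, mask in (("light (ZT 0-12)", zt < 12), ("dark (ZT 12-24)", zt >= 12)):
    occ = np.bincount(hyp.labels[mask], minlength=3) / mask.sum()
    print(f"{phase}: " + ", ".join(
        f"{name} {100 * f:.0f}%" for name, f in zip(STATE_NAMES, occ)
    ))

feats, epochs = featurize_recording(sim.recording)
print(f"\nfeatures: {feats.shape[0]} epochs x {feats.shape[1]} values "
      "(40 spectral channels + EMG RMS + activity)")

print("\nmean band-power fraction and EMG by state:")
print(f"{'state':>5} " + " ".join(f"{b.name:>6}" for b in BANDS) + "   EMG uV")
for s, name in enumerate(STATE_NAMES):
    rows = feats[hyp.labels == s]
    bands = [rows[:, :40][:, b.channel_mask()].sum(axis=1).mean() for b in BANDS]
    print(f"{name:>5} " + " ".join(f"{v:6.2f}" for v in bands)
          + f"   {rows[:, 40].mean():6.1f}")

# NREM is delta-dominant and high-EMG wake separates from atonic REM —
# the structure the vigilance-state classifier exploits.
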