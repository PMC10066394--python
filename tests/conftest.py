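import numpy as np
import pytest

from ratpsg import (
    Hypnogram,
    LightDarkSchedule,
    simulate_recording,
)


@pytest.fixture(scope="session")
def schedule():
    return LightDarkSchedule()


@pytest.fixture(scope="session")
def short_sim():
    """A 30-min default simulation at 100 Hz, shared across tests."""
    return simulate_recording(duration_h=0.5, seed=11, sampling_rate=100.0)


@pytest.fixture(scope="session")
def day_hypnogram():
    """A full-day state sequence (no signals) from the default chain."""
    from ratpsg import simulate_state_sequence

    return simulate_state_sequence(duration_h=24.0, seed=42)


def make_hypnogram(labels, start_zt=0.0):
    return Hypnogram(labels=np.asarray(labels, dtype=np.int8), start_zt=start_zt)
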