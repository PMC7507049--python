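import numpy as np
import pandas as pd
import pytest

from avconn.connectivity import EpochArray
from avconn.synthetic import EEGGenSpec, OscillatorSource, generate_eeg_dataset


def make_trial_table(rows):
    """Build a minimal trial table from (subject, stim_type, rt_ms) tuples."""
    recs = [
        {
            "subject": s,
            "group": "younger",
            "intensity": "high",
            "stim_type": st,
            "is_target": True,
            "rt_ms": rt,
            "correct": rt is not None and not np.isnan(rt),
        }
        for s, st, rt in rows
    ]
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def lagged_pair_epochs():
    """Noiseless two-channel epochs: a rigid pi/4 lag at 10 Hz, 3 trials."""
    spec = EEGGenSpec(
        n_channels=2,
        n_trials=3,
        sources=(
            OscillatorSource(freq_hz=10.0, channel_lags={0: 0.0, 1: np.pi / 4}, kappa=1e6),
        ),
        noise_sd=0.0,
        seed=11,
    )
    (epochs,) = generate_eeg_dataset(spec, 1)
    return epochs


@pytest.fixture
def random_epochs():
    """Small random epochs for structural tests."""
    rng = np.random.default_rng(3)
    return EpochArray(
        data=rng.normal(size=(4, 700, 6)),
        channel_names=("c0", "c1", "c2", "c3"),
    )
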