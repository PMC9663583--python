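import numpy as np
import pytest

from brainstates import synth
from brainstates.containers import CONDITIONS, DEFAULT_CHANNELS, TrialSet


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture()
def small_trialset(rng):
    """8 random trials, 275 samples, 8 channels, balanced conditions."""
    n, t, c = 8, 275, 8
    data = rng.standard_normal((n, t, c))
    condition = np.array([CONDITIONS[i % 4] for i in range(n)])
    subject = np.array([f"S{1 + i % 2:02d}" for i in range(n)])
    return TrialSet(data=data, fs=250.0, channels=DEFAULT_CHANNELS,
                    condition=condition, subject=subject,
                    event_sample=np.full(n, 250),
                    meta={"note": "random fixture"})


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-state dataset shared by pipeline-level tests."""
    return synth.make_dataset(n_trials_per_condition=25, n_subjects=8, seed=7)
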