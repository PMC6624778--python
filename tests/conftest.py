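import numpy as np
import pytest

from p300hist import EEGSession, RunConfig, SpellerMatrix, StimulusEvent


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def matrix():
    return SpellerMatrix()


def toy_session(n_trials=1, k_a=1, fs=16.0, soa=4, n_max=16, gap=16,
                n_channels=1, orders=None, rng=None, noise_sd=1.0):
    """Small valid session at an already-decimated rate.

    ``orders[t][i]`` optionally fixes the location order of sequence ``i``
    of trial ``t``; otherwise a random permutation is drawn.
    """
    rng = rng or np.random.default_rng(0)
    events = []
    t = 0
    for trial in range(1, n_trials + 1):
        for seq in range(1, k_a + 1):
            if orders is not None:
                perm = orders[trial - 1][seq - 1]
            else:
                perm = rng.permutation(12) + 1
            for loc in perm:
                events.append(StimulusEvent(t, int(loc), seq, trial))
                t += soa
        t += gap
    n = t + n_max
    samples = rng.normal(0.0, noise_sd, size=(n, n_channels))
    labels = [f"ch{c}" for c in range(n_channels)]
    return EEGSession(samples, fs, labels, events).validate()
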