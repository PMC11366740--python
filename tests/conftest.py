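import numpy as np
import pytest

from emomusic import synthdata as sd


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small, fast study conditions: 5 subjects x 1 trial x 20 s."""
    return sd.SynthConfig(n_subjects=5, n_trials=1, trial_s=20.0, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    return sd.gen_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def study_dataset():
    """Default study conditions (5 subjects x 3 trials x 60 s)."""
    return sd.gen_dataset(sd.SynthConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
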