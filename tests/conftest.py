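import numpy as np
import pytest

from neurostack import synth


@pytest.fixture(scope="session")
def microwire_session():
    """One seeded micro-wire session (4 channels, 30 s at 10 kHz) shared by
    the artifact and spike tests."""
    rec, truth = synth.gen_microwire(n_channels=4, fs=10_000.0, duration_s=30.0,
                                     seed=11)
    return rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
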