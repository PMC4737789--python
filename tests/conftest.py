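import numpy as np
import pytest

from cadscore.simulator import SubjectParams, simulate_pcg


@pytest.fixture(scope="session")
def clean_60bpm():
    """25 s clean recording at 60 bpm with S1-S4 and default murmur level."""
    return simulate_pcg(
        SubjectParams(heart_rate_bpm=60.0, seed=1),
        duration_s=25.0, sample_rate=8000, breath_holds=None,
    )


@pytest.fixture(scope="session")
def murmur_pair():
    """Same subject at murmur low-frequency gain 0 dB and +10 dB."""
    out = {}
    for gain in (0.0, 10.0):
        out[gain] = simulate_pcg(
            SubjectParams(seed=2, murmur_low_gain_db=gain),
            duration_s=25.0, breath_holds=None,
        )
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
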