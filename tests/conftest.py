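import numpy as np
import pytest

from onoffnet.markov import MarkovRates
from onoffnet.sessions import SessionConfig, generate_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def symmetric_rates():
    return MarkovRates(10.0, 10.0)


@pytest.fixture(scope="session")
def small_two_phase_session():
    """16-channel two-phase session, one condition, 1 s trials."""
    cfg = SessionConfig(
        n_trials_per_condition=60,
        n_attention=1,
        n_orientations=1,
        trial_window_range=(1.0, 1.0),
        rates_control=MarkovRates(10.0, 10.0),
        rates_attention=MarkovRates(10.0, 10.0),
        seed=7,
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def recovery_session():
    """Larger session for EM parameter recovery (500 trials x 1 s)."""
    cfg = SessionConfig(
        n_trials_per_condition=500,
        n_attention=1,
        n_orientations=1,
        trial_window_range=(1.0, 1.0),
        rates_control=MarkovRates(10.0, 10.0),
        rates_attention=MarkovRates(10.0, 10.0),
        seed=11,
    )
    return generate_session(cfg)
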