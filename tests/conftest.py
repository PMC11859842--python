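import numpy as np
import pytest

from nocipipe import synth


@pytest.fixture(scope="session")
def short_session():
    """A 300 s event-free session used by many signal-level tests."""
    spec = synth.SessionSpec(duration_s=300.0, seed=2)
    return synth.generate_session(spec)


@pytest.fixture(scope="session")
def long_session():
    """A 30 min session with the three surgical events."""
    spec = synth.SessionSpec(
        duration_s=1800.0, seed=3,
        events=[("t1", 400.0), ("t2", 900.0), ("t3", 1400.0)])
    return synth.generate_session(spec)


@pytest.fixture(scope="session")
def long_features(long_session):
    from nocipipe.features import build_feature_matrix

    b = long_session
    return build_feature_matrix(b.ecg, b.ppg, b.eeg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
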