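import numpy as np
import pytest

from neurofuse.containers import FeatureMatrix
from neurofuse.eeg_features import extract_eeg_features
from neurofuse.fnirs_features import extract_fnirs_features
from neurofuse.pipeline import RunConfig, preprocess_eeg, preprocess_fnirs
from neurofuse.synthetic import SimConfig, simulate_session


@pytest.fixture(scope="session")
def default_session():
    """One full default synthetic session (840 s paradigm), shared suite-wide."""
    return simulate_session(SimConfig(seed=7))


@pytest.fixture(scope="session")
def feature_tables(default_session):
    """Packaged 1 Hz feature tables (EEG 400x799, fNIRS 400x264)."""
    eeg_rec, fnirs_rec, _ = default_session
    cfg = RunConfig()
    eeg_fm = FeatureMatrix.vstack(
        [extract_eeg_features(ep) for ep in preprocess_eeg(eeg_rec, cfg)]
    )
    fnirs_fm = FeatureMatrix.vstack(
        [extract_fnirs_features(ep) for ep in preprocess_fnirs(fnirs_rec, cfg)]
    )
    return eeg_fm, fnirs_fm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
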