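import numpy as np
import pytest

from periemg.features import extract_feature_matrix, slice_epochs
from periemg.preprocess import preprocess_chain
from periemg.simulate import ProtocolSpec, simulate_session
from periemg.unmix import fit_ica


@pytest.fixture(scope="session")
def short_protocol() -> ProtocolSpec:
    """Full label vocabulary, compressed timing — for fast structural tests."""
    return ProtocolSpec(
        reps_per_block=2,
        blocks=1,
        action_duration_s=0.5,
        rest_duration_s=0.25,
        cue_duration_s=0.25,
        interblock_rest_s=1.0,
    )


@pytest.fixture(scope="session")
def default_session():
    """One full default-protocol session (3 blocks, 150 labeled epochs)."""
    recording, epochs = simulate_session(seed=101)
    return recording, epochs


@pytest.fixture(scope="session")
def default_session_features(default_session):
    """Feature matrix of the default session after the full pipeline:
    conditioning chain -> 8-component ICA -> 64 features per epoch."""
    recording, epochs = default_session
    clean = preprocess_chain(recording)
    result = fit_ica(clean, n_components=8, seed=101)
    blocks = slice_epochs(result.components, epochs)
    return extract_feature_matrix(blocks, recording.rate, labels=epochs)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
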