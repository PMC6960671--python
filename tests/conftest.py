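import numpy as np
import pytest

import pepdetect as P

# compact 10-10 cap used by unit tests where a full 60-channel montage would
# only slow things down; keeps the key fronto-central/lateral sites
SMALL_CAP = ("FZ", "FCZ", "CZ", "C3", "C4", "F3", "F4", "FC1", "FC2", "CPZ")


@pytest.fixture(scope="session")
def default_config():
    return P.SimulationConfig()


@pytest.fixture(scope="session")
def default_session42():
    """Full-size default session (60 channels, 50 trials), seed 42."""
    cfg = P.SimulationConfig(seed=42)
    return cfg, P.generate_session(cfg)


@pytest.fixture(scope="session")
def small_session():
    """Reduced session for pipeline unit tests: 20 trials, short rests."""
    cfg = P.SimulationConfig(n_trials=20, rest_duration_range=(5.0, 7.0), seed=7)
    return cfg, P.generate_session(cfg)


@pytest.fixture(scope="session")
def small_epochs(small_session):
    """Preprocessed (filtered, 50 Hz) onset-locked epochs of small_session."""
    _, (rec, _, _) = small_session
    pc = P.PipelineConfig()
    _, epochs = P.preprocess_session(rec, pc.preprocessing)
    return epochs


@pytest.fixture()
def tiny_cap_config():
    return P.SimulationConfig(
        channel_labels=SMALL_CAP,
        n_trials=4,
        rest_duration_range=(5.0, 6.0),
        seed=3,
    )


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
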