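import numpy as np
import pytest
from hypothesis import settings

from bcihier.config import PipelineConfig
from bcihier.pipeline import session_epochs
from bcihier.simulate import make_subject_suite

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def scaled_config(**overrides) -> PipelineConfig:
    """Pipeline configuration scaled to the small simulated subjects used
    throughout the tests (fewer clusters and a reduced K grid, matching the
    ~64-row level-1 training sets)."""
    defaults = dict(k=12, ic_threshold=0.8,
                    k_grid=(4, 6, 8, 10, 14, 18, 24))
    defaults.update(overrides)
    return PipelineConfig(**defaults)


@pytest.fixture(scope="session")
def expert_small():
    """Small high-skill synthetic subject: 16 channels, 24 trials/class."""
    session, truth = make_subject_suite("expert", seed=3, n_channels=16,
                                        n_trials_per_class=24)
    return session, truth


@pytest.fixture(scope="session")
def expert_epochs(expert_small):
    session, _ = expert_small
    return session_epochs(session, scaled_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
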