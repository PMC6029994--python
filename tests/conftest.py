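import numpy as np
import pytest

from simekit import FitConfig, generate_study, generate_truth
from simekit.kinetics import FrameSchedule


@pytest.fixture(scope="session")
def default_truth():
    return generate_truth("default", seed=0)


@pytest.fixture(scope="session")
def noiseless_study(default_truth):
    return generate_study(default_truth, noise="none", seed=1)


@pytest.fixture(scope="session")
def default_schedule():
    return FrameSchedule.default()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def fast_config():
    """Coarser, cheaper optimiser settings for smoke-level fit tests."""
    return FitConfig(multistarts=1, seed=0, fine_step=0.05)
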