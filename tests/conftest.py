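import numpy as np
import pytest

from myoscore.config import PipelineConfig
from myoscore.pipeline import run_study
from myoscore.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def study():
    """Full-scale synthetic study: 150+150 cells, independent train/test
    experiments, all three classifier modes. Shared across tests because
    training is the expensive step."""
    return run_study(n_cells=150, seed=0)


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated experiment for structural tests."""
    return simulate_experiment(SimConfig(n_cells_per_condition=20, seed=42))


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
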