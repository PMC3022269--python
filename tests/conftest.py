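import numpy as np
import pytest

from tetraqtl import QTLEffects, SimulationConfig, simulate_dataset

STUDY_EFFECTS = QTLEffects(mu=1.0, a1=0.6, a2=0.6, a3=0.6,
                           d12=0.5, d13=0.5, d14=0.5,
                           d23=0.5, d24=0.5, d34=0.5)


@pytest.fixture(scope="session")
def study_effects():
    """Genetic effects of the reference simulation design."""
    return STUDY_EFFECTS


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset for fast estimator checks."""
    config = SimulationConfig(n=120, alpha=0.3, r=0.05,
                              effects=STUDY_EFFECTS, h2=0.4, seed=42)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def standard_dataset():
    """An n=400 dataset at the reference study conditions."""
    config = SimulationConfig(n=400, alpha=0.3, r=0.05,
                              effects=STUDY_EFFECTS, h2=0.4, seed=7)
    return simulate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
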