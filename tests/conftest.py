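import numpy as np
import pytest

from pointcount import DistanceBinning, ScenarioConfig, TimeRemovalScheme, simulate_dataset


@pytest.fixture(scope="session")
def binning():
    return DistanceBinning()


@pytest.fixture(scope="session")
def removal():
    return TimeRemovalScheme()


@pytest.fixture(scope="session")
def easy_dataset():
    """Moderate-effort dataset at the well-identified scenario corner."""
    cfg = ScenarioConfig(p_presence=0.8, availability=0.8, n_points=300, n_visits=3)
    return simulate_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
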