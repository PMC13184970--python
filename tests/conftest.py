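import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """4 vOTUs × 4 samples with zeros, typical zero-inflated shape."""
    return pd.DataFrame(
        [[0.0, 2.0, 1.0, 0.5],
         [1.0, 0.0, 3.0, 0.5],
         [0.0, 0.0, 2.0, 0.5],
         [4.0, 1.0, 0.0, 0.5]],
        index=[f"vOTU_{i}" for i in range(4)],
        columns=[f"S{i}" for i in range(4)],
    )


@pytest.fixture
def two_ecosystem():
    import virotu

    cfg = virotu.SimulationConfig(seed=7)
    return virotu.generate_two_ecosystem_dataset(cfg)


@pytest.fixture
def time_series():
    import virotu

    cfg = virotu.SimulationConfig(seed=11)
    return virotu.generate_time_series(cfg)
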