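import numpy as np
import pandas as pd
import pytest

import tricause as tc


@pytest.fixture(scope="session")
def base1_config():
    return tc.make_scenario_config("base1", {})


@pytest.fixture(scope="session")
def base1_data(base1_config):
    return tc.simulate_dataset(base1_config, seed=42)


@pytest.fixture(scope="session")
def poa1_data():
    return tc.simulate_dataset(tc.make_scenario_config("poa1", {}), seed=42)


def random_frame(n: int = 400, seed: int = 0) -> pd.DataFrame:
    """Structureless dataset: all variables mutually independent."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "patient_id": np.arange(n),
        "cluster_id": np.repeat(np.arange(n // 20), 20),
        "z": np.repeat(rng.integers(0, 2, n // 20), 20),
        "x": rng.integers(0, 2, n),
        "y0": rng.integers(0, 2, n),
        "y1": rng.integers(0, 2, n),
        "w0": rng.standard_normal(n),
        "w1": rng.standard_normal(n),
    })


@pytest.fixture
def noise_frame():
    return random_frame()
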