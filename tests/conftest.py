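import numpy as np
import pandas as pd
import pytest

from longomics import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config synthetic cohort shared across read-only tests."""
    return simulate_dataset(SimConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def toy_matrix(values, columns=None, index=None):
    arr = np.asarray(values, dtype=float)
    columns = columns or [f"a{j}" for j in range(arr.shape[1])]
    index = index or [f"s{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, columns=columns, index=index)
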