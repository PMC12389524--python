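import numpy as np
import pandas as pd
import pytest

from mixqsar.datasets import DescriptorTable
from mixqsar.synthetic import SyntheticConfig, make_synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def linear_table():
    """Noise-free linear dataset: y = 2*inf1 - 1.5*inf2 + inf3."""
    config = SyntheticConfig(
        n_compounds=60,
        n_informative=3,
        n_redundant=0,
        n_noise=3,
        noise_sd=0.0,
        response_kind="linear",
        coefficients=[2.0, -1.5, 1.0],
        seed=42,
    )
    table, truth = make_synthetic_dataset(config)
    return table, truth


@pytest.fixture
def small_table():
    """Tiny handmade table for loader/split round trips."""
    return DescriptorTable(
        ["a", "b", "c", "d", "e"],
        pd.DataFrame({"d1": [0.0, 1.0, 2.0, 3.0, 4.0], "d2": [1.0, 0.5, 0.0, -0.5, -1.0]}),
        np.array([0.1, 0.9, 2.1, 3.0, 3.9]),
    )
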