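import numpy as np
import pandas as pd
import pytest

from metbmikit.io import OmicsLayer
from metbmikit.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort-scale synthetic dataset shared across tests (seed 5)."""
    layers, cohort, truth = generate_cohort(GeneratorConfig(seed=5))
    return layers, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_layer():
    values = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.5]])
    return OmicsLayer("demo", ["s1", "s2", "s3"], ["f1", "f2"], values, "raw")


@pytest.fixture()
def toy_cohort(rng):
    """Small cohort table with all six sex x WHO strata populated."""
    n = 240
    bmi = np.concatenate([
        rng.uniform(19, 24.9, n // 3),
        rng.uniform(25, 29.9, n // 3),
        rng.uniform(30, 40, n // 3),
    ])
    sex = np.tile([0, 1], n // 2)
    return pd.DataFrame({
        "age": rng.uniform(50, 65, n),
        "sex": sex,
        "BMI": bmi,
    }, index=[f"S{i:04d}" for i in range(n)])
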