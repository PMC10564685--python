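import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import permwell as pw

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> pw.SyntheticSpec:
    """A small planted-signal generating model used across tests."""
    return pw.SyntheticSpec(
        n_subjects=200,
        intercept=5.0,
        noise_sd=2.0,
        outcome_scale=(-1000.0, 1000.0),
        seed=7,
    ).with_effects({"Relation-Impact": 4.0, "Exercise": 3.0, "Communication": 2.0})


@pytest.fixture(scope="session")
def small_data(small_spec) -> tuple[pd.DataFrame, pd.Series]:
    X = pw.generate_predictors(small_spec)
    y = pw.generate_outcome(X, small_spec)
    return X, y


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230101)
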