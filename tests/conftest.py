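import numpy as np
import pandas as pd
import pytest

from ccbt_cea import GeneratorConfig, ImputationConfig
from ccbt_cea.synthetic_trial import generate_trial, induce_missingness


@pytest.fixture(scope="session")
def default_gen() -> GeneratorConfig:
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def trial_complete(default_gen) -> pd.DataFrame:
    return generate_trial(default_gen)


@pytest.fixture(scope="session")
def trial_missing(default_gen, trial_complete) -> pd.DataFrame:
    return induce_missingness(trial_complete, default_gen)


@pytest.fixture(scope="session")
def small_imp() -> ImputationConfig:
    return ImputationConfig(m=5, k_donors=5, n_cycles=5, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
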