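import warnings

import numpy as np
import pytest

from radpatho import synthdata


@pytest.fixture(autouse=True)
def _quiet_sklearn():
    """Silence library convergence chatter so real warnings stay visible."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*converge.*")
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield


@pytest.fixture(scope="session")
def spec():
    return synthdata.SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def cohort(spec):
    return synthdata.generate_cohort(spec)


@pytest.fixture(scope="session")
def blocks(spec, cohort):
    return synthdata.generate_feature_blocks(cohort, spec)


@pytest.fixture(scope="session")
def train_cohort(cohort):
    return cohort[cohort["split"] == "train"].reset_index(drop=True)


@pytest.fixture(scope="session")
def expression(spec, train_cohort):
    return synthdata.generate_expression(train_cohort, spec)


@pytest.fixture()
def rng():
    # fresh, identical stream per test: deterministic and order-independent
    return np.random.default_rng(12345)
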