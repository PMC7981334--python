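import numpy as np
import pytest

from fcaging import synthetic
from fcaging.study import StudyConfig, run_synthetic_study


@pytest.fixture(scope="session")
def study_result():
    """One full synthetic study (60 subjects, 60 nodes), shared across tests."""
    return run_synthetic_study(StudyConfig(seed=1))


@pytest.fixture(scope="session")
def default_cohort():
    return synthetic.make_cohort(synthetic.CohortSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
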