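import numpy as np
import pytest

from textquit.banks import Arm, generate_fixture_banks
from textquit.cohort import BehaviorParams, CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def fixture_banks():
    iv, ctl = generate_fixture_banks(seed=1)
    return {Arm.INTERVENTION: iv, Arm.CONTROL: ctl}


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n=200, seed=3))


@pytest.fixture(scope="session")
def default_params():
    return BehaviorParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
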