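import numpy as np
import pytest

from oncotraj import StudyDesign, get_model, simulate_cohort


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def m1():
    return get_model("m1")


@pytest.fixture(scope="session")
def m2():
    return get_model("m2")


@pytest.fixture(scope="session")
def m1_cohort(m1, design):
    """Small complete M1 cohort shared across likelihood tests."""
    return simulate_cohort(m1, 40, design, seed=101)


@pytest.fixture(scope="session")
def oracle_theta():
    """A deliberately event-rich parameter set for interval-level checks."""
    return {
        "beta": 0.5,
        "m_basal": 0.05,
        "m_size": 0.1,
        "d_size": 0.01,
        "d_metas": 0.2,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
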