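import numpy as np
import pytest

import apcpolish as ap


@pytest.fixture(scope="session")
def males():
    return ap.load_fixture("hcc_males")


@pytest.fixture(scope="session")
def females():
    return ap.load_fixture("hcc_females")


@pytest.fixture(scope="session")
def males_dec(males):
    return ap.median_polish(males)


@pytest.fixture(scope="session")
def females_dec(females):
    return ap.median_polish(females)


@pytest.fixture
def small_table():
    """2x2 minimal valid table."""
    return ap.AgePeriodTable(
        age_labels=("40–44", "45–49"),
        period_labels=("1976–1980", "1981–1985"),
        rates=np.array([[1.0, 2.0], [3.0, 4.0]]),
    )


@pytest.fixture
def synthetic_spec():
    """Sparse cohort effects that median polish passes through exactly."""
    I, J = 10, 7
    alpha = np.linspace(-1.2, 0.9, I)
    alpha -= np.median(alpha)
    beta = np.linspace(-0.3, 0.3, J)
    beta -= np.median(beta)
    gamma = np.zeros(I + J - 1)
    gamma[2], gamma[7], gamma[12] = 0.3, -0.3, 0.25
    return ap.SyntheticAPCSpec(
        I=I, J=J, mu=-6.5, alpha=alpha, beta=beta, gamma=gamma,
        population=1e7, seed=123,
    )
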