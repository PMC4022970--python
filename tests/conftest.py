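import numpy as np
import pytest

from logburr import LogBurrModel, fit_laplace, locomotive_data


@pytest.fixture(scope="session")
def locomotive():
    return locomotive_data()


@pytest.fixture(scope="session")
def logistic_model():
    return LogBurrModel(k=1.0)


@pytest.fixture(scope="session")
def weibull_model():
    return LogBurrModel(k=30.0)


@pytest.fixture(scope="session")
def logistic_fit(locomotive, logistic_model):
    return fit_laplace(locomotive, logistic_model)


@pytest.fixture(scope="session")
def weibull_fit(locomotive, weibull_model):
    return fit_laplace(locomotive, weibull_model)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
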