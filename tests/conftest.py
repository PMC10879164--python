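import numpy as np
import pytest

import bioage_fmd as bf


@pytest.fixture(scope="session")
def toy_kdm_params():
    """Two-marker toy: x1 = 10 + 1.0*age (s=5), x2 = 100 - 2.0*age (s=10)."""
    return bf.KDMParameters(
        markers=("m1", "m2"),
        k=np.array([1.0, -2.0]),
        q=np.array([10.0, 100.0]),
        s=np.array([5.0, 10.0]),
        s_ba2=25.0,
    )


@pytest.fixture(scope="session")
def marker_model():
    return bf.MarkerGenerativeModel()


@pytest.fixture(scope="session")
def true_mortality():
    return bf.GompertzModel(
        betas={"age": 0.04, "bioage": 0.05}, const=-11.0, gamma=0.09
    )


@pytest.fixture(scope="session")
def reference_cohort(marker_model, true_mortality):
    """A 5000-person synthetic reference population, shared across tests."""
    return bf.generate_reference_population(
        marker_model, true_mortality, n=5000, censor_horizon=23.0, seed=1
    )


@pytest.fixture(scope="session")
def fitted_kdm(reference_cohort):
    return bf.KDM(reference_cohort).fit()
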