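import numpy as np
import pytest

from extractopt.design import build_box_behnken, default_factors
from extractopt.io import load_bbd_responses
from extractopt.rsm import QuadraticModel, fit_quadratic


@pytest.fixture(scope="session")
def design():
    return build_box_behnken(default_factors(), n_center=3)


@pytest.fixture(scope="session")
def c1_tpc(design):
    """C1 TPC means + published predicted column."""
    return load_bbd_responses("TPC", "C1")


@pytest.fixture(scope="session")
def c1_tpc_fit(design, c1_tpc):
    return fit_quadratic(design, c1_tpc[0])


@pytest.fixture(scope="session")
def truth_model(c1_tpc_fit):
    """A realistic coded-space quadratic used as simulation ground truth."""
    return c1_tpc_fit.model


@pytest.fixture
def simple_coded_model():
    """Hand-specified coded model for exactness checks."""
    coef = np.array([100.0, 5.0, -3.0, 8.0, -2.0, 1.5, -4.0, 0.6, -1.2, 2.5])
    return QuadraticModel(
        coef=coef, parameterization="coded", factors=default_factors(),
        response_name="synthetic",
    )
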