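import numpy as np
import pytest

import dcmnet as d


@pytest.fixture(scope="session")
def design():
    """The study's block design: TR 4 s, 100 volumes, 40 s alternating blocks."""
    return d.make_design()


@pytest.fixture(scope="session")
def model11():
    return d.get_model(11)


@pytest.fixture(scope="session")
def reduced_model():
    """A 3-region chain with one reciprocal pair, driven at the first region."""
    a_mask = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=bool)
    c_mask = np.array([1, 0, 0], dtype=bool)
    return d.ReducedModel(a_mask=a_mask, c_mask=c_mask, region_labels=("r1", "r2", "r3"))


@pytest.fixture(scope="session")
def reduced_truth():
    """Ground-truth parameters for the reduced model, near the priors."""
    A = np.zeros((3, 3))
    A[0, 1] = 0.2
    A[1, 0] = 0.15
    A[1, 2] = -0.1
    A[2, 1] = 0.25
    return d.DCMParameters(
        A=A,
        self_log_scale=np.array([0.1, -0.1, 0.05]),
        C=np.array([0.4, 0.0, 0.0]),
        hemo=d.HemodynamicParams.from_log_scales(
            [0.05, -0.05, 0.0], [0.1, 0.0, -0.1], [0.0, 0.05, -0.05]
        ),
    )


@pytest.fixture(scope="session")
def noiseless_reduced_session(reduced_model, reduced_truth, design):
    return d.integrate_dcm(reduced_model, reduced_truth, design, noise=None)
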