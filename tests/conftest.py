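import numpy as np
import pytest

from rsmferm import datasets, fit_first_order, fit_quadratic


@pytest.fixture(scope="session")
def pb_data():
    return datasets.pb_screen()


@pytest.fixture(scope="session")
def pb_fit(pb_data):
    design, responses = pb_data
    return fit_first_order(design, responses)


@pytest.fixture(scope="session")
def ascent_data():
    return datasets.ascent_path()


@pytest.fixture(scope="session")
def bbd_data():
    return datasets.bbd_experiment()


@pytest.fixture(scope="session")
def bbd_fit(bbd_data):
    design, responses = bbd_data
    return fit_quadratic(design, responses)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
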