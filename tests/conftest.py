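import numpy as np
import pytest

import prenetfa as pf


@pytest.fixture(scope="session")
def model_a_ort():
    return pf.make_model("A-ORT")


@pytest.fixture(scope="session")
def sample_a_ort_500(model_a_ort):
    """One n=500 draw from Model A-ORT, shared across tests."""
    X, S = pf.sample_data(model_a_ort, 500, seed=42)
    return X, S


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def p2m1_model():
    """Tiny hand-checkable one-factor model: Lambda=(0.8,0.6), Psi=(0.36,0.64)."""
    return pf.FactorModel(
        np.array([[0.8], [0.6]]), np.eye(1), np.array([0.36, 0.64])
    )
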