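import numpy as np
import pandas as pd
import pytest

from epilag import synthdata as sd
from epilag.dlnm import cross_basis, lag_basis
from epilag.preprocess import encode_covariates


@pytest.fixture(scope="session")
def cohort189():
    return sd.generate_cohort(189, seed=42)


@pytest.fixture(scope="session")
def exposure189(cohort189):
    return sd.generate_exposure(cohort189, seed=43)


@pytest.fixture(scope="session")
def design189(cohort189):
    return encode_covariates(cohort189)


@pytest.fixture(scope="session")
def basis5():
    return lag_basis()


@pytest.fixture(scope="session")
def model_data(cohort189, exposure189, design189, basis5):
    """Model-ready frame: covariates + cross-basis + batch labels, no response."""
    cb = cross_basis(exposure189, basis5)
    return pd.concat(
        [design189.matrix, cb.to_frame(index=cohort189.index),
         cohort189[["plate", "sentrix_row", "sentrix_col"]]],
        axis=1,
    ), cb


def simulate_lmm_response(X, codes, beta, tau2, sigma2, seed):
    """Gaussian mixed-model response for matrix-level tests."""
    rng = np.random.default_rng(seed)
    y = X.to_numpy() @ np.asarray(beta, float)
    for name, c in codes.items():
        q = int(np.max(c)) + 1
        b = rng.normal(0.0, np.sqrt(tau2[name]), q)
        y = y + b[c]
    return y + rng.normal(0.0, np.sqrt(sigma2), len(y))
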