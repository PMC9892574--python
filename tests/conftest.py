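import warnings

import numpy as np
import pytest

from rebicop.model import FitOptions, fit
from rebicop.synthdata import generate, model_spec_for, simple_config


@pytest.fixture(scope="session")
def gaussian_dataset():
    """One synthetic dataset from the Gaussian-copula model (simple design)."""
    cfg = simple_config(n=4000, seed=7, family="N", tau=-0.3, gamma=1.0)
    return cfg, generate(cfg)


@pytest.fixture(scope="session")
def gaussian_fit(gaussian_dataset):
    """A converged fit of the matching specification on that dataset."""
    cfg, ds = gaussian_dataset
    spec = model_spec_for(cfg, num_basis=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fitted = fit(spec, ds.data)
    assert fitted.converged
    return fitted


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
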