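import numpy as np
import pytest

import doughrheo as dr


@pytest.fixture(scope="session")
def clean_params() -> dr.ConstitutiveParams:
    """Noise-free constitutive parameters for exactness checks."""
    return dr.ConstitutiveParams(C=8000.0, m=0.25, shi_true=2.0, noise_cv=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_speed_set(clean_params):
    """Noise-free traces at the five protocol platen speeds."""
    return dr.simulate_speed_set(clean_params)


@pytest.fixture(scope="session")
def clean_processed(clean_speed_set):
    return [dr.process_trace(t) for t in clean_speed_set]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
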