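import numpy as np
import pytest

from odormetric import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(
        n_molecules=12,
        latent_dim=3,
        feature_dim=8,
        n_subjects=5,
        subject_noise_sd=5.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_spec):
    return generate(small_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
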