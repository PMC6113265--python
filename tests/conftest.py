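import numpy as np
import pytest

from modscape import (
    CAParams,
    SyntheticConfig,
    generate_driving_factors,
    generate_landscape,
    train_suitability,
)


@pytest.fixture(scope="session")
def bundle100():
    """One 100x100 synthetic landscape shared across tests (read-only)."""
    return generate_landscape(SyntheticConfig(shape=(100, 100), seed=11))


@pytest.fixture(scope="session")
def factors100(bundle100):
    return generate_driving_factors(bundle100, n_factors=16, seed=11)


@pytest.fixture(scope="session")
def surface100(bundle100, factors100):
    return train_suitability(factors100, bundle100.landuse_t0,
                             sample_fraction=0.10, seed=11, min_class_samples=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
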