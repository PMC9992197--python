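import numpy as np
import pytest
from hypothesis import settings

import corespec as cs
from corespec.pipeline import build_geometry

settings.register_profile(
    "suite", deadline=None, max_examples=50, derandomize=True
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def smoke_design():
    """Tiny cohort design shared across end-to-end tests."""
    return cs.CohortDesign.smoke(master_seed=7)


@pytest.fixture(scope="session")
def geometry(smoke_design):
    """Sensor array, source space, and lead field at smoke scale."""
    return build_geometry(smoke_design)


@pytest.fixture(scope="session")
def noise_cov(geometry):
    from corespec.preprocess import NoiseCovariance

    n = geometry.array.n
    return NoiseCovariance(matrix=np.eye(n) * (2e-13) ** 2, shrinkage=0.0)
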