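import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ihnet.network import prepare_matrices
from ihnet.simulate import SimConfig, generate_bundle

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_CFG = SimConfig(
    n_genes=120, n_mirnas=20, n_samples=80,
    n_seed_expression=8, n_seed_cnv=2, n_seed_methylation=2,
    n_seed_mirnas=2, n_regulated_genes=15, rng_seed=11,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A quick planted-signal bundle for pipeline-level tests."""
    return generate_bundle(SMALL_CFG)


@pytest.fixture(scope="session")
def small_prepared(small_bundle):
    return prepare_matrices(small_bundle.matrices)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
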