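import numpy as np
import pytest

from mmclrr import SyntheticSpec, default_fixture, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_dataset():
    """The built-in imbalanced two-class dataset (48 samples, 3 views)."""
    return default_fixture()


@pytest.fixture(scope="session")
def three_cluster_data():
    """Balanced 3-cluster, 3-view data with low noise (seed 0)."""
    spec = SyntheticSpec(
        n_clusters=3,
        samples_per_cluster=(20, 20, 20),
        view_dims=(50, 60, 40),
        subspace_dim=4,
        noise_sigma=0.01,
        seed=0,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def noiseless_data():
    """Noise-free 3-cluster data for exact-structure checks."""
    spec = SyntheticSpec(
        n_clusters=3,
        samples_per_cluster=(20, 20, 20),
        view_dims=(50, 60, 40),
        subspace_dim=4,
        noise_sigma=0.0,
        seed=0,
    )
    return generate(spec)
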