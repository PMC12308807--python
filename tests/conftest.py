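import numpy as np
import pytest

from ptsne import ParametricTSNE, make_gaussian_mixture


@pytest.fixture(scope="session")
def cluster_data():
    """Three well-separated 10-D Gaussian clusters with ground-truth labels."""
    X, y = make_gaussian_mixture(3, 10, 100, separation=8.0, random_state=3)
    return X, y


@pytest.fixture(scope="session")
def trained_embedder(cluster_data):
    """One trained model shared by the estimator-behavior tests."""
    X, _ = cluster_data
    est = ParametricTSNE(random_state=3, max_epochs=250)
    est.fit(X)
    return est


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
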