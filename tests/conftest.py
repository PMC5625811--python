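import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_clusters(n_per_class, centers, noise_sd, seed):
    """Well-separated Gaussian blobs; returns (X, labels as center indices)."""
    g = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    X, y = [], []
    for k, c in enumerate(centers):
        X.append(c + noise_sd * g.standard_normal((n_per_class, centers.shape[1])))
        y.extend([k] * n_per_class)
    return np.vstack(X), np.asarray(y)


@pytest.fixture(scope="session")
def state_clusters():
    """Four separable clusters in 8-dim band-power space (mean gap 10x SD)."""
    centers = np.zeros((4, 8))
    for k in range(4):
        centers[k, 2 * k] = 10.0
    X, y = make_clusters(40, centers, noise_sd=1.0, seed=7)
    return X, y, centers
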