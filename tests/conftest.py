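import numpy as np
import pytest

from lmdist import CoenoclineParams, bray_curtis, simulate_gradient_community


def random_semimetric(rng, n, low=0.05, high=1.0):
    """Random symmetric hollow matrix; no triangle inequality implied."""
    M = rng.uniform(low, high, size=(n, n))
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 0.0)
    return M


def euclidean_cloud_distances(rng, n, dim=3, scale=1.0):
    from scipy.spatial.distance import pdist, squareform

    pts = rng.normal(size=(n, dim)) * scale
    return squareform(pdist(pts)), pts


@pytest.fixture(scope="session")
def gradient_community():
    """Default coenocline community: 50 base + 50 Dirichlet noise samples."""
    return simulate_gradient_community(CoenoclineParams(seed=0))


@pytest.fixture(scope="session")
def gradient_bc(gradient_community):
    """Bray-Curtis matrix of the default simulated gradient community."""
    return bray_curtis(gradient_community.table)
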