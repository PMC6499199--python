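import numpy as np
import pytest

from tlstrack.io import PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_cloud(rng):
    """500 points in a 1 m cube with integer-valued intensities."""
    coords = rng.uniform(0, 1, (500, 3))
    intensity = rng.integers(0, 2000, 500).astype(float)
    return PointCloud(coords, intensity)


def two_blob_cloud(rng, n_per_blob=200, separation=1.0, blob_radius=0.05):
    """Two well-separated Gaussian-ish blobs; blob diameter << separation."""
    a = rng.uniform(-blob_radius, blob_radius, (n_per_blob, 3))
    b = rng.uniform(-blob_radius, blob_radius, (n_per_blob, 3)) + [separation, 0, 0]
    return PointCloud(np.vstack([a, b]))
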