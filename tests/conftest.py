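import numpy as np
import pytest

from anricp import FixtureSpec, NoiseModel, PointCloud, build_grid_topology


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_spec():
    """8×8 version of the flat-pair geometry for fast registration tests."""
    return FixtureSpec(kind="flat_pair", rows=8, cols=8, noise_enabled=False)


@pytest.fixture
def random_cloud_pair(rng):
    def make(n=40, spread=50.0, offset=(0.0, 0.0, 0.0)):
        base = np.array([0.0, 0.0, 1100.0])
        src = base + rng.uniform(-spread, spread, size=(n, 3))
        tgt = base + np.asarray(offset) + rng.uniform(-spread, spread, size=(n, 3))
        return PointCloud(src), PointCloud(tgt)

    return make


@pytest.fixture
def grid_cloud():
    """5×4 planar-ish grid cloud with a mild bump (full-rank point matrix)."""
    xs, ys = np.meshgrid(np.linspace(-20, 20, 4), np.linspace(-20, 20, 5))
    z = 1100.0 + 3.0 * np.exp(-(xs**2 + ys**2) / 400.0)
    pts = np.stack([xs.ravel(), ys.ravel(), z.ravel()], axis=1)
    return PointCloud(pts, grid_shape=(5, 4))


@pytest.fixture
def grid_topology(grid_cloud):
    return build_grid_topology(*grid_cloud.grid_shape, 4)


@pytest.fixture
def default_noise():
    return NoiseModel()
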