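import numpy as np
import pytest

from hubcausal.grids import BinaryMask, BoldSeries, VolumeGrid


@pytest.fixture
def grid3():
    """Small 3 mm grid with the default template origin."""
    return VolumeGrid.from_spacing((8, 8, 8), origin_mm=(0.0, 0.0, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def full_mask(grid3):
    return BinaryMask(grid3, np.ones(grid3.dims, dtype=bool))


def make_bold(grid, T=60, rng=None, seed=0):
    rng = rng or np.random.default_rng(seed)
    return BoldSeries(grid, rng.standard_normal((*grid.dims, T)), tr_seconds=2.0)


@pytest.fixture
def noise_bold(grid3, rng):
    return make_bold(grid3, T=60, rng=rng)


@pytest.fixture
def worked_degree_case():
    """Four voxels with hand-computable pairwise correlations.

    v1 = v2 = [1..5], v3 = reversed, v4 = [1,3,2,5,4]:
    r(v1,v2)=1, r(v1,v4)=r(v2,v4)=0.8, all correlations with v3 negative.
    """
    grid = VolumeGrid.from_spacing((4, 1, 1), origin_mm=(0, 0, 0))
    v1 = [1, 2, 3, 4, 5]
    series = np.array([v1, v1, v1[::-1], [1, 3, 2, 5, 4]], dtype=float)
    bold = BoldSeries(grid, series.reshape(4, 1, 1, 5), tr_seconds=2.0)
    mask = BinaryMask(grid, np.ones((4, 1, 1), dtype=bool))
    return bold, mask
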