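import numpy as np
import pytest

from antrisk.gridding import GridSpec
from antrisk.landscape import generate_landscape


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic landscape shared by geometry-heavy tests."""
    return generate_landscape(
        seed=42, extent=(0.0, 0.0, 2000.0, 2000.0), n_patches=120,
        change_fraction=0.107, road_spacing=500.0,
    )


@pytest.fixture(scope="session")
def small_grid(small_bundle):
    return GridSpec.from_extent(*small_bundle.extent, cell_size=200.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
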