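import numpy as np
import pytest

from neurotopo import synthetic
from neurotopo.pipeline import _base_grid


@pytest.fixture(scope="session")
def base_grid():
    """Smooth 15x4 occupancy truth with empty DV edge rows."""
    return _base_grid(15, 4)


@pytest.fixture(scope="session")
def uniform_grid():
    return np.full((15, 4), 1.0 / 60.0)


@pytest.fixture()
def small_cell_table(base_grid):
    truth = synthetic.SyntheticTruth(
        base_grid, n_larvae=4, cells_per_larva=(12, 20), seed=42
    )
    return synthetic.gen_occupancy_dataset(truth)


@pytest.fixture(scope="session")
def unit_tetrahedron():
    """Regular tetrahedron with unit edge length."""
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.5, np.sqrt(3) / 2, 0.0],
            [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)],
        ]
    )
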