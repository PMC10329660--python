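import numpy as np
import pandas as pd
import pytest

from geovax import PixelGrid
from geovax.synthetic_world import partition_admin, simulate_population


@pytest.fixture
def grid_4x4() -> PixelGrid:
    return PixelGrid(4, 4, 1.0)


@pytest.fixture
def borno_like():
    """27-LGA single-state world on a 27x27 grid with an urban-skewed
    population, mirroring the study region's shape."""
    grid = PixelGrid(27, 27, 5.0)
    admin = partition_admin(grid, n_states=1, lgas_per_state=27)
    population = simulate_population(grid, urban_centers=3, total_pop=500_000, seed=11)
    return grid, admin, population


@pytest.fixture
def toy_obs():
    """Five-observation single-year table with three stacker children."""
    obs = pd.DataFrame(
        {
            "observation_id": range(5),
            "pixel_id": [0, 3, 7, 9, 15],
            "year": [2000] * 5,
            "trials": [10, 12, 8, 20, 15],
            "successes": [3, 5, 7, 2, 9],
            "group_id": ["a", "a", "b", "b", "b"],
        }
    )
    stackers = pd.DataFrame(
        {
            "observation_id": range(5),
            "c1": [0.2, 0.4, 0.6, 0.3, 0.8],
            "c2": [0.5, 0.45, 0.55, 0.5, 0.6],
            "c3": [0.1, 0.2, 0.3, 0.4, 0.5],
        }
    )
    return obs, stackers
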