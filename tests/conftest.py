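import numpy as np
import pandas as pd
import pytest

from vascmrf import GridSpec
from vascmrf.dictionary import (build_dictionary, default_dictionary_grid,
                                geometries_from_conditions,
                                make_family_dictionary,
                                sample_vascular_conditions)


@pytest.fixture(scope="session")
def grid3d_small():
    """Tiny 3D grid for fast unit tests (62 x 62 x 93 µm box)."""
    return GridSpec((16, 16, 24), (3.875, 3.875, 3.875))


@pytest.fixture(scope="session")
def grid2d():
    return GridSpec((64, 64, 1), (3.875, 3.875, 3.875))


@pytest.fixture(scope="session")
def dict_small():
    """Small cylinder-family dictionary shared by reconstruction unit tests."""
    return make_family_dictionary("cylinder3d", 120, seed=11,
                                  grid=GridSpec((24, 24, 36),
                                                (3.875, 3.875, 3.875)))


# ----- full-scale fixtures shared by the acceptance checks ------------------


@pytest.fixture(scope="session")
def dict_full():
    """Desk-scale 2,000-entry 3D-cylinder dictionary."""
    return make_family_dictionary("cylinder3d", 2000, seed=101)


@pytest.fixture(scope="session")
def dbl_full(dict_full):
    from vascmrf.reconstruct import dbl_train

    return dbl_train(dict_full, n_components=50, seed=7)


@pytest.fixture(scope="session")
def heldout_offgrid(dict_full):
    """Off-grid noiseless test set: new geometries, uniform-random SO2/T2."""
    n = 150
    grid = default_dictionary_grid("cylinder3d")
    conds = sample_vascular_conditions(n, seed=2023)
    geoms = geometries_from_conditions("cylinder3d", grid, conds, seed=2024)
    rng = np.random.default_rng(2025)
    samples = pd.DataFrame({"so2": rng.uniform(40.0, 85.0, n),
                            "t2": rng.uniform(50.0, 105.0, n)})
    return build_dictionary(geoms, samples)
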