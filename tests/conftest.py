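"""Shared fixtures: tiny synthetic worlds small enough for exhaustive oracles."""

import numpy as np
import pytest

from ticnet.grid import make_grid
from ticnet.synthetic import SyntheticConfig, default_ground_truth, make_connectome


@pytest.fixture(scope="session")
def grid8():
    """8x8x8 isotropic 2 mm grid, world origin at the centre."""
    return make_grid((8, 8, 8), voxel_mm=2.0)


@pytest.fixture(scope="session")
def tiny_cfg():
    return SyntheticConfig.small(dims=(10, 10, 10), n_subjects=8, T=50,
                                 n_case_lesions=4)


@pytest.fixture(scope="session")
def tiny_truth(tiny_cfg):
    return default_ground_truth(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_conn(tiny_cfg, tiny_truth):
    return make_connectome(tiny_cfg, tiny_truth, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
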