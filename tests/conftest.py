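import numpy as np
import pytest

from sdmrisk import preprocess, synthetic
from sdmrisk.grid import GridSpec


@pytest.fixture
def grid():
    return GridSpec(30, 30)


@pytest.fixture
def masked_grid():
    mask = np.zeros((30, 30), dtype=bool)
    mask[:5, :5] = True  # a "sea" corner
    return GridSpec(30, 30, nodata_mask=mask)


@pytest.fixture
def climate(grid):
    return synthetic.generate_climate(grid, seed=11)


@pytest.fixture
def bioclim(climate):
    return preprocess.derive_bioclim(climate)


@pytest.fixture
def elevation(grid):
    return synthetic.generate_elevation(grid, seed=12)


@pytest.fixture
def truth(bioclim):
    return synthetic.true_suitability(
        bioclim, synthetic.TruthParams(intercept=-1.0, linear={"gdd": 3.0})
    )


@pytest.fixture
def records(truth, grid, elevation):
    return synthetic.sample_occurrences(
        truth, grid, elevation, n=300, seed=13,
        error_rates={"offgrid": 0.05, "elev_mismatch": 0.05, "duplicate": 0.1},
    )
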