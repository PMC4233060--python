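import numpy as np
import pytest

from gridepi.laea_grid import CountGrid, GridSpec


@pytest.fixture
def small_spec() -> GridSpec:
    return GridSpec(col_range=(0, 19), row_range=(0, 19), resolution_m=1000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def random_grid(small_spec, rng) -> CountGrid:
    counts = rng.integers(0, 5, size=(small_spec.n_rows, small_spec.n_cols))
    return CountGrid(spec=small_spec, counts=counts.astype(np.int64), label="cases")
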