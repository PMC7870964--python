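import numpy as np
import pytest

from emberfire.grid import GridSpec, MonthlyField, month_range


@pytest.fixture
def small_grid():
    return GridSpec.regular(4, 6, resolution=1.0)


@pytest.fixture
def field_factory():
    """Build a MonthlyField from an array, filling in a contiguous axis."""

    def make(values, grid=None, start=(2002, 1), name="ba"):
        values = np.asarray(values, dtype=float)
        nt = values.shape[0]
        if grid is None:
            grid = GridSpec.regular(values.shape[1], values.shape[2])
        years, months = month_range(start[0], start[1], nt)
        return MonthlyField(grid, values, years, months, name)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(42)
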