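import numpy as np
import pytest

from sdmshift.grid_io import Grid, GridStack, harmonize_stack
from sdmshift.synthetic_scenarios import LandscapeSpec, make_landscape, sample_presences

NODATA = -9999.0


def make_grid(values, xll=100.0, yll=30.0, cellsize=0.5, nodata=NODATA):
    values = np.asarray(values, dtype=float)
    return Grid(values.shape[1], values.shape[0], xll, yll, cellsize, nodata, values)


@pytest.fixture
def grid_2x2():
    return make_grid([[1.0, 2.0], [3.0, NODATA]])


@pytest.fixture
def stack_3layers():
    a = make_grid([[1.0, 2.0], [3.0, 4.0]])
    b = make_grid([[10.0, 20.0], [30.0, 40.0]])
    c = make_grid([[0.0, 1.0], [0.0, 1.0]])
    return harmonize_stack({"a": a, "b": b, "c": c}, categorical={"c"})


@pytest.fixture(scope="session")
def small_landscape():
    """Compact landscape used by several fitting tests (session-scoped:
    the generator is deterministic, nothing mutates it)."""
    spec = LandscapeSpec(nrows=70, ncols=70, nodata_fraction=0.02)
    land = make_landscape(spec, seed=11)
    occ = sample_presences(land.truth, 90, seed=12)
    return land, occ


@pytest.fixture(scope="session")
def default_landscape():
    """The generator's stated default world (200x200)."""
    land = make_landscape(LandscapeSpec(), seed=5)
    occ = sample_presences(land.truth, 100, seed=6)
    return land, occ
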