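import numpy as np
import pytest

from elementscape.io_formats import ElementProfileSet, RangeMask, RasterGrid, SoilGridSet
from elementscape.synthetic_landscape import (
    generate_soil_grids,
    sample_fur_profiles,
    strong_signal_config,
)


@pytest.fixture(scope="session")
def small_landscape():
    """A compact strong-signal landscape shared by pipeline-level tests."""
    cfg = strong_signal_config(seed=7, n_individuals=40,
                               extent=(-100.0, 30.0, -88.0, 38.0))
    soil = generate_soil_grids(cfg)
    profiles, truth = sample_fur_profiles(soil, cfg)
    return cfg, soil, profiles, truth


@pytest.fixture(scope="session")
def small_profiles(small_landscape):
    return small_landscape[2]


@pytest.fixture(scope="session")
def small_soil(small_landscape):
    return small_landscape[1]


@pytest.fixture(scope="session")
def full_range(small_soil):
    return RangeMask.full(small_soil.template)


@pytest.fixture
def unit_grid():
    """A 4x4 grid over [0,4]x[0,4] degrees with cell size 1."""
    return RasterGrid.blank(0.0, 4.0, 1.0, 4, 4, fill=0.0)


def make_profiles(lons, lats, conc, elements=None):
    conc = np.asarray(conc, dtype=float)
    elements = elements or [f"E{j}" for j in range(conc.shape[1])]
    ids = [f"s{i}" for i in range(len(lons))]
    return ElementProfileSet(ids, np.asarray(lons, float), np.asarray(lats, float),
                             list(elements), conc)


@pytest.fixture
def profile_factory():
    return make_profiles
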