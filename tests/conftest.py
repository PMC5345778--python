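import numpy as np
import pytest

from mpabioecon.domain import GridDomain, build_synthetic_domain
from mpabioecon.params import (DispersalParams, EconParams, FisheryParams,
                               LifeHistoryParams, MortalityParams)


@pytest.fixture(scope="session")
def lh():
    return LifeHistoryParams()


@pytest.fixture(scope="session")
def mort():
    return MortalityParams()


@pytest.fixture(scope="session")
def dp():
    return DispersalParams()


@pytest.fixture(scope="session")
def fishp():
    return FisheryParams()


@pytest.fixture(scope="session")
def econ():
    return EconParams(baseline_distance=100.0)


@pytest.fixture(scope="session")
def small_domain():
    """5x5 grid with a one-cell land margin; fixed seed."""
    return build_synthetic_domain(5, 5, 400.0, coast_profile={"base_width": 1, "roughness": 0},
                                  seed=11)


@pytest.fixture(scope="session")
def open_domain():
    """Large mostly-water grid for placement tests."""
    return build_synthetic_domain(30, 30, 400.0, seed=2)


def make_chain_domain(n: int, cell_area: float = 400.0) -> GridDomain:
    """1-D chain of n water EEZ cells with a single land cell appended west."""
    spacing = float(np.sqrt(cell_area))
    n_tot = n + 1
    x = np.arange(n_tot) * spacing
    y = np.zeros(n_tot)
    is_land = np.zeros(n_tot, dtype=bool)
    is_land[0] = True
    dist = x.copy()
    return GridDomain(
        n_x=n_tot, n_y=1, cell_area=cell_area, x=x, y=y,
        is_land=is_land, in_eez=~is_land,
        suitability=np.where(is_land, 0.0, 0.8),
        is_breeding=np.zeros(n_tot, dtype=bool),
        dist_to_shore=dist,
        K=np.where(is_land, 0.0, 0.43),
    )


@pytest.fixture
def chain_domain():
    return make_chain_domain(5)
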