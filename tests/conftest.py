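"""Shared fixtures: synthetic schedule bundles and cached stationary solves."""

import numpy as np
import pytest

import birthdelay as bd
from birthdelay.grids import AgeGrid
from birthdelay.rates import RateSchedule


@pytest.fixture(scope="session")
def preset():
    """Deterministic China-like synthetic bundle on the default grid."""
    return bd.china_like_preset()


@pytest.fixture(scope="session")
def beta0(preset):
    """First-birth rate consistent with the preset's observed birth rate."""
    return bd.reconstruct_beta0(preset.beta_eff, preset.natural_delta)


@pytest.fixture(scope="session")
def long_grid():
    """Long, fine grid for closed-form comparisons with negligible truncation."""
    return AgeGrid(2000.0, 0.1)


@pytest.fixture()
def constant_schedule():
    def make(grid: AgeGrid, value: float) -> RateSchedule:
        return RateSchedule(grid, np.full(grid.n, value))

    return make


@pytest.fixture(scope="session")
def stationary_cache(preset, beta0):
    """Memoized stationary states per delta on the preset schedules."""
    cache: dict[float, bd.StationaryState] = {}

    def get(delta: float, eta: float = 0.48) -> bd.StationaryState:
        key = (delta, eta)
        if key not in cache:
            pol = bd.PolicyConfig(delta=delta, eta=eta)
            cache[key] = bd.stationary_state(beta0, pol, preset.mu_f)
        return cache[key]

    return get
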