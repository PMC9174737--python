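"""Deterministic parametric generators for rate schedules and pyramids.

These stand in for census-derived inputs: a unimodal fertility bump
supported on the fertile window, a Gompertz–Makeham mortality curve with
an optional infant-mortality term, and an exponentially young-heavy age
pyramid.  Generation is fully deterministic — identical parameters give
bitwise-identical schedules — so every downstream computation is exactly
reproducible.  A seeded multiplicative-noise decorator is available for
robustness experiments only.

The ``china_like_preset`` bundle is a synthetic calibration loosely
evoking early-1980s China (total fertility ~2.6, newborn female fraction
eta = 0.48, female mortality advantage at old ages, young-heavy pyramid).
It is not census data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import AgeGrid
from .rates import RateSchedule

__all__ = [
    "FertilityParams",
    "MortalityParams",
    "ChinaLikePreset",
    "make_birth_rate",
    "make_mortality",
    "make_pyramid",
    "china_like_preset",
    "with_noise",
]

_INFANT_DECAY_YEARS = 2.0  # e-folding age of the infant-mortality term


@dataclass(frozen=True)
class FertilityParams:
    """Shape of the observed birth-rate bump.

    total_fertility is the area under beta_eff (mean births per woman);
    mode_age the peak age; spread the Gaussian width; window the fertile
    ages (a_min, a_max) outside which the rate is zero.
    """

    total_fertility: float = 2.6
    mode_age: float = 25.0
    spread: float = 5.5
    window: tuple[float, float] = (12.0, 50.0)

    def __post_init__(self) -> None:
        if self.total_fertility <= 0:
            raise ValueError("total_fertility must be positive")
        a_min, a_max = self.window
        if not a_min < self.mode_age < a_max:
            raise ValueError("mode_age must lie inside the fertile window")


@dataclass(frozen=True)
class MortalityParams:
    """Gompertz–Makeham hazard with an optional infant bump.

    mu(a) = makeham + gompertz_scale * exp(gompertz_rate * a)
            + infant_bump * exp(-a / 2).
    """

    makeham: float = 0.0015
    gompertz_scale: float = 4e-5
    gompertz_rate: float = 0.094
    infant_bump: float = 0.04

    def __post_init__(self) -> None:
        for name in ("makeham", "gompertz_scale", "gompertz_rate", "infant_bump"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_birth_rate(params: FertilityParams, grid: AgeGrid) -> RateSchedule:
    """Unimodal fertility bump on the window, rescaled to total_fertility.

    A Gaussian centred on mode_age is shifted down by its larger window-edge
    value and clipped at zero, which keeps the curve continuous at the edge
    it touches; the trapezoid integral is rescaled exactly.
    """
    a_min, a_max = params.window
    if a_max > grid.a_max_grid:
        raise ValueError("fertile window extends beyond the grid")
    a = grid.nodes
    z = (a - params.mode_age) / params.spread
    raw = np.exp(-0.5 * z * z)
    edge = max(
        float(np.exp(-0.5 * ((a_min - params.mode_age) / params.spread) ** 2)),
        float(np.exp(-0.5 * ((a_max - params.mode_age) / params.spread) ** 2)),
    )
    bump = np.clip(raw - edge, 0.0, None)
    bump[(a < a_min) | (a > a_max)] = 0.0
    area = grid.trapz(bump)
    if area <= 0:
        raise ValueError("infeasible fertility window: bump has zero mass")
    return RateSchedule(grid, bump * (params.total_fertility / area))


def make_mortality(params: MortalityParams, grid: AgeGrid) -> RateSchedule:
    a = grid.nodes
    mu = (
        params.makeham
        + params.gompertz_scale * np.exp(params.gompertz_rate * a)
        + params.infant_bump * np.exp(-a / _INFANT_DECAY_YEARS)
    )
    return RateSchedule(grid, mu)


def make_pyramid(
    g: float, n_total: float, grid: AgeGrid, mu: RateSchedule
) -> RateSchedule:
    """Age pyramid with counts ∝ exp(-g a - int_0^a mu), trapezoid-normalized.

    g > 0 gives a young-heavy pyramid (the shape a population growing at
    rate g with mortality mu would have); g = 0, mu = 0 is uniform.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    shape = np.exp(-g * grid.nodes - mu.cumulative())
    return RateSchedule(grid, shape * (n_total / grid.trapz(shape)))


@dataclass(frozen=True)
class ChinaLikePreset:
    """Synthetic schedule bundle loosely evoking 1981 China (not census data)."""

    beta_eff: RateSchedule
    mu_f: RateSchedule
    mu_m: RateSchedule
    pyramid: RateSchedule
    eta: float
    natural_delta: float = 2.0

    @property
    def grid(self) -> AgeGrid:
        return self.beta_eff.grid


def china_like_preset(grid: AgeGrid | None = None) -> ChinaLikePreset:
    """Deterministic synthetic bundle: beta_eff, mu_f, mu_m, pyramid, eta = 0.48.

    Total fertility ~2.6 on window (12, 50) peaking at 25; female and male
    Gompertz–Makeham mortality with a male excess at all ages; young-heavy
    pyramid (490 million females).  The observed beta_eff is generated
    directly; the natural interbirth refractory period assumed behind it
    is 2 years (`natural_delta`).
    """
    grid = grid or AgeGrid()
    fertility = FertilityParams(
        total_fertility=2.6, mode_age=25.0, spread=5.5, window=(12.0, 50.0)
    )
    mort_f = MortalityParams(
        makeham=0.0015, gompertz_scale=4e-5, gompertz_rate=0.094, infant_bump=0.04
    )
    mort_m = MortalityParams(
        makeham=0.0022, gompertz_scale=7e-5, gompertz_rate=0.092, infant_bump=0.05
    )
    beta_eff = make_birth_rate(fertility, grid)
    mu_f = make_mortality(mort_f, grid)
    mu_m = make_mortality(mort_m, grid)
    pyramid = make_pyramid(0.025, 4.9e8, grid, mu_f)
    return ChinaLikePreset(beta_eff, mu_f, mu_m, pyramid, eta=0.48)


def with_noise(schedule: RateSchedule, sigma: float, seed: int) -> RateSchedule:
    """Multiplicative log-normal noise (robustness experiments only)."""
    rng = np.random.default_rng(seed)
    factors = np.exp(rng.normal(0.0, sigma, size=schedule.values.shape))
    return schedule.with_values(schedule.values * factors)
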