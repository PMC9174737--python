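"""Rate-schedule algebra for the delayed-birth model.

Two birth-rate functions describe the same population.  The *observed*
(effective) birth rate ``beta_eff(a)`` is the per-capita birth rate of all
age-``a`` females — the quantity a birth registry measures.  The
*first-birth* rate ``beta0(a)`` is the birth hazard of childless females.
Under a refractory period ``delta`` (no births while the youngest child is
younger than ``delta``) the two are linked, in the stationary population, by

    beta0(a) = beta_eff(a) / (1 - int_{a-delta}^{a} beta_eff(s) ds),

with ``beta_eff`` taken as zero at negative ages.  This module implements
that map in both directions, the truncation of the mother birth surface
``beta(a, tau) = beta0(a) * 1{tau > delta}``, fertile-window clamping, and
a behavioural-response adjustment (catch-up births just after the
refractory period and earlier first births).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .grids import AgeGrid, require_same_grid

__all__ = [
    "RateSchedule",
    "BirthSurface",
    "PolicyConfig",
    "BehaviouralMultipliers",
    "reconstruct_beta0",
    "forward_beta_eff",
    "truncate_by_refractory",
    "clamp_fertile_window",
    "behavioural_multipliers",
    "apply_behavioural_response",
]


@dataclass(frozen=True)
class RateSchedule:
    """A nonnegative rate (per year) tabulated on a uniform age grid.

    Values are piecewise linear between nodes and zero beyond the grid.
    """

    grid: AgeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.grid.n,):
            raise ValueError(
                f"schedule length {vals.shape} does not match grid ({self.grid.n},)"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("rate schedule contains non-finite values")
        if np.any(vals < 0):
            a_bad = self.grid.nodes[np.argmin(vals)]
            raise ValueError(f"negative rate at age {a_bad:g}")

    def with_values(self, values: np.ndarray) -> "RateSchedule":
        return RateSchedule(self.grid, values)

    def integral(self) -> float:
        """Trapezoid integral over the whole grid (e.g. total fertility)."""
        return self.grid.trapz(self.values)

    def cumulative(self) -> np.ndarray:
        return self.grid.cumtrapz(self.values)

    def __call__(self, age) -> np.ndarray:
        """Piecewise-linear evaluation; zero outside the grid."""
        return np.interp(age, self.grid.nodes, self.values, left=0.0, right=0.0)


@dataclass(frozen=True)
class BirthSurface:
    """Mother birth rate beta(a, tau) on the triangle tau <= a.

    ``values[ia, itau]`` holds the rate at (age, tau) nodes; it is zero for
    tau > a and wherever the policy forbids births.  Because the refractory
    cut makes beta discontinuous in tau at grid nodes, ``quad_values``
    stores the limit *from above* at each tau node (equal to ``values``
    away from jumps).  Quadrature in tau uses the pair: a segment
    [tau_j, tau_{j+1}] contributes  step/2 * (quad[.., j] + values[.., j+1]),
    which keeps trapezoid accuracy across the jump.
    """

    grid: AgeGrid
    values: np.ndarray
    quad_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = self.grid.n
        if vals.shape != (n, n):
            raise ValueError(f"surface shape {vals.shape} does not match grid ({n},{n})")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("birth surface must be finite and nonnegative")
        tri = np.tril(np.ones((n, n), dtype=bool))  # tau <= a
        if np.any(vals[~tri] != 0.0):
            raise ValueError("birth surface must vanish for tau > a")
        if self.quad_values is None:
            object.__setattr__(self, "quad_values", vals)
        else:
            q = np.asarray(self.quad_values, dtype=float)
            if q.shape != (n, n):
                raise ValueError("quad_values shape mismatch")
            object.__setattr__(self, "quad_values", q)

    def tau_flux(self, density: np.ndarray) -> np.ndarray:
        """Row-wise integral over tau of beta(a, tau) * density(a, tau).

        Returns one value per age node: int_0^a beta(a,tau) d(a,tau) dtau,
        using the jump-aware segment rule described in the class docstring.
        """
        step = self.grid.step
        n = self.grid.n
        # node j is a left endpoint of segment [j, j+1] only strictly inside
        # the triangle (j < a-row); it is a right endpoint for 1 <= j <= row
        left = self.quad_values * density * np.tril(np.ones((n, n)), k=-1)
        right = self.values * density
        return 0.5 * step * (left[:, :-1] + right[:, 1:]).sum(axis=1)


@dataclass(frozen=True)
class PolicyConfig:
    """Policy levers: refractory period, fertile window, sex ratio, response.

    delta is the *total* refractory period in years (math.inf = strict
    one-child limit); a no-policy baseline uses the natural delta = 2.
    """

    delta: float = 2.0
    a_min: float = 12.0
    a_max: float = 50.0
    eta: float = 0.48
    behavioural: bool = False

    def __post_init__(self) -> None:
        if self.delta < 0 or math.isnan(self.delta):
            raise ValueError(f"delta must be >= 0 (or inf), got {self.delta}")
        if not 0.0 <= self.a_min < self.a_max:
            raise ValueError(f"need 0 <= a_min < a_max, got ({self.a_min}, {self.a_max})")
        if not 0.0 < self.eta < 1.0:
            raise ValueError(f"eta must be in (0, 1), got {self.eta}")

    def snapped(self, grid: AgeGrid) -> "PolicyConfig":
        """Snap delta, a_min, a_max to grid nodes (keeps the tau-cut exact)."""
        delta = self.delta if math.isinf(self.delta) else grid.snap(self.delta)
        return replace(self, delta=delta, a_min=grid.snap(self.a_min), a_max=grid.snap(self.a_max))


@dataclass(frozen=True)
class BehaviouralMultipliers:
    """Catch-up (c1) and early-first-birth (c2) birth-rate multipliers."""

    c1: float
    c2: float
    age_cutoff: float = 40.0

    def __post_init__(self) -> None:
        if self.c1 < 1.0 or self.c2 < 1.0:
            raise ValueError("behavioural multipliers must be >= 1")


def _delta_index(grid: AgeGrid, delta: float) -> int:
    if delta < 0 or math.isnan(delta):
        raise ValueError(f"delta must be >= 0, got {delta}")
    return grid.index_of(delta)


def reconstruct_beta0(beta_eff: RateSchedule, delta: float) -> RateSchedule:
    """First-birth rate beta0 from the observed rate beta_eff under delay delta.

    beta0(a) = beta_eff(a) / (1 - int_{max(0, a-delta)}^{a} beta_eff(s) ds).

    Raises ValueError if the denominator is not positive at some age, which
    signals a beta_eff inconsistent with the stated delay.
    """
    grid = beta_eff.grid
    if delta == 0:
        return beta_eff.with_values(beta_eff.values.copy())
    cum = beta_eff.cumulative()
    if math.isinf(delta):
        window = cum
    else:
        k = _delta_index(grid, delta)
        if k == 0:
            return beta_eff.with_values(beta_eff.values.copy())
        shifted = np.concatenate([np.zeros(k), cum[:-k]]) if k < grid.n else np.zeros(grid.n)
        window = cum - shifted
    denom = 1.0 - window
    if np.any(denom <= 0.0):
        a_bad = grid.nodes[int(np.argmax(denom <= 0.0))]
        raise ValueError(
            f"beta_eff inconsistent with delta={delta:g}: "
            f"trailing integral reaches 1 at age {a_bad:g}"
        )
    return beta_eff.with_values(beta_eff.values / denom)


def forward_beta_eff(beta0: RateSchedule, delta: float) -> RateSchedule:
    """Observed rate beta_eff from the first-birth rate beta0 under delay delta.

    Solves beta_eff(a) = beta0(a) * (1 - int_{max(0,a-delta)}^a beta_eff)
    by marching forward in age; the trapezoid contribution of the current
    node is handled implicitly, so ``reconstruct_beta0`` inverts the result
    exactly (up to rounding).  For delta = inf each female bears at most one
    child and the closed form beta_eff = beta0 * exp(-int_0^a beta0) is used.
    """
    grid = beta0.grid
    if delta == 0:
        return beta0.with_values(beta0.values.copy())
    if math.isinf(delta):
        return beta0.with_values(beta0.values * np.exp(-beta0.cumulative()))
    k = _delta_index(grid, delta)
    if k == 0:
        return beta0.with_values(beta0.values.copy())
    step = grid.step
    b0 = beta0.values
    n = grid.n
    v = np.zeros(n)
    cum = np.zeros(n)  # cumulative trapezoid of v, matching grid.cumtrapz
    clamped = False
    v[0] = b0[0]
    for i in range(1, n):
        # integral over [a_{i-k}, a_i] excluding the half-weight of node i
        head = cum[i - 1] + 0.5 * step * v[i - 1]
        tail = cum[i - k] if i >= k else 0.0
        s = head - tail
        if s >= 1.0:
            v[i] = 0.0
            clamped = True
        else:
            v[i] = b0[i] * (1.0 - s) / (1.0 + 0.5 * step * b0[i])
        cum[i] = cum[i - 1] + 0.5 * step * (v[i - 1] + v[i])
    if clamped:
        warnings.warn(
            "forward_beta_eff clamped beta_eff to 0 where the trailing integral "
            "reached 1 (beta0 * delta implausibly large)",
            stacklevel=2,
        )
    return beta0.with_values(v)


def truncate_by_refractory(beta0: RateSchedule, delta: float) -> BirthSurface:
    """Mother birth surface beta(a, tau) = beta0(a) * 1{tau > delta} on tau <= a."""
    grid = beta0.grid
    n = grid.n
    vals = np.zeros((n, n))
    quad = np.zeros((n, n))
    if math.isinf(delta):
        return BirthSurface(grid, vals, quad)
    k = _delta_index(grid, delta)
    ia = np.arange(n)[:, None]
    itau = np.arange(n)[None, :]
    mask = (itau > k) & (itau <= ia)
    vals[mask] = np.broadcast_to(beta0.values[:, None], (n, n))[mask]
    quad[:] = vals
    # limit from above at the cut node tau = delta
    rows = np.arange(k + 1, n)
    quad[rows, k] = beta0.values[rows]
    return BirthSurface(grid, vals, quad)


def clamp_fertile_window(rate: RateSchedule, a_min: float, a_max: float) -> RateSchedule:
    """Zero the schedule outside the fertile window [a_min, a_max]."""
    if a_min >= a_max:
        raise ValueError(f"need a_min < a_max, got ({a_min}, {a_max})")
    grid = rate.grid
    lo, hi = grid.index_of(a_min), grid.index_of(a_max)
    out = np.zeros_like(rate.values)
    out[lo : hi + 1] = rate.values[lo : hi + 1]
    return rate.with_values(out)


def behavioural_multipliers(delta: float) -> BehaviouralMultipliers:
    """Behavioural-response multipliers for a refractory period delta.

    c1 = 1 + 0.1 * min(delta - 2, 10)   (catch-up burst in the year after
    the refractory period ends); c2 = 1 + 0.05 * min(delta - 2, 10)
    (earlier first births, applied when a + delta <= 40).  Below the
    natural refractory period (delta < 2) the formulas do not apply and
    both multipliers are 1.
    """
    if delta < 2.0:
        warnings.warn(
            f"behavioural multipliers undefined for delta={delta:g} < 2; using 1",
            stacklevel=2,
        )
        return BehaviouralMultipliers(1.0, 1.0)
    excess = min(delta - 2.0, 10.0)
    return BehaviouralMultipliers(1.0 + 0.1 * excess, 1.0 + 0.05 * excess)


def apply_behavioural_response(
    beta0: RateSchedule, surface: BirthSurface, policy: PolicyConfig
) -> tuple[RateSchedule, BirthSurface]:
    """Adjust (beta0, surface) for behavioural response to the policy.

    Mothers who just cleared the refractory period give birth at
    c1 * beta0(a) for one year (delta < tau <= delta + 1); childless
    females young enough to fit another child before the age cutoff
    (a + delta <= 40) use c2 * beta0(a).
    """
    if not policy.behavioural:
        return beta0, surface
    grid = require_same_grid(beta0.grid, surface.grid)
    mult = behavioural_multipliers(policy.delta)
    delta = policy.delta
    n = grid.n

    # c2: earlier first births while a + delta <= age_cutoff
    b0_adj = beta0.values.copy()
    if not math.isinf(delta):
        young = grid.nodes + delta <= mult.age_cutoff + 1e-9
        b0_adj[young] *= mult.c2

    # c1: one-year catch-up window just after the refractory period
    vals = surface.values.copy()
    quad = surface.quad_values.copy()
    if not math.isinf(delta) and mult.c1 != 1.0:
        k = grid.index_of(delta)
        k1 = k + grid.index_of(1.0)
        window = slice(k + 1, min(k1 + 1, n))
        vals[:, window] *= mult.c1
        quad[:, window] *= mult.c1
        rows = np.arange(k + 1, n)
        quad[rows, k] *= mult.c1  # right limit at the cut is boosted
        if k1 < n:
            rows2 = np.arange(k1 + 1, n)
            quad[rows2, k1] = surface.values[rows2, k1]  # right limit past window
    return beta0.with_values(b0_adj), BirthSurface(grid, vals, quad)
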