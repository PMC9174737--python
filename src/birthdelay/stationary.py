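"""Stationary analysis: asymptotic growth rate and stationary age/parity densities.

At long times the normalized densities of the delayed-birth model converge
to stationary shapes h0(a) (childless), h(a, tau) (mothers) and
h_tot(a) = h0 + int h dtau, while the total population grows like
exp(lambda * t).  The growth rate is the unique root of the renewal
condition

    z(lambda) = eta * int_0^inf beta_eff(a) exp(-a lambda - int_0^a mu_f) da = 1,

an Euler–Lotka equation in the observed birth rate beta_eff.  For a
truncated birth surface beta(a, tau) = beta0(a) 1{tau > delta}, beta_eff
follows from beta0 by forward marching (`rates.forward_beta_eff`); for a
general surface (e.g. with behavioural response) the module solves the
two-component eigenproblem directly through a Volterra equation for the
new-mother boundary density h(a, 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import AgeGrid, require_same_grid
from .rates import (
    BirthSurface,
    PolicyConfig,
    RateSchedule,
    apply_behavioural_response,
    clamp_fertile_window,
    forward_beta_eff,
    truncate_by_refractory,
)

__all__ = [
    "StationaryState",
    "z_value",
    "solve_growth_rate",
    "solve_growth_rate_from_surface",
    "beta_eff_from_stationary",
    "solve_policy_growth_rate",
    "stationary_total_density",
    "stationary_childless_density",
    "stationary_mother_density",
    "stationary_state",
    "senior_fraction",
    "stationary_female_fraction",
    "scan_policy",
]

_BRACKET_LIMIT = 64.0
_Z_TOL = 1e-10


@dataclass(frozen=True)
class StationaryState:
    """Asymptotic growth rate and normalized stationary densities.

    h_tot integrates to 1; h0(a) + int_0^a h(a, tau) dtau = h_tot(a);
    beta_eff_used is the effective (whole-population) birth rate consistent
    with the policy that produced the state.
    """

    lam: float
    h_tot: RateSchedule
    h0: RateSchedule
    h_surface: np.ndarray
    beta_eff_used: RateSchedule

    @property
    def grid(self) -> AgeGrid:
        return self.h_tot.grid


def z_value(lam: float, beta_eff: RateSchedule, mu_f: RateSchedule, eta: float) -> float:
    """Renewal integral z(lambda); strictly decreasing in lambda."""
    grid = require_same_grid(beta_eff.grid, mu_f.grid)
    expo = -lam * grid.nodes - mu_f.cumulative()
    # evaluate only where beta_eff > 0: exp may overflow to inf at very
    # negative lambda on long grids, and 0 * inf would poison the sum
    integrand = np.zeros(grid.n)
    mask = beta_eff.values > 0.0
    with np.errstate(over="ignore"):
        integrand[mask] = beta_eff.values[mask] * np.exp(expo[mask])
    return float(eta * grid.trapz(integrand))


def _bisect_root(f, lo: float = -1.0, hi: float = 1.0) -> float:
    """Root of a decreasing function f (f(lo) > 0 > f(hi)), bracket-expanding."""
    while f(hi) > 0.0:
        hi *= 2.0
        if hi > _BRACKET_LIMIT:
            raise ValueError("growth rate root not bracketed below +64/yr")
    while f(lo) < 0.0:
        lo *= 2.0
        if lo < -_BRACKET_LIMIT:
            raise ValueError("growth rate root not bracketed above -64/yr")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < _Z_TOL or (hi - lo) < 1e-15:
            return mid
        if fm > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def solve_growth_rate(beta_eff: RateSchedule, mu_f: RateSchedule, eta: float) -> float:
    """Unique lambda with z(lambda) = 1 (bracketed bisection, |z - 1| < 1e-10)."""
    if beta_eff.integral() <= 0.0:
        raise ValueError("beta_eff is identically zero: no births, lambda undefined")
    return _bisect_root(lambda lam: z_value(lam, beta_eff, mu_f, eta) - 1.0)


# --- general (two-component) eigenproblem --------------------------------


def _char_decay(surface: BirthSurface, mu_f: RateSchedule) -> np.ndarray:
    """E0[i, j] = exp(-int over the characteristic from age a_{i-j} to a_i
    of (mu_f + beta along the diagonal)), the lambda-free part of the
    mother-density propagator.  Zero above the triangle.
    """
    grid = require_same_grid(surface.grid, mu_f.grid)
    n = grid.n
    step = grid.step
    mu = mu_f.values
    E0 = np.zeros((n, n))
    for d in range(n):
        m = n - d  # diagonal length, points (i=d+s, j=s)
        quad_diag = np.diagonal(surface.quad_values, offset=-d)
        vals_diag = np.diagonal(surface.values, offset=-d)
        mu_diag = mu[d:]
        seg = 0.5 * step * (
            mu_diag[:-1] + quad_diag[:-1] + mu_diag[1:] + vals_diag[1:]
        )
        cum = np.concatenate(([0.0], np.cumsum(seg)))
        E0[np.arange(d, n), np.arange(m)] = np.exp(-cum)
    return E0


def _tau_weights(surface: BirthSurface) -> np.ndarray:
    """W[i, j]: quadrature weight of beta*h at node (i, j) in the tau flux
    integral, with the jump-aware left/right convention."""
    n = surface.grid.n
    step = surface.grid.step
    # node j is a left endpoint of segment [j, j+1] only for j < i (strict),
    # and a right endpoint of [j-1, j] for 1 <= j <= i
    W = 0.5 * step * surface.quad_values * np.tril(np.ones((n, n)), k=-1)
    W[:, 1:] += 0.5 * step * surface.values[:, 1:]
    W *= np.tril(np.ones((n, n)))
    return W


class _GeneralEigenproblem:
    """Volterra-equation machinery for an arbitrary birth surface.

    For a trial lambda, the new-mother boundary density b(a) = h(a, 0)
    (with h0(0) = 1) satisfies

        b(a) = beta0(a) h0(a) + int_0^a beta(a,tau) b(a-tau) E(a,tau) dtau,

    marched forward in age; z(lambda) is then the boundary condition at
    age 0.  All lambda-free factors are precomputed once.
    """

    def __init__(self, beta0: RateSchedule, surface: BirthSurface, mu_f: RateSchedule):
        self.grid = require_same_grid(beta0.grid, surface.grid, mu_f.grid)
        self.beta0 = beta0
        self.mu_f = mu_f
        self.K = _tau_weights(surface) * _char_decay(surface, mu_f)
        self.h0_factor = np.exp(-self.grid.cumtrapz(mu_f.values + beta0.values))
        self.mu_cum = mu_f.cumulative()

    def boundary_density(self, lam: float) -> tuple[np.ndarray, np.ndarray]:
        """Returns (h0, b) for the trial lambda, normalized to h0(0) = 1."""
        grid = self.grid
        n = grid.n
        elam = np.exp(-lam * grid.step * np.arange(n))
        h0 = self.h0_factor * np.exp(-lam * grid.nodes)
        src = self.beta0.values * h0
        K = self.K
        b = np.zeros(n)
        b[0] = src[0] / (1.0 - K[0, 0]) if K[0, 0] < 1.0 else 0.0
        for i in range(1, n):
            ker = K[i, 1 : i + 1] * elam[1 : i + 1]
            conv = float(np.dot(ker, b[i - 1 :: -1]))
            denom = 1.0 - K[i, 0]
            b[i] = (src[i] + conv) / denom
        return h0, b

    def flux(self, lam: float, b: np.ndarray) -> np.ndarray:
        """Repeat-birth flux int beta(a,tau) h(a,tau) dtau per age node."""
        grid = self.grid
        n = grid.n
        elam = np.exp(-lam * grid.step * np.arange(n))
        out = np.zeros(n)
        K = self.K
        for i in range(1, n):
            out[i] = float(np.dot(K[i, : i + 1] * elam[: i + 1], b[i::-1]))
        return out

    def z(self, lam: float) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
        h0, b = self.boundary_density(lam)
        flux = self.flux(lam, b)
        first = self.beta0.values * h0
        return self.eta * (self.grid.trapz(first) + self.grid.trapz(flux)), h0, b, flux

    eta: float = 0.5


def solve_growth_rate_from_surface(
    beta0: RateSchedule, surface: BirthSurface, mu_f: RateSchedule, eta: float
) -> float:
    """Growth rate from the two-component eigenproblem for a general surface.

    Agrees with `solve_growth_rate` on `forward_beta_eff` output when the
    surface is the plain refractory truncation of beta0; required for
    behavioural-response surfaces where the simple beta0 <-> beta_eff
    relation does not hold.
    """
    prob = _GeneralEigenproblem(beta0, surface, mu_f)
    prob.eta = eta

    def f(lam: float) -> float:
        return prob.z(lam)[0] - 1.0

    return _bisect_root(f)


def beta_eff_from_stationary(
    beta0: RateSchedule, surface: BirthSurface, mu_f: RateSchedule, lam: float
) -> RateSchedule:
    """Effective birth rate from the stationary densities.

    beta_eff(a) = [beta0(a) h0(a) + int beta(a,tau) h(a,tau) dtau] / h_tot(a)
    with the densities built from (beta0, surface, lam) alone — an
    independent route that cross-validates `forward_beta_eff`.
    """
    prob = _GeneralEigenproblem(beta0, surface, mu_f)
    h0, b = prob.boundary_density(lam)
    flux = prob.flux(lam, b)
    grid = prob.grid
    h_tot = np.exp(-lam * grid.nodes - prob.mu_cum)
    return RateSchedule(grid, (beta0.values * h0 + flux) / h_tot)


# --- densities -----------------------------------------------------------


def stationary_total_density(lam: float, mu_f: RateSchedule) -> RateSchedule:
    """Normalized stationary age density h_tot(a) ∝ exp(-a lam - int_0^a mu_f)."""
    grid = mu_f.grid
    vals = np.exp(-lam * grid.nodes - mu_f.cumulative())
    return RateSchedule(grid, vals / grid.trapz(vals))


def stationary_childless_density(
    lam: float, mu_f: RateSchedule, beta0: RateSchedule, h_tot0: float
) -> RateSchedule:
    """Childless density h0(a) = h_tot(0) exp(-a lam - int_0^a (mu_f + beta0))."""
    grid = require_same_grid(mu_f.grid, beta0.grid)
    vals = h_tot0 * np.exp(-lam * grid.nodes - grid.cumtrapz(mu_f.values + beta0.values))
    return RateSchedule(grid, vals)


def stationary_mother_density(
    lam: float,
    mu_f: RateSchedule,
    surface: BirthSurface,
    h_tot: RateSchedule,
    beta_eff: RateSchedule,
    h0: RateSchedule | None = None,
    check_tol: float = 1e-2,
) -> np.ndarray:
    """Mother density h(a, tau) by the method of characteristics.

    h(a, tau) = h_tot(a-tau) beta_eff(a-tau)
                * exp(-tau lam - int_{a-tau}^a (mu_f + beta) along the path).

    If `h0` is given, the reconstruction identity
    h0 + int h dtau = h_tot is verified at every node (relative to the
    peak of h_tot); failure signals lambda/beta_eff inconsistent with the
    surface and raises ValueError.
    """
    grid = require_same_grid(mu_f.grid, surface.grid, h_tot.grid, beta_eff.grid)
    n = grid.n
    E0 = _char_decay(surface, mu_f)
    boundary = h_tot.values * beta_eff.values  # h(a, 0) = h_tot(a) beta_eff(a)
    h = np.zeros((n, n))
    taus = grid.step * np.arange(n)
    for d in range(n):
        m = n - d
        rows = np.arange(d, n)
        cols = np.arange(m)
        h[rows, cols] = boundary[d] * np.exp(-lam * taus[:m]) * E0[rows, cols]
    if h0 is not None:
        marg = np.trapezoid(h, dx=grid.step, axis=1)
        resid = np.abs(h0.values + marg - h_tot.values)
        worst = float(resid.max() / h_tot.values.max())
        if worst > check_tol:
            raise ValueError(
                f"stationary reconstruction h0 + int h dtau != h_tot "
                f"(max relative residual {worst:.3e}); lambda or beta_eff "
                f"inconsistent with the surface"
            )
    return h


def solve_policy_growth_rate(
    beta0: RateSchedule, policy: PolicyConfig, mu_f: RateSchedule
) -> tuple[float, RateSchedule]:
    """Growth rate and effective birth rate under a policy.

    Clamps beta0 to the fertile window, applies the refractory period
    (and, if enabled, the behavioural response), computes the
    policy-consistent beta_eff and solves z(lambda) = 1.
    """
    grid = require_same_grid(beta0.grid, mu_f.grid)
    pol = policy.snapped(grid)
    b0 = clamp_fertile_window(beta0, pol.a_min, pol.a_max)
    if pol.behavioural and not math.isinf(pol.delta) and pol.delta > 2.0:
        surface = truncate_by_refractory(b0, pol.delta)
        b0_adj, surf_adj = apply_behavioural_response(b0, surface, pol)
        lam = solve_growth_rate_from_surface(b0_adj, surf_adj, mu_f, pol.eta)
        beta_eff = beta_eff_from_stationary(b0_adj, surf_adj, mu_f, lam)
        return lam, beta_eff
    beta_eff = forward_beta_eff(b0, pol.delta)
    lam = solve_growth_rate(beta_eff, mu_f, pol.eta)
    return lam, beta_eff


def stationary_state(
    beta0: RateSchedule, policy: PolicyConfig, mu_f: RateSchedule
) -> StationaryState:
    """Full stationary solution (lambda and all normalized densities)."""
    grid = require_same_grid(beta0.grid, mu_f.grid)
    pol = policy.snapped(grid)
    b0 = clamp_fertile_window(beta0, pol.a_min, pol.a_max)
    surface = truncate_by_refractory(b0, pol.delta)
    if pol.behavioural and not math.isinf(pol.delta) and pol.delta > 2.0:
        b0, surface = apply_behavioural_response(b0, surface, pol)
    lam, beta_eff = solve_policy_growth_rate(beta0, pol, mu_f)
    h_tot = stationary_total_density(lam, mu_f)
    h0 = stationary_childless_density(lam, mu_f, b0, float(h_tot.values[0]))
    h = stationary_mother_density(lam, mu_f, surface, h_tot, beta_eff, h0=h0)
    return StationaryState(lam, h_tot, h0, h, beta_eff)


# --- policy summaries ----------------------------------------------------


def senior_fraction(h_tot: RateSchedule, threshold: float = 65.0) -> float:
    """Share of the stationary population aged `threshold` and above."""
    grid = h_tot.grid
    i = grid.index_of(threshold)
    return float(np.trapezoid(h_tot.values[i:], dx=grid.step))


def stationary_female_fraction(
    lam: float, mu_f: RateSchedule, mu_m: RateSchedule, eta: float
) -> float:
    """Stationary female share of the two-sex population.

    Both sexes share the female-driven birth stream (eta female,
    1 - eta male) and grow at the female-system lambda, so the stationary
    masses are F ∝ eta int exp(-a lam - int mu_f) da and
    M ∝ (1-eta) int exp(-a lam - int mu_m) da.
    """
    grid = require_same_grid(mu_f.grid, mu_m.grid)
    female = eta * grid.trapz(np.exp(-lam * grid.nodes - mu_f.cumulative()))
    male = (1.0 - eta) * grid.trapz(np.exp(-lam * grid.nodes - mu_m.cumulative()))
    return float(female / (female + male))


def scan_policy(
    beta0: RateSchedule,
    mu_f: RateSchedule,
    mu_m: RateSchedule,
    deltas: Sequence[float],
    a_mins: Sequence[float],
    eta: float,
    a_max: float = 50.0,
    behavioural: bool = False,
    senior_threshold: float = 65.0,
) -> pd.DataFrame:
    """Policy scan over a (delta, a_min) grid.

    Returns one row per combination (delta outer loop, a_min inner) with
    columns delta, a_min, lambda, senior_fraction, female_fraction.
    """
    rows = []
    for delta in deltas:
        for a_min in a_mins:
            pol = PolicyConfig(
                delta=delta, a_min=a_min, a_max=a_max, eta=eta, behavioural=behavioural
            )
            lam, _ = solve_policy_growth_rate(beta0, pol, mu_f)
            h_tot = stationary_total_density(lam, mu_f)
            rows.append(
                {
                    "delta": delta,
                    "a_min": a_min,
                    "lambda": lam,
                    "senior_fraction": senior_fraction(h_tot, senior_threshold),
                    "female_fraction": stationary_female_fraction(lam, mu_f, mu_m, eta),
                }
            )
    return pd.DataFrame(rows, columns=["delta", "a_min", "lambda", "senior_fraction", "female_fraction"])
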