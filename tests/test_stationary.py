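"""Growth-rate eigenproblem, stationary densities and policy summaries."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

import birthdelay as bd
from birthdelay.grids import AgeGrid
from birthdelay.rates import RateSchedule, clamp_fertile_window, truncate_by_refractory
from birthdelay.stationary import (
    beta_eff_from_stationary,
    solve_growth_rate_from_surface,
    stationary_mother_density,
)


def const(grid, value):
    return RateSchedule(grid, np.full(grid.n, value))


class TestZValue:
    def test_constant_rates_closed_form(self, long_grid):
        # z(lambda) = eta b / (lambda + m) for constant schedules
        beff, mu = const(long_grid, 0.1), const(long_grid, 0.02)
        assert bd.z_value(0.03, beff, mu, 0.5) == pytest.approx(1.0, abs=1e-5)
        assert bd.z_value(0.08, beff, mu, 0.5) == pytest.approx(0.5, abs=1e-5)

    def test_vanishes_at_large_lambda(self, preset):
        assert bd.z_value(10.0, preset.beta_eff, preset.mu_f, 0.48) < 1e-3

    def test_strictly_decreasing(self, preset):
        lams = np.linspace(-0.2, 0.2, 9)
        zs = [bd.z_value(l, preset.beta_eff, preset.mu_f, 0.48) for l in lams]
        assert np.all(np.diff(zs) < 0)


class TestSolveGrowthRate:
    def test_constant_rates_closed_form(self, long_grid):
        lam = bd.solve_growth_rate(const(long_grid, 0.1), const(long_grid, 0.02), 0.5)
        assert lam == pytest.approx(0.03, abs=1e-6)

    def test_scaled_schedule_gives_zero_growth(self, preset):
        z0 = bd.z_value(0.0, preset.beta_eff, preset.mu_f, 0.48)
        scaled = preset.beta_eff.with_values(preset.beta_eff.values / z0)
        lam = bd.solve_growth_rate(scaled, preset.mu_f, 0.48)
        assert lam == pytest.approx(0.0, abs=1e-12)

    def test_fertility_window_against_analytic_root(self, long_grid):
        # fertility confined to a window around [20, 30], mu = 0; the
        # independent oracle integrates the same piecewise-linear rate with
        # adaptive quadrature and bisects the analytic renewal condition
        from scipy.integrate import quad

        grid = long_grid
        knots_a = [19.9, 20.0, 30.0, 30.1]
        knots_v = [0.0, 0.3, 0.3, 0.0]
        vals = np.interp(grid.nodes, knots_a, knots_v, left=0.0, right=0.0)
        lam = bd.solve_growth_rate(RateSchedule(grid, vals), const(grid, 0.0), 0.5)

        def z_analytic(l):
            val, _ = quad(
                lambda a: np.interp(a, knots_a, knots_v) * math.exp(-l * a), 19.9, 30.1
            )
            return 0.5 * val - 1.0

        lam_ref = brentq(z_analytic, 1e-6, 1.0, xtol=1e-14)
        assert lam == pytest.approx(lam_ref, abs=2e-5)

    def test_no_births_raises(self, long_grid):
        with pytest.raises(ValueError, match="zero"):
            bd.solve_growth_rate(const(long_grid, 0.0), const(long_grid, 0.01), 0.5)

    def test_increasing_in_eta(self, preset):
        lams = [
            bd.solve_growth_rate(preset.beta_eff, preset.mu_f, eta)
            for eta in (0.4, 0.48, 0.6)
        ]
        assert lams[0] < lams[1] < lams[2]

    def test_decreasing_in_mortality(self, preset):
        bumped = preset.mu_f.with_values(preset.mu_f.values + 0.01)
        assert bd.solve_growth_rate(preset.beta_eff, bumped, 0.48) < bd.solve_growth_rate(
            preset.beta_eff, preset.mu_f, 0.48
        )


class TestPolicyGrowthRate:
    def test_strict_one_child_constant_closed_form(self, long_grid):
        # delta = inf, beta0 = b, mu = 0: beta_eff = b e^{-ba},
        # z = eta b / (b + lambda) = 1 => lambda = -b (1 - eta)
        pol = bd.PolicyConfig(delta=math.inf, a_min=0.0, a_max=2000.0, eta=0.48)
        lam, beff = bd.solve_policy_growth_rate(const(long_grid, 0.1), pol, const(long_grid, 0.0))
        assert lam == pytest.approx(-0.1 * 0.52, abs=1e-4)
        np.testing.assert_allclose(
            beff.values, 0.1 * np.exp(-0.1 * long_grid.nodes), rtol=1e-6
        )

    def test_lambda_non_increasing_in_delta(self, preset, beta0):
        deltas = [2.0, 3.0, 4.0, 6.0, 10.0, 20.0, 45.0, math.inf]
        lams = [
            bd.solve_policy_growth_rate(beta0, bd.PolicyConfig(delta=d), preset.mu_f)[0]
            for d in deltas
        ]
        assert np.all(np.diff(lams) <= 1e-12)
        # largest drop per unit delta at small delta, and a flat tail once
        # delta exceeds the fertile window span
        assert (lams[0] - lams[1]) > (lams[2] - lams[3]) / 2
        assert lams[-2] == pytest.approx(lams[-1], abs=1e-5)

    def test_general_eigenproblem_agrees_with_marching(self, preset, beta0):
        # same lambda from the Volterra two-component route and from the
        # beta_eff marching + Euler-Lotka route
        b0c = clamp_fertile_window(beta0, 12.0, 50.0)
        for delta in (2.0, 6.0):
            lam_march, _ = bd.solve_policy_growth_rate(
                beta0, bd.PolicyConfig(delta=delta), preset.mu_f
            )
            surf = truncate_by_refractory(b0c, delta)
            lam_gen = solve_growth_rate_from_surface(b0c, surf, preset.mu_f, 0.48)
            assert lam_gen == pytest.approx(lam_march, abs=2e-5)

    def test_effective_rate_closure(self, preset, beta0):
        # beta_eff from the stationary densities equals beta_eff from
        # forward marching of the delay relation
        b0c = clamp_fertile_window(beta0, 12.0, 50.0)
        for delta in (2.0, 4.0):
            lam, beff = bd.solve_policy_growth_rate(
                beta0, bd.PolicyConfig(delta=delta), preset.mu_f
            )
            surf = truncate_by_refractory(b0c, delta)
            beff_dens = beta_eff_from_stationary(b0c, surf, preset.mu_f, lam)
            assert np.max(np.abs(beff_dens.values - beff.values)) < 1e-4

    def test_behavioural_response_raises_growth(self, preset, beta0):
        lam_plain, _ = bd.solve_policy_growth_rate(
            beta0, bd.PolicyConfig(delta=6.0), preset.mu_f
        )
        lam_resp, _ = bd.solve_policy_growth_rate(
            beta0, bd.PolicyConfig(delta=6.0, behavioural=True), preset.mu_f
        )
        assert lam_resp > lam_plain
        # the response blunts, but does not erase, the policy effect
        lam_base, _ = bd.solve_policy_growth_rate(
            beta0, bd.PolicyConfig(delta=2.0), preset.mu_f
        )
        assert lam_resp < lam_base


class TestStationaryDensities:
    def test_total_density_uniform(self):
        grid = AgeGrid(100.0, 0.1)
        h = bd.stationary_total_density(0.0, const(grid, 0.0))
        np.testing.assert_allclose(h.values, 0.01, rtol=1e-12)

    def test_total_density_exponential(self, long_grid):
        lam, m = 0.01, 0.02
        h = bd.stationary_total_density(lam, const(long_grid, m))
        expected = (lam + m) * np.exp(-(lam + m) * long_grid.nodes)
        np.testing.assert_allclose(h.values, expected, rtol=1e-5)

    def test_total_density_peak_when_shrinking(self, preset, stationary_cache):
        # lambda < 0 with realistic mortality: interior maximum appears
        st = stationary_cache(8.0)
        assert st.lam < 0
        peak = np.argmax(st.h_tot.values)
        assert 0 < peak < st.grid.n - 1
        assert st.h_tot.values[peak] > st.h_tot.values[0]

    def test_childless_equals_total_without_births(self, long_grid):
        mu = const(long_grid, 0.01)
        h_tot = bd.stationary_total_density(0.005, mu)
        h0 = bd.stationary_childless_density(
            0.005, mu, const(long_grid, 0.0), float(h_tot.values[0])
        )
        np.testing.assert_allclose(h0.values, h_tot.values, rtol=1e-12)

    def test_childless_ratio_identity(self, preset, beta0):
        # h0 / h_tot = exp(-int beta0), independent of lambda and mu_f
        b0c = clamp_fertile_window(beta0, 12.0, 50.0)
        expected = np.exp(-b0c.cumulative())
        for lam in (-0.01, 0.02):
            h_tot = bd.stationary_total_density(lam, preset.mu_f)
            h0 = bd.stationary_childless_density(lam, preset.mu_f, b0c, float(h_tot.values[0]))
            np.testing.assert_allclose(h0.values / h_tot.values, expected, rtol=1e-10)
        # constant ratio past the fertile window
        tail = preset.grid.nodes > 50.0
        assert np.ptp(expected[tail]) == 0.0

    def test_mother_density_zero_at_age_zero(self, stationary_cache):
        st = stationary_cache(2.0)
        np.testing.assert_array_equal(st.h_surface[0, :], 0.0)

    def test_mother_density_one_child_closed_form(self, preset, beta0):
        # zero surface: no within-mother attrition by further births
        pol = bd.PolicyConfig(delta=math.inf)
        st = bd.stationary_state(beta0, pol, preset.mu_f)
        grid = st.grid
        mu_cum = preset.mu_f.cumulative()
        boundary = st.h_tot.values * st.beta_eff_used.values
        i, j = grid.index_of(30.0), grid.index_of(5.0)
        d = i - j
        expected = boundary[d] * math.exp(
            -st.lam * grid.nodes[j] - (mu_cum[i] - mu_cum[d])
        )
        assert st.h_surface[i, j] == pytest.approx(expected, rel=1e-6)

    def test_reconstruction_identity(self, stationary_cache):
        for delta in (2.0, 6.0):
            st = stationary_cache(delta)
            marg = np.trapezoid(st.h_surface, dx=st.grid.step, axis=1)
            resid = np.abs(st.h0.values + marg - st.h_tot.values)
            assert resid.max() / st.h_tot.values.max() < 1e-3
            assert st.grid.trapz(st.h_tot.values) == pytest.approx(1.0, abs=1e-10)

    def test_inconsistent_lambda_rejected(self, preset, beta0):
        b0c = clamp_fertile_window(beta0, 12.0, 50.0)
        lam, beff = bd.solve_policy_growth_rate(beta0, bd.PolicyConfig(delta=2.0), preset.mu_f)
        surf = truncate_by_refractory(b0c, 2.0)
        h_tot = bd.stationary_total_density(lam + 0.05, preset.mu_f)  # wrong lambda
        h0 = bd.stationary_childless_density(
            lam + 0.05, preset.mu_f, b0c, float(h_tot.values[0])
        )
        with pytest.raises(ValueError, match="inconsistent"):
            stationary_mother_density(
                lam, preset.mu_f, surf, h_tot, beff, h0=h0, check_tol=1e-3
            )


class TestSummaries:
    def test_senior_fraction_uniform(self):
        grid = AgeGrid(100.0, 0.1)
        h = bd.stationary_total_density(0.0, const(grid, 0.0))
        assert bd.senior_fraction(h) == pytest.approx(0.35, abs=1e-12)

    def test_senior_fraction_exponential(self, long_grid):
        lam, m = 0.0, 0.02
        h = bd.stationary_total_density(lam, const(long_grid, m))
        assert bd.senior_fraction(h) == pytest.approx(math.exp(-65 * (lam + m)), rel=1e-4)

    def test_senior_fraction_grows_with_delta(self, preset, beta0):
        fracs = []
        for delta in (2.0, 4.0, 8.0, math.inf):
            lam, _ = bd.solve_policy_growth_rate(beta0, bd.PolicyConfig(delta=delta), preset.mu_f)
            fracs.append(bd.senior_fraction(bd.stationary_total_density(lam, preset.mu_f)))
        assert np.all(np.diff(fracs) > 0)

    def test_female_fraction_equals_eta_for_equal_mortality(self, preset):
        frac = bd.stationary_female_fraction(0.004, preset.mu_f, preset.mu_f, 0.48)
        assert frac == pytest.approx(0.48, abs=1e-14)

    def test_female_fraction_constant_mortalities(self, long_grid):
        # lambda = 0: F ∝ eta/mu_f = 48, M ∝ (1-eta)/mu_m = 26
        frac = bd.stationary_female_fraction(
            0.0, const(long_grid, 0.01), const(long_grid, 0.02), 0.48
        )
        assert frac == pytest.approx(48.0 / 74.0, rel=1e-4)

    def test_female_fraction_increases_with_delta(self, preset, beta0):
        fracs = []
        for delta in (2.0, 6.0, math.inf):
            lam, _ = bd.solve_policy_growth_rate(beta0, bd.PolicyConfig(delta=delta), preset.mu_f)
            fracs.append(bd.stationary_female_fraction(lam, preset.mu_f, preset.mu_m, 0.48))
        assert np.all(np.diff(fracs) > 0)
        assert fracs[0] > 0.48  # female mortality advantage at old age


class TestScanPolicy:
    def test_single_point_matches_direct_solve(self, preset, beta0):
        df = bd.scan_policy(beta0, preset.mu_f, preset.mu_m, [2.0], [12.0], 0.48)
        lam, _ = bd.solve_policy_growth_rate(beta0, bd.PolicyConfig(delta=2.0), preset.mu_f)
        assert len(df) == 1
        assert df["lambda"].iloc[0] == pytest.approx(lam, abs=1e-12)

    def test_row_order_and_monotone_delta(self, preset, beta0):
        df = bd.scan_policy(beta0, preset.mu_f, preset.mu_m, [2.0, 4.0, 6.0], [12.0, 20.0], 0.48)
        assert list(df["delta"]) == [2.0, 2.0, 4.0, 4.0, 6.0, 6.0]
        for a_min in (12.0, 20.0):
            sub = df[df["a_min"] == a_min]
            assert np.all(np.diff(sub["lambda"]) < 0)

    def test_one_child_amin_interior_maximum(self, preset, beta0):
        # under the strict one-child limit, raising the minimum childbearing
        # age first raises lambda (longer generations while nearly everyone
        # still has their one child), then lowers it
        a_mins = np.arange(12.0, 37.0, 1.0)
        df = bd.scan_policy(beta0, preset.mu_f, preset.mu_m, [math.inf], a_mins, 0.48)
        lams = df["lambda"].to_numpy()
        k = int(np.argmax(lams))
        assert 0 < k < len(lams) - 1
        assert lams[k] > lams[0] and lams[k] > lams[-1]
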