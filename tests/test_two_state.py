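"""Closed-form two-state model versus independent oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from petite_dynamics import (
    Regime,
    TwoStateParams,
    ValidationError,
    classify_regime,
    equilibrium_fraction,
    mutant_fraction_at,
    population_growth_rate,
    solve_closed_form,
    sweep_fraction_grid,
)


def _random_params(rng):
    g_wt = rng.uniform(0.05, 1.0)
    r = rng.uniform(0.0, 0.5)
    g_mut = rng.uniform(0.0, 1.0)
    return TwoStateParams(
        g_wt=g_wt, g_mut=g_mut, r=r,
        p_wt0=rng.uniform(0.1, 10.0), p_mut0=rng.uniform(0.0, 5.0),
    )


class TestClosedFormVsODE:
    def test_random_parameter_grid(self, ode_oracle):
        rng = np.random.default_rng(42)
        times = np.array([0.3, 1.7, 4.0, 9.5])
        for _ in range(30):
            p = _random_params(rng)
            traj = solve_closed_form(p, times)
            wt, mut = ode_oracle(p, times)
            assert np.allclose(traj.p_wt, wt, rtol=1e-8)
            assert np.allclose(traj.p_mut, mut, rtol=1e-8, atol=1e-12)

    def test_degenerate_branch_matches_ode(self, ode_oracle):
        rng = np.random.default_rng(7)
        times = np.array([1.0, 5.0, 12.0])
        for _ in range(10):
            g_wt = rng.uniform(0.2, 0.8)
            r = rng.uniform(0.01, 0.15)
            p = TwoStateParams(g_wt=g_wt, g_mut=g_wt - r, r=r, p_wt0=2.0, p_mut0=0.5)
            traj = solve_closed_form(p, times)
            wt, mut = ode_oracle(p, times)
            assert np.allclose(traj.p_wt, wt, rtol=1e-8)
            assert np.allclose(traj.p_mut, mut, rtol=1e-8)

    def test_degenerate_branch_is_limit_of_generic(self):
        base = dict(g_wt=0.5, r=0.1, p_wt0=1.0, p_mut0=0.2)
        t = np.array([2.0, 8.0])
        exact = solve_closed_form(TwoStateParams(g_mut=0.4, **base), t)
        near = solve_closed_form(TwoStateParams(g_mut=0.4 + 1e-8, **base), t)
        assert np.allclose(exact.p_mut, near.p_mut, rtol=1e-6)

    def test_example_params_match_ode(self, ode_oracle):
        p = TwoStateParams(g_wt=0.5, g_mut=0.25, r=0.05, p_wt0=1.0, p_mut0=0.0)
        traj = solve_closed_form(p, [10.0])
        wt, mut = ode_oracle(p, [10.0])
        assert np.allclose(traj.p_wt, wt, rtol=1e-8)
        assert np.allclose(traj.p_mut, mut, rtol=1e-8)


class TestClosedFormBasics:
    def test_no_loss_no_initial_mutants_stays_pure(self):
        p = TwoStateParams(g_wt=0.6, g_mut=0.2, r=0.0, p_wt0=1.0, p_mut0=0.0)
        traj = solve_closed_form(p, [5.0])
        assert traj.p_mut[0] == 0.0
        assert traj.f[0] == 0.0

    def test_time_zero_returns_initial_condition(self):
        p = TwoStateParams(g_wt=0.4, g_mut=0.3, r=0.1, p_wt0=2.5, p_mut0=1.5)
        traj = solve_closed_form(p, [0.0])
        assert traj.p_wt[0] == pytest.approx(2.5)
        assert traj.p_mut[0] == pytest.approx(1.5)

    def test_negative_time_rejected(self):
        p = TwoStateParams(g_wt=0.4, g_mut=0.3, r=0.1)
        with pytest.raises(ValidationError):
            solve_closed_form(p, [-1.0])
        with pytest.raises(ValidationError):
            solve_closed_form(p, [np.nan])

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(g_wt=0.4, g_mut=0.3, r=-0.1),
            dict(g_wt=0.4, g_mut=0.3, r=0.1, p_wt0=0.0, p_mut0=0.0),
            dict(g_wt=np.inf, g_mut=0.3, r=0.1),
            dict(g_wt=0.4, g_mut=0.3, r=0.1, p_wt0=-1.0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            TwoStateParams(**kwargs)

    def test_cell_conservation_with_zero_growth(self):
        # pure conversion: a rho+ cell becomes a rho0 cell, total constant
        p = TwoStateParams(g_wt=0.0, g_mut=0.0, r=0.3, p_wt0=4.0, p_mut0=1.0)
        traj = solve_closed_form(p, np.linspace(0, 20, 11))
        assert np.allclose(traj.p_wt + traj.p_mut, 5.0, rtol=1e-12)


class TestMutantFraction:
    def test_zero_without_source(self):
        p = TwoStateParams(g_wt=0.5, g_mut=0.3, r=0.0, p_mut0=0.0)
        assert mutant_fraction_at(p, 100.0) == 0.0

    def test_faster_mutant_outcompetes(self):
        p = TwoStateParams(g_wt=0.3, g_mut=0.6, r=0.0, p_wt0=1.0, p_mut0=0.01)
        assert mutant_fraction_at(p, 100.0) > 0.999

    def test_coexistence_limit_matches_equilibrium(self):
        p = TwoStateParams(g_wt=0.5, g_mut=0.3, r=0.05, p_mut0=0.0)
        assert mutant_fraction_at(p, 200.0) == pytest.approx(0.25, abs=1e-6)

    def test_overflow_safe_at_very_large_time(self):
        p = TwoStateParams(g_wt=1.0, g_mut=0.5, r=0.2)
        f = mutant_fraction_at(p, 5000.0)
        assert 0.0 <= f <= 1.0

    def test_monotone_and_bounded_by_equilibrium(self):
        p = TwoStateParams(g_wt=0.5, g_mut=0.3, r=0.05, p_mut0=0.0)
        f_star = equilibrium_fraction(p)
        f = np.atleast_1d(mutant_fraction_at(p, np.linspace(0, 120, 200)))
        assert np.all(np.diff(f) >= -1e-12)
        assert np.all(f <= f_star + 1e-9)

    @given(
        g_wt=st.floats(0.01, 1.0),
        g_mut=st.floats(0.0, 1.0),
        r=st.floats(0.0, 0.5),
        f0=st.floats(0.0, 1.0),
        t=st.floats(0.0, 500.0),
    )
    def test_fraction_always_in_unit_interval(self, g_wt, g_mut, r, f0, t):
        p = TwoStateParams(g_wt=g_wt, g_mut=g_mut, r=r).with_initial_fraction(f0)
        f = mutant_fraction_at(p, t)
        assert 0.0 <= f <= 1.0


class TestEquilibriumAndRegime:
    def test_no_loss_equilibrium_zero(self):
        assert equilibrium_fraction(TwoStateParams(g_wt=0.5, g_mut=0.3, r=0.0)) == 0.0

    def test_coexistence_equilibrium_matches_ode_limit(self):
        p = TwoStateParams(g_wt=0.5, g_mut=0.3, r=0.05)
        assert equilibrium_fraction(p) == pytest.approx(0.25, abs=1e-12)
        assert mutant_fraction_at(p, 300.0) == pytest.approx(0.25, abs=1e-6)

    def test_high_loss_rate_fixes_mutant(self):
        assert equilibrium_fraction(TwoStateParams(g_wt=0.5, g_mut=0.5, r=0.1)) == 1.0

    @pytest.mark.parametrize(
        "g_wt,g_mut,r,expected",
        [
            (0.5, 0.3, 0.05, Regime.COEXISTENCE),
            (0.5, 0.6, 0.0, Regime.FIXATION),
            (0.5, 0.4, 0.1, Regime.FIXATION),  # boundary g_wt - r == g_mut
        ],
    )
    def test_regime_classification(self, g_wt, g_mut, r, expected):
        label = classify_regime(TwoStateParams(g_wt=g_wt, g_mut=g_mut, r=r))
        assert label.regime is expected
        if expected is Regime.FIXATION:
            assert label.f_star == 1.0
        else:
            assert label.f_star < 1.0

    def test_long_run_rate_is_max_branch_rate(self):
        for p in (
            TwoStateParams(g_wt=0.5, g_mut=0.3, r=0.05),
            TwoStateParams(g_wt=0.5, g_mut=0.6, r=0.05),
        ):
            label = classify_regime(p)
            assert label.long_run_growth_rate == pytest.approx(
                max(p.g_wt - p.r, p.g_mut), abs=1e-12
            )


class TestPopulationGrowthRate:
    def test_pure_wildtype_rate(self):
        p = TwoStateParams(g_wt=0.45, g_mut=0.1, r=0.0, p_mut0=0.0)
        for t in (0.0, 3.0, 50.0):
            assert population_growth_rate(p, t) == pytest.approx(0.45)

    def test_long_run_weighted_average(self):
        p = TwoStateParams(g_wt=0.5, g_mut=0.3, r=0.05)
        f_star = equilibrium_fraction(p)
        expect = (1 - f_star) * p.g_wt + f_star * p.g_mut
        assert population_growth_rate(p, 400.0) == pytest.approx(expect, abs=1e-6)

    def test_matches_finite_difference_of_log_total(self):
        p = TwoStateParams(g_wt=0.5, g_mut=0.2, r=0.08, p_wt0=1.0, p_mut0=0.3)
        h = 1e-5
        for t in (0.5, 2.0, 10.0):
            lo = solve_closed_form(p, [t - h])
            hi = solve_closed_form(p, [t + h])
            fd = (
                np.log(hi.p_wt[0] + hi.p_mut[0]) - np.log(lo.p_wt[0] + lo.p_mut[0])
            ) / (2 * h)
            assert population_growth_rate(p, t) == pytest.approx(fd, rel=1e-6)

    def test_underflowed_total_raises(self):
        from petite_dynamics import UndefinedFractionError

        # a pure, strongly decaying mutant population underflows to zero total
        p = TwoStateParams(g_wt=0.0, g_mut=-800.0, r=0.0, p_wt0=0.0, p_mut0=1e-300)
        with pytest.raises(UndefinedFractionError):
            mutant_fraction_at(p, 10.0)


class TestSweep:
    def test_zero_loss_row_is_zero(self):
        base = TwoStateParams(g_wt=0.5, g_mut=0.3, r=0.1, p_mut0=0.0)
        grid = sweep_fraction_grid(base, "r", [0.0], [1.0, 5.0, 10.0])
        assert np.all(grid == 0.0)

    def test_fraction_monotone_in_loss_rate_and_mutant_rate(self):
        base = TwoStateParams(g_wt=0.5, g_mut=0.3, r=0.05, p_mut0=0.0)
        times = [2.0, 6.0, 12.0]
        grid_r = sweep_fraction_grid(base, "r", np.linspace(0, 0.2, 9), times)
        assert np.all(np.diff(grid_r, axis=0) >= -1e-12)
        base2 = TwoStateParams(g_wt=0.5, g_mut=0.0, r=0.05, p_mut0=0.0)
        grid_g = sweep_fraction_grid(base2, "g_mut", np.linspace(0, 0.8, 9), times)
        assert np.all(np.diff(grid_g, axis=0) >= -1e-12)

    def test_grid_splits_between_regimes(self):
        base = TwoStateParams(g_wt=0.5, g_mut=0.0, r=0.1, p_mut0=0.0)
        g_mut_values = [0.1, 0.7]  # below and above g_wt - r
        grid = sweep_fraction_grid(base, "g_mut", g_mut_values, [300.0])
        f_star_low = equilibrium_fraction(
            TwoStateParams(g_wt=0.5, g_mut=0.1, r=0.1)
        )
        assert grid[0, 0] == pytest.approx(f_star_low, abs=1e-6)
        assert grid[1, 0] > 0.999

    def test_unknown_parameter_rejected(self):
        base = TwoStateParams(g_wt=0.5, g_mut=0.3, r=0.05)
        with pytest.raises(ValidationError):
            sweep_fraction_grid(base, "g_wt", [0.1], [1.0])
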