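"""Two-strain consortium: dynamics, steady states, scans and the homeostatic range."""

import numpy as np
import pytest

from microdaisy import (
    SystemState,
    homeostatic_range,
    integrate,
    rhs_two,
    scan_surface,
    steady_state,
    symmetric_consortium,
)
from microdaisy.two_strain import free_ph


@pytest.fixture(scope="module")
def params():
    return symmetric_consortium()  # gamma=0.04, delta=0.01, omega=0.5, opt 7, width 9


@pytest.fixture(scope="module")
def slice_004(params):
    """Steady-state slice at gamma = 0.04 over the default pH_in grid."""
    return scan_surface(params, gamma_grid=[0.04])


class TestRhs:
    def test_extinction_is_absorbing(self, params):
        dx = rhs_two(SystemState(abundances=[0.0, 0.0], pH_f=7.0), params)
        np.testing.assert_array_equal(dx, [0.0, 0.0])

    def test_mirror_symmetry_at_neutral_input(self, params):
        dx = rhs_two(SystemState(abundances=[0.2, 0.2], pH_f=7.0), params)
        assert dx[0] == pytest.approx(dx[1])

    def test_full_occupancy_leaves_pure_dilution(self, params):
        dx = rhs_two(SystemState(abundances=[1.0, 0.0], pH_f=7.0), params)
        assert dx[0] == pytest.approx(-params.delta * 1.0)

    def test_ph_is_algebraic_not_integrated(self, params):
        # whatever pH_f the state claims, the derivative uses the QSS relation
        a = rhs_two(SystemState(abundances=[0.3, 0.1], pH_f=2.0), params)
        b = rhs_two(SystemState(abundances=[0.3, 0.1], pH_f=12.0), params)
        np.testing.assert_array_equal(a, b)

    def test_invalid_sign_convention_rejected(self):
        with pytest.raises(ValueError):
            symmetric_consortium(gamma=-0.04)


class TestIntegrate:
    def test_euler_matches_exponential_decay(self):
        traj = integrate(lambda x: -0.01 * x, [1.0], dt=0.01, t_end=100.0)
        assert traj.abundances[-1, 0] == pytest.approx(np.exp(-1.0), abs=1e-3)

    def test_rk4_agrees_with_euler_at_small_step(self):
        rhs = lambda x: -0.01 * x  # noqa: E731
        eu = integrate(rhs, [1.0], dt=0.01, t_end=100.0, method="euler")
        rk = integrate(rhs, [1.0], dt=0.01, t_end=100.0, method="rk4")
        assert abs(eu.abundances[-1, 0] - rk.abundances[-1, 0]) < 1e-4

    def test_step_halving_converges_at_steady_state(self, params):
        rhs = lambda x: rhs_two(SystemState(abundances=x, pH_f=0.0), params)  # noqa: E731
        coarse = integrate(rhs, [0.01, 0.01], dt=0.02, t_end=3000.0)
        fine = integrate(rhs, [0.01, 0.01], dt=0.01, t_end=3000.0)
        assert np.abs(coarse.abundances[-1] - fine.abundances[-1]).max() < 1e-6

    def test_records_free_ph_when_given(self, params):
        rhs = lambda x: rhs_two(SystemState(abundances=x, pH_f=0.0), params)  # noqa: E731
        traj = integrate(
            rhs, [0.01, 0.01], dt=0.01, t_end=1.0, free_ph_fn=lambda x: free_ph(x, params)
        )
        assert np.isfinite(traj.pH_f).all()

    def test_bad_method_rejected(self):
        with pytest.raises(ValueError):
            integrate(lambda x: x, [1.0], dt=0.01, t_end=1.0, method="heun")


class TestSteadyState:
    def test_balanced_equilibrium_at_neutral_input(self, params):
        r = steady_state(params)
        assert r.converged
        assert r.state.pH_f == pytest.approx(7.0, abs=1e-9)
        assert r.state.abundances[0] == pytest.approx(r.state.abundances[1], abs=1e-9)

    def test_coexistence_closed_form(self, params):
        # quasi-steady-state algebra: both strains at growth-dilution balance
        # forces pH_f = pH_opt, total = 1 - delta/beta(pH_opt + omega*gamma/delta)
        # and the population split X_a - X_b = (pH_opt - pH_in) * delta / gamma
        beta_eq = 1.0 - (2.0 / 9.0) ** 2
        expected_total = 1.0 - 0.01 / beta_eq  # 0.98948...
        # tolerance 1e-5: the solver stops at residual 1e-9 on |dX/dt|, which
        # leaves the slow (population-difference) mode a few 1e-6 from the
        # exact equilibrium
        for pH_in in (5.0, 7.0, 9.5):
            p = symmetric_consortium(pH_in=pH_in)
            r = steady_state(p)
            x = r.state.abundances
            assert r.converged
            assert x.sum() == pytest.approx(expected_total, abs=1e-5)
            assert x[0] - x[1] == pytest.approx((7.0 - pH_in) * 0.01 / 0.04, abs=1e-5)
            assert r.state.pH_f == pytest.approx(7.0, abs=1e-5)

    def test_extreme_input_collapses(self):
        r = steady_state(symmetric_consortium(pH_in=30.0))
        assert r.converged
        np.testing.assert_array_equal(r.state.abundances, [0.0, 0.0])

    def test_nonconvergence_is_reported_not_raised(self, params):
        r = steady_state(params, t_max=0.5)
        assert not r.converged
        assert r.residual >= 1e-9


class TestScanSurface:
    def test_gamma_zero_rows_identity(self, params):
        table = scan_surface(params, gamma_grid=[0.0], pH_in_grid=np.linspace(0, 16, 33))
        np.testing.assert_array_equal(table["pH_f"].to_numpy(), table["pH_in"].to_numpy())

    def test_neutral_input_regulated(self, slice_004):
        row = slice_004[np.isclose(slice_004["pH_in"], 7.0)].iloc[0]
        assert row["pH_f"] == pytest.approx(7.0, abs=1e-9)

    def test_logistic_bounds_hold_everywhere(self, slice_004):
        total = slice_004["X_a"] + slice_004["X_b"]
        assert (slice_004[["X_a", "X_b"]] >= 0).all().all()
        assert (total <= 1.0 + 1e-9).all()

    def test_deterministic_rerun(self, params):
        grid = np.linspace(5, 9, 9)
        a = scan_surface(params, pH_in_grid=grid, gamma_grid=[0.02])
        b = scan_surface(params, pH_in_grid=grid, gamma_grid=[0.02])
        assert a.equals(b)

    def test_mirror_symmetry_of_tables(self, slice_004):
        # pH_in -> 14 - pH_in with strain swap maps steady states to steady states
        df = slice_004.set_index(np.round(slice_004["pH_in"], 6))
        for pin in np.round(np.arange(0.0, 14.01, 0.5), 6):
            a = df.loc[pin]
            b = df.loc[np.round(14.0 - pin, 6)]
            assert a["X_a"] == pytest.approx(b["X_b"], abs=1e-6)
            assert a["pH_f"] - 7.0 == pytest.approx(7.0 - b["pH_f"], abs=1e-6)


class TestHomeostaticRange:
    def test_reference_slice_covers_printed_interval(self, slice_004):
        rng = homeostatic_range(slice_004)
        assert rng is not None
        assert rng.pH_in_low <= 3.0
        assert rng.pH_in_high >= 12.0

    def test_no_regulation_without_production(self, params):
        # gamma=0: the qualifying interval is only the +/- pH_tolerance band
        # around the optimum (pH_f tracks pH_in; no widening by regulation)
        table = scan_surface(params, gamma_grid=[0.0])
        rng = homeostatic_range(table)
        assert rng is not None
        assert rng.width == pytest.approx(2 * 2.0, abs=0.2 + 1e-9)

    def test_width_monotone_in_gamma(self, params):
        gammas = [0.0, 0.01, 0.02, 0.03, 0.04, 0.05]
        table = scan_surface(params, gamma_grid=gammas)
        widths = []
        for g in gammas:
            sl = table[np.isclose(table["gamma"], g)]
            rng = homeostatic_range(sl)
            widths.append(0.0 if rng is None else rng.width)
        assert all(b >= a - 1e-9 for a, b in zip(widths, widths[1:]))

    def test_coexistence_subinterval_closed_form(self, slice_004):
        # both strains above 1e-3 exactly where |pH_opt - pH_in|*delta/gamma
        # stays below the coexistence total 0.98948
        both = slice_004[(slice_004["X_a"] > 1e-3) & (slice_004["X_b"] > 1e-3)]
        assert both["pH_in"].min() == pytest.approx(3.1, abs=0.1001)
        assert both["pH_in"].max() == pytest.approx(10.9, abs=0.1001)
        # and there pH_f is pinned at the optimum
        assert np.abs(both["pH_f"] - 7.0).max() < 1e-3

    def test_slice_without_optimum_warns_empty(self, params):
        table = scan_surface(params, gamma_grid=[0.04], pH_in_grid=np.linspace(0, 2, 5))
        with pytest.warns(UserWarning):
            assert homeostatic_range(table) is None
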