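"""Diffusion solver vs the Crank series, inverse De estimation, De surface."""

import numpy as np
import pytest

from atpex import (
    DeSurfaceCoefficients,
    GRAPE_POMACE_DE_SURFACE,
    KineticsCurve,
    ParticleSystem,
    crank_fraction,
    default_system,
    eval_de_surface,
    fit_de,
    fit_de_surface,
    solve_diffusion,
)
from atpex.diffusion import CalibrationRangeWarning
from atpex.exceptions import DegenerateDataError, DomainError, SingularDesignError


def system_with_alpha(alpha: float, r: float = 1e-3) -> ParticleSystem:
    """Bath with a prescribed capacity ratio alpha = V/(k*Vp)."""
    v = 50e-6
    vp = v / alpha
    return ParticleSystem(
        r=r, m_solid=vp * 1000.0, rho_particle=1000.0, v_solution=v, cs0=10.0
    )


class TestCrankSeries:
    def test_zero_time(self):
        assert crank_fraction(20.0, 0.0) == 0.0

    def test_exhausted_at_long_times(self):
        for alpha in (2.0, 20.0, 200.0):
            assert crank_fraction(alpha, 50.0) == pytest.approx(1.0, abs=1e-9)

    def test_infinite_bath_limit_matches_classical_series(self):
        # alpha -> inf reduces to 1 - (6/pi^2) sum n^-2 exp(-n^2 pi^2 tau)
        tau = 0.1
        classical = 1.0 - 6.0 / np.pi**2 * sum(
            np.exp(-(n**2) * np.pi**2 * tau) / n**2 for n in range(1, 8)
        )
        assert crank_fraction(1e6, tau) == pytest.approx(classical, abs=1e-6)
        assert crank_fraction(1e6, 0.1) == pytest.approx(0.7705, abs=5e-4)

    def test_monotone_in_tau(self):
        taus = np.linspace(0.0, 2.0, 50)
        for alpha in (2.0, 20.0):
            vals = [crank_fraction(alpha, t) for t in taus]
            assert np.all(np.diff(vals) >= 0.0)

    def test_input_validation(self):
        with pytest.raises(DomainError):
            crank_fraction(-1.0, 0.1)
        with pytest.raises(DomainError):
            crank_fraction(1.0, -0.1)
        with pytest.raises(DomainError):
            crank_fraction(1.0, 0.1, n_roots=5)


class TestSolverAgainstOracle:
    @pytest.mark.parametrize("alpha", [2.0, 20.0, 200.0])
    def test_extracted_fraction_matches_series(self, alpha):
        """Finite-volume solution vs the analytical series, with grid
        refinement: halving the radial step must shrink the error."""
        s = system_with_alpha(alpha)
        de = 3e-10
        taus = np.array([0.01, 0.1, 0.3, 1.0])
        times = taus * s.r**2 / de
        errs = {}
        for n in (60, 120):
            sol = solve_diffusion(s, de, times, n_radial=n)
            eq = alpha / (1.0 + alpha)
            got = sol.fractions / eq  # M_t / M_inf
            ref = np.array([crank_fraction(alpha, t) for t in taus])
            errs[n] = np.max(np.abs(got - ref) / ref)
        assert errs[120] < 1e-3
        assert errs[120] < errs[60]

    def test_short_time_alpha_twenty(self):
        s = system_with_alpha(20.0)
        de = 3e-10
        tau = 0.3
        sol = solve_diffusion(s, de, [tau * s.r**2 / de], n_radial=120)
        got = sol.fractions[-1] / (20.0 / 21.0)
        assert got == pytest.approx(crank_fraction(20.0, 0.3), rel=1e-3)


class TestSolverPhysics:
    def test_yield_zero_at_time_zero(self, system):
        sol = solve_diffusion(system, 3e-10, [0.0, 60.0, 600.0])
        assert sol.curve.yields[0] == 0.0

    def test_equilibrium_mass_balance(self, system):
        # tau > 5: the bath holds Vp/(V+Vp) of nothing left ungiven
        t_eq = 6.0 * system.r**2 / 3e-10
        sol = solve_diffusion(system, 3e-10, [t_eq])
        c_expected = (
            system.particle_volume * system.cs0
            / (system.v_solution + system.particle_volume)
        )
        assert sol.c_liquid[-1] == pytest.approx(c_expected, rel=1e-6)
        assert sol.curve.yields[-1] == pytest.approx(
            system.equilibrium_yield_mg_per_g, rel=1e-6
        )

    def test_mass_conserved_to_one_ppm_at_all_output_times(self, system, times_s):
        for de in (1.5e-10, 3e-10, 4.3e-10):
            sol = solve_diffusion(system, de, times_s)
            assert sol.mass_error_rel < 1e-6

    def test_yields_nondecreasing_and_concave_trending(self, system):
        t = np.linspace(30.0, 3600.0, 40)
        sol = solve_diffusion(system, 3e-10, t)
        dy = np.diff(sol.curve.yields)
        assert np.all(dy > -1e-9)
        # increments shrink: no interior extrema for k_interface = 1
        assert np.all(np.diff(dy) < 1e-9)

    def test_scale_consistency_in_dimensionless_time(self, system):
        # rescaling times by x and De by 1/x leaves the curve invariant
        t = np.array([150.0, 600.0, 1800.0, 3600.0])
        a = solve_diffusion(system, 3e-10, t).curve.yields
        b = solve_diffusion(system, 1.5e-10, 2.0 * t).curve.yields
        assert np.allclose(a, b, rtol=1e-6)

    def test_radial_spread_shrinks_with_time(self, system):
        """Interior content flattens as extraction proceeds: the radial
        max-minus-min strictly decreases over the 2.5/10/30/60 min
        snapshots at the 96.1 W/L, 30 degC condition."""
        de = eval_de_surface(96.1, 30.0, GRAPE_POMACE_DE_SURFACE)
        sol = solve_diffusion(system, de, np.array([2.5, 10.0, 30.0, 60.0]) * 60.0)
        spread = sol.profile.spread()
        assert np.all(np.diff(spread) < 0.0)
        assert np.all(sol.profile.values >= -1e-12)
        assert np.all(sol.profile.values <= system.cs0 * (1 + 1e-12))

    def test_invalid_inputs_rejected(self, system):
        with pytest.raises(DomainError):
            solve_diffusion(system, -1e-10, [60.0])
        with pytest.raises(DomainError):
            solve_diffusion(system, 3e-10, [60.0], n_radial=10)
        with pytest.raises(DomainError):
            solve_diffusion(system, 3e-10, [60.0, 30.0])


class TestFitDe:
    def test_noiseless_recovery_within_one_percent(self, system, times_s):
        truth = 3.0e-10
        sol = solve_diffusion(system, truth, times_s)
        fit = fit_de(sol.curve, system)
        assert fit.de == pytest.approx(truth, rel=1e-2)
        assert fit.r_squared > 0.9999
        assert not fit.at_bound

    def test_noisy_recovery_within_ten_percent(self, system, times_s):
        truth = 3.0e-10
        sol = solve_diffusion(system, truth, times_s)
        rng = np.random.default_rng(42)
        noisy = np.clip(sol.curve.yields * (1.0 + rng.normal(0, 0.03, times_s.size)), 0, None)
        fit = fit_de(KineticsCurve(times=times_s, yields=noisy), system)
        assert fit.de == pytest.approx(truth, rel=0.10)

    def test_degenerate_data_rejected(self, system, times_s):
        flat = KineticsCurve(times=times_s, yields=np.zeros_like(times_s))
        with pytest.raises(DegenerateDataError):
            fit_de(flat, system)
        with pytest.raises(DegenerateDataError):
            fit_de(KineticsCurve(times=times_s[:2], yields=[0.0, 1.0]), system)

    def test_boundary_flagged(self, system, times_s):
        sol = solve_diffusion(system, 3.0e-10, times_s)
        fit = fit_de(sol.curve, system, bounds=(1e-12, 1e-10))
        assert fit.at_bound


class TestDeSurface:
    def test_printed_coefficients_at_center_condition(self):
        got = eval_de_surface(96.1, 30.0, GRAPE_POMACE_DE_SURFACE)
        assert got == pytest.approx(3.149e-10, abs=5e-13)

    def test_zero_coefficients(self):
        zero = DeSurfaceCoefficients(0, 0, 0, 0, 0, 0)
        assert eval_de_surface(60.0, 30.0, zero) == 0.0

    def test_monotone_across_experimental_corners(self):
        lo = eval_de_surface(41.1, 20.0, GRAPE_POMACE_DE_SURFACE)
        hi = eval_de_surface(111.2, 40.0, GRAPE_POMACE_DE_SURFACE)
        assert 0.0 < lo < hi

    def test_positive_inside_calibration_box(self):
        for aed in np.linspace(41.1, 111.2, 8):
            for temp in np.linspace(20.0, 40.0, 5):
                assert eval_de_surface(aed, temp, GRAPE_POMACE_DE_SURFACE) > 0.0

    def test_warns_outside_calibration_box(self):
        with pytest.warns(CalibrationRangeWarning):
            eval_de_surface(150.0, 30.0, GRAPE_POMACE_DE_SURFACE)

    def test_noiseless_ols_recovery(self):
        grid = [(a, t) for a in (41.1, 63.5, 96.1, 111.2) for t in (20.0, 30.0, 40.0)]
        rows = [
            (a, t, eval_de_surface(a, t, GRAPE_POMACE_DE_SURFACE)) for a, t in grid
        ]
        coeffs, r2 = fit_de_surface(rows)
        assert np.all(
            np.abs(coeffs.as_array() / GRAPE_POMACE_DE_SURFACE.as_array() - 1.0) < 1e-4
        )
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_noisy_ols_keeps_high_r_squared(self):
        rng = np.random.default_rng(3)
        grid = [(a, t) for a in (41.1, 63.5, 96.1, 111.2) for t in (20.0, 30.0, 40.0)]
        rows = [
            (a, t, eval_de_surface(a, t, GRAPE_POMACE_DE_SURFACE) * (1 + rng.normal(0, 0.05)))
            for a, t in grid
        ]
        _, r2 = fit_de_surface(rows)
        assert r2 >= 0.9

    def test_singular_design_rejected(self):
        rows = [(50.0, t, 2e-10) for t in (20.0, 25.0, 30.0, 35.0, 40.0, 45.0)]
        with pytest.raises(SingularDesignError):
            fit_de_surface(rows)
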