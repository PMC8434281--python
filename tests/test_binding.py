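"""Equilibrium speciation, titration simulation and parameter recovery."""

import numpy as np
import pytest

from zincturn import refdata
from zincturn.binding import (
    BindingSystem,
    TitrationDataset,
    competition_curve,
    direct_curve,
    fit_competition,
    fit_direct,
    fit_ph_midpoint,
    simulate_titration,
    solve_competition,
    solve_single,
)
from zincturn.synthetic import make_titration


def bisection_oracle(p_total, m_total, k_d, n=2, iters=200):
    """Independent bisection on the free-peptide mass balance."""
    lo, hi = 0.0, p_total
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        comp = m_total * mid**n / (k_d**n + mid**n)
        if mid + n * comp - p_total > 0:
            hi = mid
        else:
            lo = mid
    p = 0.5 * (lo + hi)
    comp = m_total * p**n / (k_d**n + p**n)
    return n * comp / p_total


class TestSolveSingle:
    def test_no_binding_limit(self):
        res = solve_single(8e-4, 4e-4, 1e3, n=2)
        assert res.saturation("M") < 1e-6

    def test_stoichiometric_limit(self):
        res = solve_single(8e-4, 4e-4, 1e-12, n=2)
        assert res.saturation("M") == pytest.approx(1.0, abs=1e-4)

    def test_matches_bisection_oracle_at_study_conditions(self):
        y = solve_single(8.0e-4, 4.0e-4, 85e-6, n=2).saturation("M")
        oracle = bisection_oracle(8.0e-4, 4.0e-4, 85e-6)
        assert y == pytest.approx(oracle, abs=1e-10)

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p_t = 10 ** rng.uniform(-5, -2)
            m_t = 10 ** rng.uniform(-6, -2)
            k_d = 10 ** rng.uniform(-7, -3)
            res = solve_single(p_t, m_t, k_d, n=2)
            assert res.p_free + 2 * res.complexes["M"] == pytest.approx(p_t, rel=1e-9)
            assert res.m_free["M"] + res.complexes["M"] == pytest.approx(m_t, rel=1e-9)
            assert 0.0 <= res.saturation("M") <= 1.0

    def test_saturation_monotone_in_titrant(self):
        grid = np.linspace(1e-6, 2.5 * 8e-4, 60)
        y = direct_curve(8e-4, grid, 85e-6, 2)
        assert np.all(np.diff(y) > -1e-12)


class TestSolveCompetition:
    def test_symmetric_metals_give_equal_complexes(self):
        res = solve_competition(1e-3, 5e-4, 5e-4, 85e-6, k_ex=1.0)
        assert res.complexes["M1"] == pytest.approx(res.complexes["M2"], rel=1e-9)

    def test_reduces_to_single_when_m2_vanishes(self):
        a = solve_competition(1e-3, 3.5e-3, 1e-12, 85e-6, k_ex=230.4)
        b = solve_single(1e-3, 3.5e-3, 85e-6)
        assert a.saturation("M1") == pytest.approx(b.saturation("M"), rel=1e-6)

    def test_kd_identity_between_parameterizations(self):
        k_d1 = 85e-6
        k_ex = (85 / 5.6) ** 2
        res = solve_competition(1e-3, 3.5e-3, 2e-3, k_d1, k_ex)
        # K_D2 = K_D1/sqrt(K_ex) must hold exactly in the solved speciation
        k_d2 = k_d1 / np.sqrt(k_ex)
        lhs = (res.m_free["M2"] ** 0.5) * res.p_free / res.complexes["M2"] ** 0.5
        assert lhs == pytest.approx(k_d2, rel=1e-12)

    def test_displacement_matches_nested_bisection_oracle(self):
        p_t, m1, k_d1 = 1.0e-3, 3.5e-3, 85e-6
        k_ex = (85 / 5.6) ** 2
        k_d2 = k_d1 / np.sqrt(k_ex)

        def oracle(m2):
            lo, hi = 0.0, p_t
            for _ in range(200):
                p = 0.5 * (lo + hi)
                c1 = m1 * p**2 / (k_d1**2 + p**2)
                c2 = m2 * p**2 / (k_d2**2 + p**2)
                if p + 2 * (c1 + c2) - p_t > 0:
                    hi = p
                else:
                    lo = p
            p = 0.5 * (lo + hi)
            return 2 * (m1 * p**2 / (k_d1**2 + p**2)) / p_t

        for m2 in (5e-5, 5e-4, 2e-3, 6e-3):
            ours = solve_competition(p_t, m1, m2, k_d1, k_ex).saturation("M1")
            assert ours == pytest.approx(oracle(m2), abs=1e-9)
        # displacement is monotone decreasing in the competing titrant
        grid = np.linspace(5e-5, 6e-3, 40)
        y = competition_curve(p_t, m1, grid, k_d1, k_ex)
        assert np.all(np.diff(y) < 1e-12)


class TestSimulate:
    def _system(self):
        return BindingSystem(p_total=8e-4, metal_totals={"Co": 1e-4},
                             k_d={"Co": 85e-6}, n=2)

    def test_zero_noise_is_exact_solver_curve(self):
        grid = np.linspace(1e-5, 2e-3, 12)
        data = simulate_titration(self._system(), grid, noise_sd=0.0)
        assert np.allclose(data.observed, direct_curve(8e-4, grid, 85e-6, 2))

    def test_seed_reproducibility(self):
        grid = np.linspace(1e-5, 2e-3, 12)
        a = simulate_titration(self._system(), grid, noise_sd=0.02, seed=5)
        b = simulate_titration(self._system(), grid, noise_sd=0.02, seed=5)
        assert np.array_equal(a.observed, b.observed)

    def test_noise_magnitude(self):
        grid = np.linspace(1e-5, 2e-3, 10)
        clean = direct_curve(8e-4, grid, 85e-6, 2)
        resid = []
        for seed in range(100):
            d = simulate_titration(self._system(), grid, noise_sd=0.02, seed=seed)
            resid.extend(d.observed - clean)
        assert np.std(resid) == pytest.approx(0.02, rel=0.15)


class TestFits:
    def test_direct_noiseless_exact_recovery(self):
        data = make_titration("direct", noise_sd=0.0)
        fit = fit_direct(data)
        assert fit.k_d == pytest.approx(85e-6, rel=1e-5)
        assert fit.n == pytest.approx(2.0, abs=1e-3)

    def test_wrong_stoichiometry_fits_worse(self):
        data = make_titration("direct", noise_sd=0.0)
        good = fit_direct(data, fit_n=False, n0=2.0)
        bad = fit_direct(data, fit_n=False, n0=1.0)
        assert bad.rss > 10 * good.rss

    def test_direct_recovery_under_noise(self):
        data = make_titration("direct", noise_sd=0.02, seed=42)
        fit = fit_direct(data)
        assert abs(fit.k_d - 85e-6) / 85e-6 < 0.10
        assert round(fit.n) == 2

    def test_median_recovery_error_over_replicates(self):
        errors = []
        for seed in range(200):
            data = make_titration("direct", noise_sd=0.02, seed=seed)
            fit = fit_direct(data, fit_n=False, n0=2.0)
            errors.append(abs(fit.k_d - 85e-6) / 85e-6)
        assert np.median(errors) < 0.05

    def test_competition_noiseless_exact_recovery(self):
        data = make_titration("competition", noise_sd=0.0)
        fit = fit_competition(data, k_d1=85e-6)
        assert fit.k_ex == pytest.approx(refdata.BINDING.k_ex_zn, rel=1e-5)
        assert fit.k_d_derived == pytest.approx(5.6e-6, rel=1e-5)

    def test_competition_recovery_zn(self):
        data = make_titration("competition", noise_sd=0.02, seed=7)
        fit = fit_competition(data, k_d1=85e-6)
        assert abs(fit.k_d_derived - 5.6e-6) / 5.6e-6 < 0.10

    def test_competition_recovery_cd(self):
        data = make_titration("competition", noise_sd=0.02, seed=7, k_d2=5.0e-6)
        fit = fit_competition(data, k_d1=85e-6)
        assert abs(fit.k_d_derived - 5.0e-6) / 5.0e-6 < 0.10


class TestPhMidpoint:
    def test_noiseless_recovery(self):
        data = make_titration("ph", noise_sd=0.0)
        mid, se = fit_ph_midpoint(data.titrant_totals, data.observed)
        assert mid == pytest.approx(7.1, abs=1e-6)

    def test_sign_agnostic(self):
        data = make_titration("ph", noise_sd=0.0, low=1.0, high=0.0)
        mid, _ = fit_ph_midpoint(data.titrant_totals, data.observed)
        assert mid == pytest.approx(7.1, abs=1e-6)

    def test_noisy_recovery_within_tenth_of_unit(self):
        data = make_titration("ph", noise_sd=0.02, seed=3)
        mid, _ = fit_ph_midpoint(data.titrant_totals, data.observed)
        assert mid == pytest.approx(7.1, abs=0.1)

    def test_requires_enough_points(self):
        with pytest.raises(ValueError):
            fit_ph_midpoint(np.array([6, 7, 8]), np.array([0, 0.5, 1.0]))


def test_titrant_totals_must_increase():
    with pytest.raises(ValueError):
        TitrationDataset(p_total=1e-3, titrant_totals=np.array([1e-4, 1e-4]),
                         observed=np.array([0.1, 0.2]))
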