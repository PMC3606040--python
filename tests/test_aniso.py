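"""Exponential and polynomial anisotropic scale models and their fits."""

import numpy as np
import pytest
from scipy.optimize import minimize

from conftest import make_reflections
from solvscale.aniso import (
    fit_exponential_aniso,
    fit_exponential_aniso_minimized,
    fit_polynomial_aniso,
    k_aniso_exponential,
    k_aniso_polynomial,
)
from solvscale.reflection_model import (
    ReflectionSet,
    UnitCell,
    derive_constraint_matrix,
    point_group_rotations,
)

TWO_PI_SQ = 2 * np.pi**2


@pytest.fixture(scope="module")
def triclinic():
    return make_reflections(60, seed=3)


@pytest.fixture(scope="module")
def identity_constraint():
    return derive_constraint_matrix(np.eye(3, dtype=int)[None])


class TestEvaluation:
    def test_zero_tensor_gives_ones(self, triclinic):
        np.testing.assert_array_equal(
            k_aniso_exponential(np.zeros(6), triclinic.indices), 1.0
        )

    def test_f000_is_one(self):
        u = np.array([0.1, 0.2, -0.05, 0.01, 0.0, 0.02])
        assert k_aniso_exponential(u, np.array([[0, 0, 0]]))[0] == 1.0

    def test_cubic_direct_evaluation(self):
        # a = 1 Å cubic cell, U = 0.01 I, (1,1,1): exp(-2π²·0.03)
        u = np.array([0.01, 0.01, 0.01, 0, 0, 0])
        val = k_aniso_exponential(u, np.array([[1, 1, 1]]))[0]
        assert val == pytest.approx(np.exp(-TWO_PI_SQ * 0.03), rel=1e-12)
        assert val == pytest.approx(0.5531, abs=5e-5)

    def test_polynomial_zero_coeffs_and_f000(self):
        refl = ReflectionSet(np.array([[0, 0, 0], [1, 2, 3]]), UnitCell(10, 10, 10))
        vals = k_aniso_polynomial(np.zeros(6), np.zeros(6), refl)
        np.testing.assert_array_equal(vals, 1.0)
        v0 = np.arange(1.0, 7.0)
        assert k_aniso_polynomial(v0, v0, refl)[0] == 1.0  # F000 stays 1

    def test_polynomial_taylor_matches_exponential_at_small_s(self):
        # cubic cell: sᵗUs = u·s² for U = u·I, so both Taylor orders are
        # representable; error must shrink like the cube of 2π² sᵗUs
        cell = UnitCell(1, 1, 1)
        u_iso = 1e-3
        u6 = u_iso * np.array([1.0, 1, 1, 0, 0, 0])
        v0 = -TWO_PI_SQ * u6
        v1 = (TWO_PI_SQ * u_iso) ** 2 / 2.0 * np.array([1.0, 1, 1, 0, 0, 0])
        prev_err = None
        for hkl in ([3, 0, 0], [2, 0, 0], [1, 0, 0]):
            refl = ReflectionSet(np.array([hkl]), cell)
            exact = k_aniso_exponential(u6, refl.indices)[0]
            poly = k_aniso_polynomial(v0, v1, refl)[0]
            x = TWO_PI_SQ * u_iso * refl.s_squared[0]
            assert abs(poly - exact) < x**3  # remainder bound
            if prev_err is not None:
                assert abs(poly - exact) < prev_err
            prev_err = abs(poly - exact)


class TestExponentialFit:
    def test_exact_data_gives_zero_tensor(self, triclinic, identity_constraint):
        amp = np.abs(np.random.default_rng(0).standard_normal(len(triclinic))) + 0.5
        model = fit_exponential_aniso(amp, amp, triclinic, identity_constraint)
        np.testing.assert_allclose(model.u_cryst, 0.0, atol=1e-12)

    def test_noiseless_tetragonal_recovery(self):
        cell = UnitCell(40, 40, 60)
        refl = make_reflections(200, cell=cell, symbol="P 4/m m m", seed=11)
        c = derive_constraint_matrix(refl.rotations)
        u_true = c.rows.T @ np.array([4e-4, -2.5e-4])
        base = np.abs(np.random.default_rng(1).standard_normal(len(refl))) + 0.5
        f_obs = k_aniso_exponential(u_true, refl.indices) * base
        model = fit_exponential_aniso(f_obs, base, refl, c)
        np.testing.assert_allclose(model.u_cryst, u_true, rtol=1e-8)

    def test_matches_nonlinear_minimizer_on_log_residual(self, triclinic,
                                                         identity_constraint):
        rng = np.random.default_rng(7)
        n = 50
        refl = make_reflections(n, seed=9)
        base = np.abs(rng.standard_normal(n)) + 0.5
        f_obs = base * np.exp(rng.normal(0, 0.2, n))
        fitted = fit_exponential_aniso(f_obs, base, refl, identity_constraint)
        v = np.column_stack([
            refl.indices[:, 0] ** 2, refl.indices[:, 1] ** 2,
            refl.indices[:, 2] ** 2,
            2 * refl.indices[:, 0] * refl.indices[:, 1],
            2 * refl.indices[:, 0] * refl.indices[:, 2],
            2 * refl.indices[:, 1] * refl.indices[:, 2],
        ]).astype(float)

        def log_residual(u6):
            k = np.exp(-TWO_PI_SQ * (v @ u6))
            return np.sum((np.log(f_obs) - np.log(k * base)) ** 2)

        res = minimize(log_residual, np.zeros(6), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 40000})
        np.testing.assert_allclose(fitted.u_cryst, res.x, atol=1e-6)

    def test_nonpositive_reflections_excluded_and_counted(self, identity_constraint):
        refl = make_reflections(30, seed=2)
        base = np.ones(30)
        f_obs = np.ones(30)
        f_obs[:3] = 0.0
        model = fit_exponential_aniso(f_obs, base, refl, identity_constraint)
        assert model.n_excluded == 3

    def test_reindexing_invariance_under_point_group(self):
        # permuting reflections by a point-group rotation must not change the fit
        cell = UnitCell(40, 40, 60)
        refl = make_reflections(150, cell=cell, symbol="P 4/m m m", seed=21)
        c = derive_constraint_matrix(refl.rotations)
        rng = np.random.default_rng(3)
        base = np.abs(rng.standard_normal(len(refl))) + 0.5
        f_obs = base * np.exp(rng.normal(0, 0.1, len(refl)))
        u_a = fit_exponential_aniso(f_obs, base, refl, c).u_cryst
        rot = refl.rotations[1]
        refl_b = ReflectionSet(refl.indices @ rot.T, cell, refl.rotations)
        u_b = fit_exponential_aniso(f_obs, base, refl_b, c).u_cryst
        np.testing.assert_allclose(u_a, u_b, atol=1e-10)


class TestPolynomialFit:
    def test_exact_data_gives_zero_coefficients(self, triclinic):
        amp = np.abs(np.random.default_rng(0).standard_normal(len(triclinic))) + 0.5
        model = fit_polynomial_aniso(amp, amp, triclinic)
        np.testing.assert_allclose(model.v0, 0.0, atol=1e-9)
        np.testing.assert_allclose(model.v1, 0.0, atol=1e-9)

    def test_noiseless_recovery_is_exact(self):
        refl = make_reflections(100, seed=13)
        rng = np.random.default_rng(4)
        v0 = rng.normal(0, 1e-3, 6)
        v1 = rng.normal(0, 1e-4, 6)
        base = np.abs(rng.standard_normal(100)) + 0.5
        f_obs = k_aniso_polynomial(v0, v1, refl) * base
        model = fit_polynomial_aniso(f_obs, base, refl)
        np.testing.assert_allclose(model.v0, v0, atol=1e-8)
        np.testing.assert_allclose(model.v1, v1, atol=1e-8)

    def test_matches_explicit_normal_equations(self):
        refl = make_reflections(30, seed=17)
        rng = np.random.default_rng(5)
        base = np.abs(rng.standard_normal(30)) + 0.5
        f_obs = base * (1 + rng.normal(0, 0.1, 30))
        model = fit_polynomial_aniso(f_obs, base, refl)
        # brute-force normal equations assembled by explicit summation
        h, k, l = refl.indices.T.astype(float)
        v = np.column_stack([h * h, k * k, l * l, 2 * h * k, 2 * h * l, 2 * k * l])
        s2 = refl.s_squared
        cols = [base * v[:, j] for j in range(6)]
        cols += [base * s2 * v[:, j] for j in range(6)]
        m = np.zeros((12, 12))
        b = np.zeros(12)
        for i in range(12):
            b[i] = np.sum(cols[i] * (f_obs - base))
            for j in range(12):
                m[i, j] = np.sum(cols[i] * cols[j])
        expected = np.linalg.solve(m, b)
        np.testing.assert_allclose(
            np.concatenate([model.v0, model.v1]), expected, atol=1e-8
        )


class TestMinimizedExponential:
    def test_noiseless_equals_analytic(self):
        cell = UnitCell(40, 40, 60)
        refl = make_reflections(150, cell=cell, symbol="P 4/m m m", seed=23)
        c = derive_constraint_matrix(refl.rotations)
        u_true = c.rows.T @ np.array([3e-4, -1e-4])
        base = np.abs(np.random.default_rng(6).standard_normal(len(refl))) + 0.5
        f_obs = k_aniso_exponential(u_true, refl.indices) * base
        analytic = fit_exponential_aniso(f_obs, base, refl, c)
        minimized = fit_exponential_aniso_minimized(f_obs, base, refl, c)
        np.testing.assert_allclose(minimized.u_cryst, analytic.u_cryst, atol=1e-7)

    def test_never_worse_than_analytic_on_amplitude_residual(self):
        cell = UnitCell(40, 40, 60)
        refl = make_reflections(200, cell=cell, symbol="P 4/m m m", seed=29)
        c = derive_constraint_matrix(refl.rotations)
        rng = np.random.default_rng(8)
        base = np.abs(rng.standard_normal(len(refl))) + 0.2
        # heteroscedastic noise separates the two targets' minima
        f_obs = base * np.exp(rng.normal(0, 0.4, len(refl))) * (
            1 + 0.5 * rng.random(len(refl))
        )

        def amp_residual(u6):
            k = k_aniso_exponential(u6, refl.indices)
            return np.sum((f_obs - k * base) ** 2)

        analytic = fit_exponential_aniso(f_obs, base, refl, c)
        minimized = fit_exponential_aniso_minimized(f_obs, base, refl, c)
        assert amp_residual(minimized.u_cryst) <= amp_residual(analytic.u_cryst) + 1e-9

    def test_log_and_amplitude_minima_differ_on_noisy_data(self):
        # the two residuals have distinct minima once noise is asymmetric
        refl = make_reflections(200, seed=31)
        c = derive_constraint_matrix(np.eye(3, dtype=int)[None])
        rng = np.random.default_rng(9)
        base = np.abs(rng.standard_normal(len(refl))) + 0.2
        f_obs = base * np.exp(rng.normal(0, 0.5, len(refl)))

        def amp_residual(u6):
            k = k_aniso_exponential(u6, refl.indices)
            return np.sum((f_obs - k * base) ** 2)

        analytic = fit_exponential_aniso(f_obs, base, refl, c)
        minimized = fit_exponential_aniso_minimized(f_obs, base, refl, c)
        assert amp_residual(minimized.u_cryst) < amp_residual(analytic.u_cryst)
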