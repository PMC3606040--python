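"""Twin-fraction estimation and twinned scale determination."""

import numpy as np
import pytest

from conftest import random_bin
from solvscale import SimulationSpec, UnitCell, simulate
from solvscale.solvent import bin_moments, ls_bin_residual, solve_bin_scales
from solvscale.twinning import (
    TwinIntensities,
    TwinModel,
    estimate_twin_fractions,
    iterate_twin_scaling,
    parse_twin_operator,
    solve_twin_bin_scales,
    twin_total_intensity,
)

TWO_DOMAIN = np.array([np.eye(3, dtype=int),
                       parse_twin_operator("k,h,-l")])


class TestOperatorParsing:
    def test_inversion_law(self):
        np.testing.assert_array_equal(
            parse_twin_operator("-h,-k,l"), np.diag([-1, -1, 1])
        )

    def test_exchange_law(self):
        t = parse_twin_operator("k,h,-l")
        np.testing.assert_array_equal(
            t, np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]])
        )

    def test_invalid_law_raises(self):
        with pytest.raises(ValueError):
            parse_twin_operator("h,k")
        with pytest.raises(ValueError):
            parse_twin_operator("h,q,l")


class TestTotalIntensity:
    def test_single_domain_identity(self, rng):
        i1 = rng.random(10)
        model = TwinModel(np.eye(3, dtype=int)[None], fractions=np.array([1.0]))
        out = twin_total_intensity(model, TwinIntensities(i1[None], i1))
        np.testing.assert_array_equal(out, i1)

    def test_equal_fractions_equal_intensities(self, rng):
        i1 = rng.random(10)
        model = TwinModel(TWO_DOMAIN, fractions=np.array([0.5, 0.5]))
        out = twin_total_intensity(model, TwinIntensities(np.vstack([i1, i1]), i1))
        np.testing.assert_allclose(out, i1)

    def test_weighted_mean(self):
        model = TwinModel(TWO_DOMAIN, fractions=np.array([0.7, 0.3]))
        ti = TwinIntensities(np.array([[10.0], [20.0]]), np.array([13.0]))
        assert twin_total_intensity(model, ti)[0] == pytest.approx(13.0)


class TestFractionEstimation:
    def test_single_domain_is_unity(self, rng):
        ti = TwinIntensities(rng.random((1, 30)), rng.random(30))
        model = estimate_twin_fractions(ti)
        np.testing.assert_array_equal(model.fractions, [1.0])

    def test_noiseless_recovery(self, rng):
        i1, i2 = rng.random(200) * 10, rng.random(200) * 10
        ti = TwinIntensities(np.vstack([i1, i2]), 0.7 * i1 + 0.3 * i2)
        model = estimate_twin_fractions(ti)
        np.testing.assert_allclose(model.fractions, [0.7, 0.3], atol=1e-8)

    def test_matches_brute_force_scan(self, rng):
        i1, i2 = rng.random(30) * 10, rng.random(30) * 10
        iobs = (0.6 * i1 + 0.4 * i2) * (1 + 0.05 * rng.standard_normal(30))
        model = estimate_twin_fractions(TwinIntensities(np.vstack([i1, i2]), iobs))
        # constraint eliminated by substitution α₂ = 1 − α₁
        alphas = np.arange(-0.5, 1.5, 1e-4)
        ls = [(np.sum((iobs - a * i1 - (1 - a) * i2) ** 2), a) for a in alphas]
        best_alpha = min(ls)[1]
        assert model.fractions[0] == pytest.approx(best_alpha, abs=2e-4)

    def test_constraint_always_exact(self, rng):
        for n_dom in (2, 3, 4):
            im = rng.random((n_dom, 50)) * 5
            iobs = rng.random(50) * 5
            model = estimate_twin_fractions(TwinIntensities(im, iobs))
            assert abs(model.fractions.sum() - 1.0) < 1e-12

    def test_exchange_symmetry(self, rng):
        i1, i2 = rng.random(100), rng.random(100)
        iobs = 0.65 * i1 + 0.35 * i2
        a = estimate_twin_fractions(TwinIntensities(np.vstack([i1, i2]), iobs))
        b = estimate_twin_fractions(TwinIntensities(np.vstack([i2, i1]), iobs))
        np.testing.assert_allclose(a.fractions, b.fractions[::-1], atol=1e-10)

    def test_identical_domains_warn_but_solve(self, rng, caplog):
        i1 = rng.random(40)
        ti = TwinIntensities(np.vstack([i1, i1]), i1)
        model = estimate_twin_fractions(ti)
        assert abs(model.fractions.sum() - 1.0) < 1e-10


class TestTwinnedBinScales:
    def test_n1_bitwise_reduction(self, rng):
        fo, fc, fm = random_bin(rng, n=50, k_mask=0.3, noise=0.1)
        m = bin_moments(fc, fm, fo)
        a = solve_bin_scales(m)
        b = solve_twin_bin_scales([m], np.array([1.0]))
        assert a[0] == b[0] and a[1] == b[1]  # bit-identical

    def test_noiseless_twinned_recovery(self, rng):
        n = 80
        fc1 = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        fm1 = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        fc2 = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        fm2 = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        i_tot = 0.6 * np.abs(fc1 + 0.3 * fm1) ** 2 + 0.4 * np.abs(fc2 + 0.3 * fm2) ** 2
        fo = np.sqrt(i_tot)
        mlist = [bin_moments(fc1, fm1, fo), bin_moments(fc2, fm2, fo)]
        k_big, k_mask, _ = solve_twin_bin_scales(mlist, np.array([0.6, 0.4]))
        assert k_mask == pytest.approx(0.3, abs=1e-8)
        assert k_big == pytest.approx(1.0, abs=1e-8)

    def test_beats_grid_on_twinned_residual(self, rng):
        n = 50
        for _ in range(5):
            fc1 = rng.standard_normal(n) + 1j * rng.standard_normal(n)
            fm1 = rng.standard_normal(n) + 1j * rng.standard_normal(n)
            fc2 = rng.standard_normal(n) + 1j * rng.standard_normal(n)
            fm2 = rng.standard_normal(n) + 1j * rng.standard_normal(n)
            km_true = rng.uniform(0, 0.6)
            i_tot = 0.55 * np.abs(fc1 + km_true * fm1) ** 2 + 0.45 * np.abs(
                fc2 + km_true * fm2
            ) ** 2
            fo = np.sqrt(i_tot) * (1 + 0.1 * rng.standard_normal(n))
            mlist = [bin_moments(fc1, fm1, fo), bin_moments(fc2, fm2, fo)]
            frac = np.array([0.55, 0.45])
            k_big, k_mask, diag = solve_twin_bin_scales(mlist, frac)
            # grid over the α-weighted residual
            u = 0.55 * mlist[0].u + 0.45 * mlist[1].u
            v = 0.55 * mlist[0].v + 0.45 * mlist[1].v
            w = 0.55 * mlist[0].w + 0.45 * mlist[1].w
            from solvscale.solvent import BinMoments

            mbar = BinMoments(u, v, w, mlist[0].i_obs)
            grid = min(
                ls_bin_residual(mbar, a, b)
                for a in np.linspace(1e-3, 4, 400)
                for b in np.linspace(0, 1.5, 400)
            )
            assert diag["ls"] <= grid + 1e-9 * (1 + grid)


def twinned_dataset(fractions, noise=0.0, n=5000, seed=0):
    spec = SimulationSpec(
        cell=UnitCell(50.0, 50.0, 70.0),
        spacegroup="P 1",
        d_min=2.2,
        d_max=35.0,
        n_reflections=n,
        twin_operators=TWO_DOMAIN,
        twin_fractions=np.asarray(fractions, float),
        noise=noise,
        seed=seed,
    )
    return simulate(spec)


class TestIterateTwinScaling:
    def test_spurious_operator_fraction_vanishes(self):
        f_obs, f_calc, f_mask, refl, _ = twinned_dataset([1.0, 0.0], n=4000, seed=2)
        model, _scales = iterate_twin_scaling(
            f_obs, f_calc, f_mask, refl, TWO_DOMAIN, min_count=250
        )
        assert model.fractions[1] == pytest.approx(0.0, abs=1e-3)
        assert model.fractions[0] == pytest.approx(1.0, abs=1e-3)

    def test_joint_recovery_noiseless(self):
        f_obs, f_calc, f_mask, refl, truth = twinned_dataset(
            [0.55, 0.45], n=5000, seed=3
        )
        model, scales = iterate_twin_scaling(
            f_obs, f_calc, f_mask, refl, TWO_DOMAIN, min_count=250
        )
        np.testing.assert_allclose(model.fractions, [0.55, 0.45], atol=1e-2)
        # per-bin estimates match the generating curve where they are
        # determined (bin centers); the piecewise-linear spread stays close
        spec = truth["spec"]
        truth_at_centers = spec.k_sol * np.exp(
            -spec.b_sol * scales.bin_centers_s2 / 4.0
        )
        np.testing.assert_allclose(
            scales.k_mask_bins_smoothed, truth_at_centers, atol=1e-2
        )
        np.testing.assert_allclose(scales.k_mask, truth["k_mask"], atol=0.05)

    def test_iteration_cap_one_is_single_round(self):
        f_obs, f_calc, f_mask, refl, _ = twinned_dataset([0.6, 0.4], n=3000, seed=4)
        m1, s1 = iterate_twin_scaling(
            f_obs, f_calc, f_mask, refl, TWO_DOMAIN, max_iter=1, min_count=250
        )
        # one round = estimate fractions at unit scales, then one scale pass
        i1 = np.abs(f_calc) ** 2
        assert m1.fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert s1.k_mask is not None

    def test_fractions_always_in_range_and_normalised(self):
        for seed in (5, 6):
            f_obs, f_calc, f_mask, refl, _ = twinned_dataset(
                [0.8, 0.2], noise=0.05, n=3000, seed=seed
            )
            model, _ = iterate_twin_scaling(
                f_obs, f_calc, f_mask, refl, TWO_DOMAIN, min_count=250
            )
            assert np.all(model.fractions >= 0.0)
            assert np.all(model.fractions <= 1.0)
            assert model.fractions.sum() == pytest.approx(1.0, abs=1e-9)
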