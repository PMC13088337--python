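"""MBAR free energies, PMF projection, dihedral PCA, and barriers."""

import numpy as np
import pytest
from scipy.integrate import quad

from etkit.constants import KB_KCAL
from etkit.pmf import (
    BiasModel,
    CollectiveVariable,
    FreeEnergyProfile,
    MBARResult,
    UmbrellaWindow,
    apply_burn_in,
    classify_conformation,
    extract_barrier,
    fit_dihedral_pca,
    generate_window_centers,
    project_pmf,
    solve_mbar,
)
from etkit.synthetic import AnalyticPotential, SamplerSpec, sample_umbrella_windows

KBT300 = KB_KCAL * 300.0


class TestWindowCenters:
    def test_unit_example(self):
        np.testing.assert_allclose(generate_window_centers(0, 1, 1), [0, 1])

    def test_endpoints_inclusive(self):
        c = generate_window_centers(14.1, 23.1, 0.2)
        assert c[0] == pytest.approx(14.1)
        assert c[-1] == pytest.approx(23.1)
        np.testing.assert_allclose(np.diff(c), 0.2)

    def test_non_commensurate_rejected(self):
        with pytest.raises(ValueError, match="commensurate"):
            generate_window_centers(0.0, 1.0, 0.3)


class TestBurnIn:
    def test_fraction_discard(self):
        w = UmbrellaWindow(0, 0.0, 1.0, np.arange(100.0))
        (out,) = apply_burn_in([w], 0.15)
        assert out.rc_samples.size == 85
        assert out.rc_samples[0] == 15.0
        assert out.n_discarded == 15

    def test_zero_fraction_identity(self):
        w = UmbrellaWindow(0, 0.0, 1.0, np.arange(10.0))
        (out,) = apply_burn_in([w], 0.0)
        np.testing.assert_array_equal(out.rc_samples, w.rc_samples)

    def test_ceiling_rule(self):
        w = UmbrellaWindow(0, 0.0, 1.0, np.arange(10.0))
        (out,) = apply_burn_in([w], 0.15)
        assert out.rc_samples.size == 8  # ceil(1.5) = 2 dropped

    def test_emptied_window_rejected(self):
        w = UmbrellaWindow(3, 0.0, 1.0, np.array([1.0]))
        with pytest.raises(ValueError, match="window 3"):
            apply_burn_in([w], 0.9)


def quadrature_free_energies(potential, windows, bias):
    """Independent oracle: f_k from 1-D quadrature of the biased partition
    functions, relative to the first window."""
    beta = bias.beta
    out = []
    for w in windows:
        pref = w.force_constant if bias.convention == "k_full" else 0.5 * w.force_constant

        def integrand(x, c=w.bias_center, p=pref):
            return np.exp(-beta * (potential.energy(x) + p * (x - c) ** 2))

        z, _ = quad(integrand, -30, 30, limit=200)
        out.append(-np.log(z) / beta)
    out = np.array(out)
    return out - out[0]


class TestSolveMBAR:
    def test_single_unbiased_window(self):
        w = UmbrellaWindow(0, 0.0, 0.0, np.random.default_rng(0).normal(size=50))
        res = solve_mbar([w])
        assert res.converged
        np.testing.assert_allclose(res.free_energies, [0.0])
        np.testing.assert_allclose(res.sample_weights, np.full(50, 1 / 50), atol=1e-12)

    def test_identical_windows_symmetric(self):
        samples = np.random.default_rng(1).normal(size=200)
        w1 = UmbrellaWindow(0, 0.0, 5.0, samples)
        w2 = UmbrellaWindow(1, 0.0, 5.0, samples.copy())
        res = solve_mbar([w1, w2])
        assert res.free_energies[1] == pytest.approx(0.0, abs=1e-9)

    def test_harmonic_windows_match_quadrature(self):
        pot = AnalyticPotential("harmonic", kappa=2.0)
        centers = tuple(np.linspace(-1.2, 1.2, 9))
        spec = SamplerSpec(
            potential=pot, centers=centers, force_constant=10.0,
            n_samples=2000, seed=7,
        )
        windows, _ = sample_umbrella_windows(spec)
        bias = BiasModel()
        res = solve_mbar(windows, bias)
        assert res.converged
        oracle = quadrature_free_energies(pot, windows, bias)
        # agreement within the estimator's own asymptotic statistical error
        err = np.abs(res.free_energies - oracle)[1:]
        se = res.free_energy_se()[1:]
        assert np.all(err <= 4 * se)

    def test_free_energies_stable_under_sample_doubling(self):
        pot = AnalyticPotential("harmonic", kappa=2.0)
        centers = tuple(np.linspace(-1.2, 1.2, 9))
        results = {}
        for n in (2000, 4000):
            spec = SamplerSpec(
                potential=pot, centers=centers, force_constant=10.0,
                n_samples=n, seed=7,
            )
            windows, _ = sample_umbrella_windows(spec)
            results[n] = solve_mbar(windows)
        diff = np.abs(results[2000].free_energies - results[4000].free_energies)[1:]
        se = results[2000].free_energy_se()[1:]
        assert np.all(diff <= 2 * se)

    def test_weights_positive_and_normalized(self):
        pot = AnalyticPotential("harmonic", kappa=1.0)
        spec = SamplerSpec(
            potential=pot, centers=(-0.5, 0.0, 0.5), force_constant=5.0,
            n_samples=500, seed=2,
        )
        windows, _ = sample_umbrella_windows(spec)
        res = solve_mbar(windows)
        w = res.sample_weights
        assert np.all(w > 0)
        assert abs(w.sum() - 1.0) < 1e-10

    def test_half_convention_equivalence(self):
        """U = k(x-c)^2 under k_full equals U = (2k)/2 (x-c)^2 under k_half."""
        samples = np.random.default_rng(3).normal(0.3, 0.4, size=400)
        w_full = [
            UmbrellaWindow(0, 0.0, 5.0, samples),
            UmbrellaWindow(1, 0.5, 5.0, samples + 0.2),
        ]
        w_half = [
            UmbrellaWindow(0, 0.0, 10.0, samples),
            UmbrellaWindow(1, 0.5, 10.0, samples + 0.2),
        ]
        res_full = solve_mbar(w_full, BiasModel(convention="k_full"))
        res_half = solve_mbar(w_half, BiasModel(convention="k_half"))
        np.testing.assert_allclose(
            res_full.free_energies, res_half.free_energies, atol=1e-8
        )
        np.testing.assert_allclose(res_full.log_weights, res_half.log_weights, atol=1e-8)

    def test_nan_energies_rejected(self):
        w = UmbrellaWindow(0, 0.0, 1.0, np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            solve_mbar([w])


class TestHarmonicRecovery:
    def test_pmf_matches_planted_harmonic(self):
        """Planted U = κx²/2; umbrella windows spanning ±3σ must reproduce
        the quadratic PMF within 0.2 kcal/mol over the sampled range."""
        kappa = 2.0
        sigma = np.sqrt(KBT300 / kappa)
        pot = AnalyticPotential("harmonic", kappa=kappa)
        centers = tuple(np.linspace(-3 * sigma, 3 * sigma, 13))
        spec = SamplerSpec(
            potential=pot, centers=centers, force_constant=5.0,
            n_samples=5000, seed=21,
        )
        windows, _ = sample_umbrella_windows(spec)
        res = solve_mbar(windows)
        x = np.concatenate([w.rc_samples for w in windows])
        prof = project_pmf(res, None, x, n_bins=40)
        ok = ~prof.empty_bin_mask & (prof.bin_counts > 1e-4)
        expected = 0.5 * kappa * prof.bin_centers[ok] ** 2
        expected = expected - expected.min()
        dev = np.abs(prof.F[ok] - expected)
        assert dev.max() < 0.2


class TestDihedralPCA:
    def test_zero_variance_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="variance"):
            fit_dihedral_pca(X)

    def test_single_varying_dihedral_supports_pc1(self):
        rng = np.random.default_rng(4)
        X = np.zeros((500, 4))
        X[:, 2] = rng.normal(0.0, 0.5, size=500)
        model = fit_dihedral_pca(X)
        # loadings live on the (cos, sin) pair of dihedral 2 only, and the
        # covariance is rank <= 2 by construction
        pc1 = model.components[0]
        on = np.abs(pc1[[2, 6]]).sum()
        off = np.abs(np.delete(pc1, [2, 6])).sum()
        assert on > 0.999
        assert off < 1e-6
        total = model.explained_variance.sum()
        assert model.explained_variance[:2].sum() == pytest.approx(total, rel=1e-9)
        assert np.all(model.explained_variance[2:] < 1e-12 * total)

    def test_two_modes_variance_ratio(self):
        rng = np.random.default_rng(8)
        n = 20000
        X = np.zeros((n, 2))
        X[:, 0] = 0.05 * 2.0 * rng.standard_normal(n)  # sd ratio 2 -> var 4
        X[:, 1] = np.pi / 2 + 0.05 * rng.standard_normal(n)
        model = fit_dihedral_pca(X)
        ratio = model.explained_variance[0] / model.explained_variance[1]
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_components_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(300, 3))
        model = fit_dihedral_pca(X)
        G = model.components @ model.components.T
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)
        for row in model.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_invariant_under_sample_relabeling(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(200, 3))
        m1 = fit_dihedral_pca(X)
        m2 = fit_dihedral_pca(X[rng.permutation(200)])
        np.testing.assert_allclose(m1.components, m2.components, atol=1e-8)
        np.testing.assert_allclose(
            m1.explained_variance, m2.explained_variance, atol=1e-10
        )


def uniform_mbar(n, temperature=300.0):
    """Uniform-weight MBARResult stand-in for projection-only tests."""
    return MBARResult(
        free_energies=np.array([0.0]),
        log_weights=np.full(n, -np.log(n)),
        n_retained_per_window=np.array([n]),
        converged=True,
        final_residual=0.0,
        bias=BiasModel(temperature=temperature),
    )


class TestProjectPMF:
    def test_boltzmann_inversion_of_standard_normal(self):
        rng = np.random.default_rng(30)
        s = rng.standard_normal(200_000)
        prof = project_pmf(uniform_mbar(s.size), None, s, n_bins=60)
        ok = ~prof.empty_bin_mask & (np.abs(prof.bin_centers) <= 2.0)
        x = prof.bin_centers[ok]
        y = prof.F[ok]
        # F(s) = kBT s^2/2 + const
        design = np.vstack([x**2, np.ones_like(x)]).T
        coef, res_, *_ = np.linalg.lstsq(design, y, rcond=None)
        pred = design @ coef
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99
        assert coef[0] == pytest.approx(KBT300 / 2, rel=0.1)

    def test_single_sample_weight_masks_other_bins(self):
        res = MBARResult(
            free_energies=np.array([0.0]),
            log_weights=np.array([0.0, -800.0, -800.0]),
            n_retained_per_window=np.array([3]),
            converged=True,
            final_residual=0.0,
        )
        prof = project_pmf(res, None, np.array([0.0, 5.0, 10.0]), bin_edges=np.array([-1, 1, 6, 11.0]))
        assert prof.F[0] == pytest.approx(0.0, abs=1e-12)

    def test_collective_variable_evaluator_applied(self):
        s = np.linspace(-1, 1, 1000)
        cv = CollectiveVariable("abs", evaluator=np.abs)
        prof = project_pmf(uniform_mbar(s.size), cv, s, n_bins=10)
        assert prof.bin_centers.min() >= 0

    def test_all_samples_one_bin_warns(self):
        prof = project_pmf(uniform_mbar(5), None, np.zeros(5))
        assert prof.single_bin_warning


class TestExtractBarrier:
    def test_simple_profile(self):
        prof = FreeEnergyProfile(
            bin_centers=np.array([0.0, 1.0, 2.0]),
            F=np.array([0.0, 5.0, 1.0]),
            bin_counts=np.ones(3),
            empty_bin_mask=np.zeros(3, bool),
        )
        barrier, dab = extract_barrier(prof, (-0.5, 0.5), (1.5, 2.5))
        assert barrier == pytest.approx(5.0)
        assert dab == pytest.approx(1.0)

    def test_monotone_profile(self):
        prof = FreeEnergyProfile(
            bin_centers=np.arange(5.0),
            F=np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
            bin_counts=np.ones(5),
            empty_bin_mask=np.zeros(5, bool),
        )
        barrier, dab = extract_barrier(prof, (0, 0.5), (3.5, 4.5))
        assert barrier == pytest.approx(4.0)
        assert dab == pytest.approx(4.0)

    def test_overlapping_ranges_rejected(self):
        prof = FreeEnergyProfile(
            bin_centers=np.arange(3.0),
            F=np.zeros(3),
            bin_counts=np.ones(3),
            empty_bin_mask=np.zeros(3, bool),
        )
        with pytest.raises(ValueError, match="overlap"):
            extract_barrier(prof, (0, 2), (1, 3))


class TestClassifyConformation:
    @pytest.mark.parametrize(
        "d,label",
        [(27.4, "distal"), (18.38, "proximal"), (21.0, "intermediate")],
    )
    def test_thresholds(self, d, label):
        assert classify_conformation(d) == label
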