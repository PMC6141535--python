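"""Factor rotation, species correlations, clustering and regressions."""

import numpy as np
import pytest

from sdfa import (cluster_assemblages, correlation_cis, covariate_correlation,
                  pca_rotate, species_correlations,
                  spatial_vs_spatiotemporal_regression, variance_explained)
from sdfa.summaries import CorrelationSummary, fisher_ci


class TestPcaRotate:
    def test_diagonal_loadings_unchanged_up_to_sign(self):
        L = np.diag([3.0, 2.0, 1.0])
        rf = pca_rotate(L)
        np.testing.assert_allclose(np.abs(rf.L_rot), L, atol=1e-12)

    def test_outer_product_preserved(self):
        rng = np.random.default_rng(0)
        L = rng.standard_normal((5, 3))
        rf = pca_rotate(L)
        np.testing.assert_allclose(rf.L_rot @ rf.L_rot.T, L @ L.T, atol=1e-10)

    def test_var_explained_matches_eigenvalues(self):
        rng = np.random.default_rng(1)
        L = rng.standard_normal((3, 2))
        rf = pca_rotate(L)
        eig = np.sort(np.linalg.eigvalsh(L @ L.T))[::-1]
        expected = eig[:2] / eig[:2].sum()
        np.testing.assert_allclose(rf.var_explained, expected, atol=1e-10)

    def test_counter_rotation_preserves_predictions(self):
        rng = np.random.default_rng(2)
        L = rng.standard_normal((4, 3))
        coeffs = rng.standard_normal((10, 3))           # knots x factors
        rf = pca_rotate(L, coeffs)
        np.testing.assert_allclose(rf.coeff_rot @ rf.L_rot.T, coeffs @ L.T,
                                   atol=1e-9)

    def test_counter_rotation_spatiotemporal(self):
        rng = np.random.default_rng(3)
        L = rng.standard_normal((4, 2))
        coeffs = rng.standard_normal((7, 2, 5))         # knots x factors x years
        rf = pca_rotate(L, coeffs)
        before = np.einsum("kft,cf->kct", coeffs, L)
        after = np.einsum("kft,cf->kct", rf.coeff_rot, rf.L_rot)
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_sign_convention(self):
        rf = pca_rotate(np.array([[-2.0], [1.0]]))
        col = rf.L_rot[:, 0]
        assert col[np.argmax(np.abs(col))] > 0


class TestVarianceExplained:
    def test_rank_one(self):
        rf = pca_rotate(np.array([[1.0, 0.0], [2.0, 0.0]]))
        assert variance_explained(rf, 1) == pytest.approx(1.0)

    def test_full_rank_sums_to_one(self):
        rng = np.random.default_rng(4)
        rf = pca_rotate(rng.standard_normal((5, 3)))
        assert variance_explained(rf, 3) == pytest.approx(1.0)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(5)
        rf = pca_rotate(rng.standard_normal((5, 3)))
        vals = [variance_explained(rf, k) for k in (1, 2, 3)]
        assert vals == sorted(vals)

    def test_matches_eigenvalue_ratio(self):
        rng = np.random.default_rng(6)
        L = rng.standard_normal((5, 3))
        rf = pca_rotate(L)
        eig = np.sort(np.linalg.eigvalsh(L @ L.T))[::-1]
        assert variance_explained(rf, 2) == pytest.approx(
            eig[:2].sum() / eig[:3].sum(), abs=1e-10)

    def test_out_of_range_rejected(self):
        rf = pca_rotate(np.eye(2))
        with pytest.raises(ValueError):
            variance_explained(rf, 0)
        with pytest.raises(ValueError):
            variance_explained(rf, 3)


class TestSpeciesCorrelations:
    def test_identity_loadings(self):
        cs = species_correlations(np.eye(3))
        np.testing.assert_allclose(cs.corr, np.eye(3))

    def test_single_shared_factor(self):
        cs = species_correlations(np.ones((4, 1)))
        np.testing.assert_allclose(cs.corr, np.ones((4, 4)))

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(7)
        L = rng.standard_normal((4, 2))
        fields = rng.standard_normal((100_000, 2)) @ L.T
        mc = np.corrcoef(fields.T)
        cs = species_correlations(L)
        assert np.max(np.abs(cs.corr - mc)) < 0.01

    def test_invariant_to_rotation(self):
        rng = np.random.default_rng(8)
        L = rng.standard_normal((4, 2))
        theta = 1.1
        Q = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        np.testing.assert_allclose(species_correlations(L).corr,
                                   species_correlations(L @ Q).corr, atol=1e-12)

    def test_zero_variance_species_flagged(self):
        L = np.array([[1.0], [0.0]])
        cs = species_correlations(L)
        assert cs.undefined[1] and not cs.undefined[0]
        assert np.isnan(cs.corr[0, 1])


class TestCorrelationCIs:
    def test_zero_covariance_makes_everything_significant(self, tiny_fit_se):
        import copy
        res = copy.copy(tiny_fit_se)
        res.param_cov = np.zeros_like(tiny_fit_se.param_cov)
        cs = correlation_cis(res, which="L_omega_r", n_draws=50, seed=0)
        np.testing.assert_allclose(cs.se, 0.0, atol=1e-12)
        assert cs.significant.all()

    def test_deterministic_under_seed(self, tiny_fit_se):
        a = correlation_cis(tiny_fit_se, which="L_omega_r", n_draws=100, seed=3)
        b = correlation_cis(tiny_fit_se, which="L_omega_r", n_draws=100, seed=3)
        np.testing.assert_array_equal(a.ci_lo, b.ci_lo)

    def test_mask_is_ci_spanning_zero(self, tiny_fit_se):
        cs = correlation_cis(tiny_fit_se, which="L_eps_r", n_draws=200, seed=1)
        off = ~np.eye(cs.corr.shape[0], dtype=bool)
        spans = (cs.ci_lo <= 0) & (cs.ci_hi >= 0)
        np.testing.assert_array_equal(cs.masked[off], spans[off])

    def test_missing_covariance_rejected(self, truth_fit):
        with pytest.raises(ValueError, match="covariance"):
            correlation_cis(truth_fit, which="L_omega_r")


class TestClusterAssemblages:
    def test_perfect_blocks_recovered(self):
        blocks = [np.ones((2, 2)), np.ones((3, 3)), np.ones((1, 1))]
        from scipy.linalg import block_diag
        corr = block_diag(*blocks)
        np.fill_diagonal(corr, 1.0)
        labels = cluster_assemblages(corr, n_groups=3)
        assert len(set(labels[:2])) == 1
        assert len(set(labels[2:5])) == 1
        assert len({labels[0], labels[2], labels[5]}) == 3

    def test_singletons(self):
        labels = cluster_assemblages(np.eye(4), n_groups=4)
        assert sorted(labels) == [0, 1, 2, 3]

    def test_noisy_blocks_high_rand_index(self):
        rng = np.random.default_rng(9)
        truth = np.repeat([0, 1, 2], 4)
        corr = np.where(truth[:, None] == truth[None, :], 0.7, 0.0)
        noise = 0.05 * rng.standard_normal(corr.shape)
        corr = np.clip(corr + 0.5 * (noise + noise.T), -1, 1)
        np.fill_diagonal(corr, 1.0)
        labels = cluster_assemblages(corr, n_groups=3)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_too_many_groups_rejected(self):
        with pytest.raises(ValueError):
            cluster_assemblages(np.eye(3), n_groups=4)

    def test_undefined_entries_imputed_with_warning(self):
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = np.nan
        with pytest.warns(UserWarning, match="imputed"):
            cluster_assemblages(corr, n_groups=2)


class TestSpatialVsSpatiotemporalRegression:
    def test_proportional_loadings_give_unit_correlation(self, truth_fit):
        import copy
        res = copy.copy(truth_fit)
        ps = truth_fit.params.copy()
        fl = truth_fit.fields.copy()
        # make the spatiotemporal structure a copy of the spatial one
        ps.L_eps_r = ps.L_omega_r.copy()
        fl.eps_r = np.repeat(fl.omega_r[:, :, None], res.config.n_years, axis=2)
        res.params, res.fields = ps, fl
        out = spatial_vs_spatiotemporal_regression(res, comp="r")
        assert out["pearson_r"] == pytest.approx(1.0, abs=1e-9)
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_r_squared_equals_r_squared(self, truth_fit):
        out = spatial_vs_spatiotemporal_regression(truth_fit, comp="p")
        assert out["r_squared"] == pytest.approx(out["pearson_r"] ** 2)

    def test_independent_loadings_centre_near_zero(self):
        # realized pair correlations from unrelated random structures
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(30):
            a = np.corrcoef((rng.standard_normal((40, 2)) @
                             rng.standard_normal((2, 4))).T)
            b = np.corrcoef((rng.standard_normal((40, 2)) @
                             rng.standard_normal((2, 4))).T)
            iu = np.triu_indices(4, 1)
            rs.append(np.corrcoef(a[iu], b[iu])[0, 1])
        assert abs(np.mean(rs)) < 0.15


class TestCovariateCorrelation:
    def test_perfect_positive(self):
        z = np.linspace(0, 1, 30)
        out = covariate_correlation(z, z)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_perfect_negative(self):
        z = np.linspace(0, 1, 30)
        out = covariate_correlation(z, -z)
        assert out["pearson_r"] == pytest.approx(-1.0)

    def test_constant_covariate_flagged(self):
        out = covariate_correlation(np.arange(5.0), np.ones(5))
        assert out["undefined"]

    def test_attenuation_with_noise(self):
        # coeff = 0.8 z + e: expected r = 0.8 / sqrt(0.64 + sigma^2)
        rng = np.random.default_rng(12)
        sigma = 0.5
        expect = 0.8 / np.sqrt(0.64 + sigma**2)
        rs = []
        for _ in range(200):
            z = rng.standard_normal(100)
            coeff = 0.8 * z + sigma * rng.standard_normal(100)
            rs.append(covariate_correlation(coeff, z)["pearson_r"])
        assert np.mean(rs) == pytest.approx(expect, abs=0.02)

    def test_fisher_ci_contains_r(self):
        lo, hi = fisher_ci(0.6, 50)
        assert lo < 0.6 < hi
        assert -1 <= lo and hi <= 1
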