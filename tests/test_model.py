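"""Likelihood core: predictors, delta-gamma terms, joint NLL, Laplace, fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.linalg import block_diag
from scipy.special import expit
from scipy.stats import multivariate_normal

from sdfa import (FieldSet, ModelConfig, ParameterSet, SurveyDesign,
                  build_correlation_matrix, delta_gamma_loglik, fit,
                  information_criteria, joint_nll, joint_nll_grad_fields,
                  laplace_marginal_nll, make_knot_grid, matrix_normal_logpdf,
                  prepare_data, predictor_density, predictor_encounter,
                  simulate_survey, simulate_truth)
from sdfa.model import _eta_component


# ---------------------------------------------------------------------------
# predictors

class TestPredictors:
    def _setup(self, seed=0):
        grid = make_knot_grid(6, (0, 100, 0, 80))
        cfg = ModelConfig(n_species=2, n_years=3, n_knots=6, n_surveys=2,
                          n_factors_omega_p=1, n_factors_eps_p=1,
                          n_factors_omega_r=1, n_factors_eps_r=1, seed=0)
        truth = simulate_truth(cfg, grid, seed=seed, n_assemblages=1)
        return cfg, truth

    def test_all_zero_gives_even_odds(self):
        cfg, truth = self._setup()
        ps = ParameterSet.zeros(cfg)
        fl = FieldSet.zeros(cfg, 6)
        eta = predictor_encounter(ps, fl, {"knot": 0, "year": 0, "survey": 0}, 0)
        assert eta == 0.0
        assert expit(eta) == 0.5
        assert predictor_density(ps, fl, {"knot": 0, "year": 0, "survey": 0}, 0) == 0.0

    def test_intercept_only(self):
        cfg, truth = self._setup()
        ps = ParameterSet.zeros(cfg)
        fl = FieldSet.zeros(cfg, 6)
        ps.beta_p[0, 1] = np.log(4.0)   # logit of 0.8
        eta = predictor_encounter(ps, fl, {"knot": 2, "year": 1, "survey": 0}, 0)
        assert expit(eta) == pytest.approx(0.8)

    def test_offset_doubles_expected_catch(self):
        cfg, _ = self._setup()
        ps = ParameterSet.zeros(cfg)
        fl = FieldSet.zeros(cfg, 6)
        ps.beta_r[0, 0] = np.log(2.0)
        eta = predictor_density(ps, fl, {"knot": 0, "year": 0, "survey": 0,
                                         "swept_area": 2.0}, 0)
        assert np.exp(eta) == pytest.approx(4.0)

    def test_term_by_term_hand_sum(self):
        cfg, truth = self._setup(seed=3)
        ps, fl = truth.params, truth.fields
        haul = {"knot": 4, "year": 2, "survey": 1}
        for c in range(2):
            expected = (ps.beta_p[c, 2]
                        + sum(ps.L_omega_p[c, f] * fl.omega_p[4, f]
                              for f in range(1))
                        + sum(ps.L_eps_p[c, f] * fl.eps_p[4, f, 2]
                              for f in range(1))
                        + ps.delta_p[1] * 1.0)
            assert predictor_encounter(ps, fl, haul, c) == pytest.approx(
                expected, rel=1e-12)

    def test_unknown_survey_rejected(self):
        cfg, truth = self._setup()
        with pytest.raises(ValueError, match="survey"):
            predictor_encounter(truth.params, truth.fields,
                                {"knot": 0, "year": 0, "survey": 7}, 0)


# ---------------------------------------------------------------------------
# delta-gamma observation terms

class TestDeltaGammaLoglik:
    def test_zero_catch_branch(self):
        assert delta_gamma_loglik(0.0, 0.25, 1.0, 1.0) == pytest.approx(np.log(0.75))

    def test_exponential_special_case(self):
        # k = 1: positive branch is ln p + ln(1/r) - C/r
        c, p, r = 3.0, 0.4, 2.0
        assert delta_gamma_loglik(c, p, r, 1.0) == pytest.approx(
            np.log(p) - np.log(r) - c / r)

    @pytest.mark.parametrize("p,r,k", [(0.3, 1.0, 1.0), (0.7, 2.5, 0.7),
                                       (0.5, 0.4, 3.0), (0.9, 10.0, 1.5)])
    def test_positive_branch_integrates_to_p(self, p, r, k):
        val, _ = quad(lambda c: np.exp(delta_gamma_loglik(c, p, r, k)),
                      0, np.inf, limit=200)
        assert val == pytest.approx(p, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            delta_gamma_loglik(-1.0, 0.5, 1.0, 1.0)
        with pytest.raises(ValueError):
            delta_gamma_loglik(1.0, 1.5, 1.0, 1.0)


# ---------------------------------------------------------------------------
# joint NLL

def _small_problem(seed=5, n_hauls=40, n_surveys=1):
    grid = make_knot_grid(6, (0, 150, 0, 100))
    cfg = ModelConfig(n_species=2, n_years=3, n_knots=6, n_surveys=n_surveys,
                      n_factors_omega_p=1, n_factors_eps_p=1,
                      n_factors_omega_r=1, n_factors_eps_r=1, seed=0)
    truth = simulate_truth(cfg, grid, seed=seed, n_assemblages=1)
    table = simulate_survey(
        truth, SurveyDesign(hauls_per_year={v: n_hauls for v in range(n_surveys)}),
        seed=seed + 1)
    data = prepare_data(table, grid, cfg)
    return cfg, grid, truth, table, data


class TestJointNLL:
    def test_zero_fields_empty_data_is_prior_at_zero(self):
        from sdfa.model import ModelData
        cfg, grid, truth, _, data = _small_problem()
        empty = ModelData(
            config=cfg, grid=grid, species=data.species, surveys=data.surveys,
            knot_idx=np.zeros(0, dtype=int), year_idx=np.zeros(0, dtype=int),
            species_idx=np.zeros(0, dtype=int), survey_idx=np.zeros(0, dtype=int),
            log_area=np.zeros(0), catch=np.zeros(0), start_year=1990,
            Q_p=data.Q_p, Q_r=data.Q_r)
        fl = FieldSet.zeros(cfg, len(grid))
        val = joint_nll(truth.params, fl, empty)
        expected = 0.0
        for comp in ("p", "r"):
            R = build_correlation_matrix(grid, truth.params.matern(comp, cfg.nu))
            expected -= matrix_normal_logpdf(np.zeros((len(grid), 1)), R,
                                             np.eye(1), jitter=0.0)
            for _ in range(cfg.n_years):
                expected -= matrix_normal_logpdf(np.zeros((len(grid), 1)), R,
                                                 np.eye(1), jitter=0.0)
        assert val == pytest.approx(expected, rel=1e-9)

    def test_adding_one_observation_is_additive(self):
        cfg, grid, truth, table, data = _small_problem()
        row = table.iloc[[0]].copy()
        table2 = pd.concat([table, row], ignore_index=True)
        data2 = prepare_data(table2, grid, cfg)
        fl = truth.fields
        base = joint_nll(truth.params, fl, data)
        extra = joint_nll(truth.params, fl, data2)
        haul = {"knot": data.knot_idx[0], "year": data.year_idx[0],
                "survey": data.survey_idx[0],
                "swept_area": float(np.exp(data.log_area[0]))}
        c = data.species_idx[0]
        eta_p = predictor_encounter(truth.params, fl, haul, c)
        eta_r = predictor_density(truth.params, fl, haul, c,
                                  offset_policy=cfg.offset_policy)
        ll = delta_gamma_loglik(data.catch[0], expit(eta_p), np.exp(eta_r),
                                truth.params.k[c])
        assert extra - base == pytest.approx(-ll, rel=1e-9)

    def test_gradient_matches_finite_differences(self):
        cfg, grid, truth, _, data = _small_problem(seed=7)
        rng = np.random.default_rng(0)
        fl = truth.fields.copy()
        g = joint_nll_grad_fields(truth.params, fl, data)
        for arr, garr in [(fl.omega_p, g.omega_p), (fl.eps_p, g.eps_p),
                          (fl.omega_r, g.omega_r), (fl.eps_r, g.eps_r)]:
            for _ in range(5):
                ix = tuple(rng.integers(0, s) for s in arr.shape)
                h, old = 1e-6, arr[ix]
                arr[ix] = old + h
                fp = joint_nll(truth.params, fl, data)
                arr[ix] = old - h
                fm = joint_nll(truth.params, fl, data)
                arr[ix] = old
                fd = (fp - fm) / (2 * h)
                assert abs(fd - garr[ix]) / max(1.0, abs(fd)) < 1e-5

    def test_invariant_under_orthogonal_rotation(self):
        # rotating loadings while counter-rotating fields leaves NLL unchanged
        grid = make_knot_grid(6, (0, 150, 0, 100))
        cfg = ModelConfig(n_species=3, n_years=2, n_knots=6, seed=0,
                          n_factors_omega_p=2, n_factors_eps_p=2,
                          n_factors_omega_r=2, n_factors_eps_r=2)
        truth = simulate_truth(cfg, grid, seed=2, n_assemblages=1)
        table = simulate_survey(truth, SurveyDesign(hauls_per_year={0: 30}), seed=3)
        data = prepare_data(table, grid, cfg)
        base = joint_nll(truth.params, truth.fields, data)
        theta = 0.7
        Q = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        ps = truth.params.copy()
        fl = truth.fields.copy()
        for kind in ("omega", "eps"):
            for comp in ("p", "r"):
                setattr(ps, f"L_{kind}_{comp}", ps.loading(kind, comp) @ Q)
        fl.omega_p = fl.omega_p @ Q
        fl.omega_r = fl.omega_r @ Q
        fl.eps_p = np.einsum("kft,fg->kgt", fl.eps_p, Q)
        fl.eps_r = np.einsum("kft,fg->kgt", fl.eps_r, Q)
        rotated = joint_nll(ps, fl, data)
        assert rotated == pytest.approx(base, abs=1e-8)


# ---------------------------------------------------------------------------
# Laplace approximation

def _gaussian_problem(sigma=0.5, seed=4):
    grid = make_knot_grid(5, (0, 120, 0, 90), layout="random", seed=0)
    cfg = ModelConfig(n_species=2, n_years=3, n_knots=5, family="gaussian",
                      offset_policy="none", seed=0,
                      n_factors_omega_p=0, n_factors_eps_p=0,
                      n_factors_omega_r=1, n_factors_eps_r=1)
    truth = simulate_truth(cfg, grid, seed=seed, n_assemblages=1)
    truth.params.log_sigma = float(np.log(sigma))
    table = simulate_survey(truth, SurveyDesign(hauls_per_year={0: 15}), seed=5)
    data = prepare_data(table, grid, cfg)
    return cfg, grid, truth, data


def gaussian_marginal_nll_closed_form(cfg, grid, ps, data):
    """Exact marginal NLL for the linear-Gaussian variant via dense algebra."""
    K, T = len(grid), cfg.n_years
    R = build_correlation_matrix(grid, ps.matern("r", cfg.nu))
    Fw, Fe = cfg.n_factors_omega_r, cfg.n_factors_eps_r
    blocks = [np.kron(R, np.eye(Fw))] + [np.kron(R, np.eye(Fe))] * T
    cov_u = block_diag(*[b for b in blocks if b.size])
    n = data.n_obs
    n_u = K * Fw + K * Fe * T
    Z = np.zeros((n, n_u))
    for i in range(n):
        s, t, c = data.knot_idx[i], data.year_idx[i], data.species_idx[i]
        for f in range(Fw):
            Z[i, s * Fw + f] = ps.L_omega_r[c, f]
        off = K * Fw + t * K * Fe
        for f in range(Fe):
            Z[i, off + s * Fe + f] = ps.L_eps_r[c, f]
    mean = ps.beta_r[data.species_idx, data.year_idx]
    cov_y = Z @ cov_u @ Z.T + ps.sigma**2 * np.eye(n)
    return -multivariate_normal(mean, cov_y, allow_singular=True).logpdf(data.catch)


class TestLaplace:
    def test_exact_in_linear_gaussian_limit(self):
        cfg, grid, truth, data = _gaussian_problem()
        exact = gaussian_marginal_nll_closed_form(cfg, grid, truth.params, data)
        approx, _, _ = laplace_marginal_nll(truth.params, data)
        assert approx == pytest.approx(exact, abs=1e-6)

    def test_no_random_effects_equals_joint_nll(self):
        grid = make_knot_grid(6, (0, 150, 0, 100))
        cfg = ModelConfig(n_species=2, n_years=2, n_knots=6, seed=0,
                          n_factors_omega_p=0, n_factors_eps_p=0,
                          n_factors_omega_r=0, n_factors_eps_r=0)
        truth = simulate_truth(cfg, grid, seed=1, n_assemblages=1)
        table = simulate_survey(truth, SurveyDesign(hauls_per_year={0: 25}), seed=2)
        data = prepare_data(table, grid, cfg)
        fl = FieldSet.zeros(cfg, len(grid))
        marg, _, _ = laplace_marginal_nll(truth.params, data)
        assert marg == pytest.approx(joint_nll(truth.params, fl, data), rel=1e-12)

    def test_duplicating_data_increases_nll(self):
        cfg, grid, truth, table, data = _small_problem(seed=9)
        doubled = prepare_data(pd.concat([table, table], ignore_index=True),
                               grid, cfg)
        v1, _, _ = laplace_marginal_nll(truth.params, data)
        v2, _, _ = laplace_marginal_nll(truth.params, doubled)
        assert v2 > v1


# ---------------------------------------------------------------------------
# fitting and information criteria

class TestFit:
    def test_multi_start_stability(self):
        cfg, grid, truth, table, data = _small_problem(seed=13, n_hauls=60)
        nlls = [fit(data, seed=s, maxiter=300).nll for s in (0, 1, 2)]
        assert max(nlls) - min(nlls) < 0.5

    def test_nested_model_never_worse_in_sample(self):
        grid = make_knot_grid(6, (0, 150, 0, 100))
        big = ModelConfig(n_species=2, n_years=3, n_knots=6, seed=0,
                          n_factors_omega_p=1, n_factors_eps_p=1,
                          n_factors_omega_r=1, n_factors_eps_r=1)
        small = ModelConfig(n_species=2, n_years=3, n_knots=6, seed=0,
                            n_factors_omega_p=0, n_factors_eps_p=0,
                            n_factors_omega_r=1, n_factors_eps_r=1)
        truth = simulate_truth(big, grid, seed=3, n_assemblages=1)
        table = simulate_survey(truth, SurveyDesign(hauls_per_year={0: 50}), seed=4)
        fit_big = fit(prepare_data(table, grid, big), seed=0)
        fit_small = fit(prepare_data(table, grid, small), seed=0)
        assert fit_big.nll <= fit_small.nll + 0.1

    def test_shrinkage_under_null_loadings(self):
        grid = make_knot_grid(6, (0, 150, 0, 100))
        cfg = ModelConfig(n_species=2, n_years=3, n_knots=6, seed=0,
                          n_factors_omega_p=1, n_factors_eps_p=1,
                          n_factors_omega_r=1, n_factors_eps_r=1)
        truth = simulate_truth(cfg, grid, seed=6, n_assemblages=1)
        for name in ("L_omega_p", "L_eps_p", "L_omega_r", "L_eps_r"):
            setattr(truth.params, name, np.zeros_like(getattr(truth.params, name)))
        table = simulate_survey(truth, SurveyDesign(hauls_per_year={0: 60}), seed=7)
        res = fit(prepare_data(table, grid, cfg), seed=0)
        mags = np.concatenate([np.abs(res.params.loading(k, c)).ravel()
                               for k in ("omega", "eps") for c in ("p", "r")])
        # truth loadings are zero; fitted magnitudes stay far below the
        # generator's signal scale of 1.0
        assert mags.mean() < 0.35

    def test_convergence_report_present(self, tiny_fit_se):
        assert tiny_fit_se.converged
        assert np.isfinite(tiny_fit_se.grad_norm)
        assert tiny_fit_se.hessian_pd is not None
        assert tiny_fit_se.param_cov.shape == (tiny_fit_se.n_fixed,) * 2


class TestInformationCriteria:
    def test_aic_formula(self, tiny_fit_se):
        res = tiny_fit_se
        aic, bic = information_criteria(res)
        assert aic == pytest.approx(2 * res.n_fixed + 2 * res.nll)
        assert bic == pytest.approx(np.log(res.n_obs) * res.n_fixed + 2 * res.nll)

    def test_bic_aic_penalty_gap(self, tiny_fit_se):
        # BIC - AIC = (ln n - 2) * n_fixed; equal when ln(n_obs) = 2
        res = tiny_fit_se
        aic, bic = information_criteria(res)
        assert bic - aic == pytest.approx(
            (np.log(res.n_obs) - 2.0) * res.n_fixed)
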