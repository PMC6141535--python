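"""Shared fixtures: small simulated datasets and (slow) fitted models."""

from __future__ import annotations

import numpy as np
import pytest

from sdfa import (FieldSet, ModelConfig, SurveyDesign, make_knot_grid,
                  prepare_data, simulate_survey, simulate_truth)
from sdfa.model import FitResult, fit as fit_model
from sdfa.params import pack_params, param_index


@pytest.fixture(scope="session")
def small_grid():
    return make_knot_grid(12, (0.0, 300.0, 0.0, 200.0), layout="regular")


@pytest.fixture(scope="session")
def small_config():
    return ModelConfig(n_species=3, n_years=4, n_knots=12, n_surveys=2,
                       n_factors_omega_p=1, n_factors_eps_p=1,
                       n_factors_omega_r=1, n_factors_eps_r=1, seed=0)


@pytest.fixture(scope="session")
def small_truth(small_config, small_grid):
    return simulate_truth(small_config, small_grid, seed=5, n_assemblages=2)


@pytest.fixture(scope="session")
def small_table(small_truth):
    return simulate_survey(small_truth,
                           SurveyDesign(hauls_per_year={0: 60, 1: 40}), seed=6)


@pytest.fixture(scope="session")
def small_data(small_table, small_grid, small_config):
    return prepare_data(small_table, small_grid, small_config)


def fitresult_from_truth(truth, data) -> FitResult:
    """A FitResult built directly from ground truth (no optimisation)."""
    config = truth.config
    x = pack_params(truth.params, config)
    return FitResult(
        config=config, data=data, params=truth.params, fields=truth.fields,
        x=x, index=param_index(config), nll=np.nan, aic=np.nan, bic=np.nan,
        n_fixed=len(x), n_obs=data.n_obs, converged=True, grad_norm=0.0,
        n_outer_iter=0,
    )


@pytest.fixture(scope="session")
def truth_fit(small_truth, small_data):
    """Prediction surface built on the simulation truth itself."""
    return fitresult_from_truth(small_truth, small_data)


@pytest.fixture(scope="session")
def tiny_fit_se():
    """A real (small) fit with standard errors, shared across tests."""
    grid = make_knot_grid(10, (0.0, 250.0, 0.0, 150.0), layout="regular")
    config = ModelConfig(n_species=3, n_years=3, n_knots=10, n_surveys=1,
                         n_factors_omega_p=1, n_factors_eps_p=1,
                         n_factors_omega_r=1, n_factors_eps_r=1, seed=0)
    truth = simulate_truth(config, grid, seed=21, n_assemblages=2)
    table = simulate_survey(truth, SurveyDesign(hauls_per_year={0: 70}), seed=22)
    data = prepare_data(table, grid, config)
    result = fit_model(data, se=True, seed=0, maxiter=200)
    result.truth = truth   # stashed for recovery-style assertions
    return result
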