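"""Scikit-learn style front end for the spatial dynamic factor model.

``SpatialDynamicFactorAnalysis`` wraps data preparation, knot-grid
construction and marginal-likelihood maximisation behind the familiar
``fit`` / ``predict`` / ``get_params`` surface, so the model composes
with sklearn tooling.  ``X`` is a long-format station-catch DataFrame
(one row per haul x species, zero catches explicit).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import ModelConfig
from .families import delta_gamma_loglik, gaussian_nll_terms
from .model import _eta_component, fit as fit_model, prepare_data
from .synthetic import KnotGrid, make_knot_grid

__all__ = ["SpatialDynamicFactorAnalysis"]


class SpatialDynamicFactorAnalysis(BaseEstimator):
    """Joint dynamic species distribution model with latent factor fields.

    Parameters
    ----------
    n_factors_spatial, n_factors_spatiotemporal : int
        Factor counts applied to both the encounter and positive-density
        components (set per-component counts via ``factor_counts``).
    factor_counts : dict, optional
        Overrides ``{"omega_p": ..., "eps_p": ..., "omega_r": ..., "eps_r": ...}``.
    n_knots : int
        Knots laid out over the data extent when no grid is supplied.
    grid : KnotGrid, optional
        Explicit spatial support; overrides ``n_knots``/``knot_layout``.
    family : str
        ``"delta_gamma"`` (the operational model) or ``"gaussian"``.
    offset_policy : str
        How log swept area enters the density predictor:
        ``"offset"`` (coefficient fixed at 1), ``"covariate"`` or ``"none"``.
    se : bool
        Compute a finite-difference outer Hessian for standard errors.

    Attributes
    ----------
    result_ : FitResult
        Full fit object (estimates, field modes, NLL, AIC/BIC, diagnostics).
    params_, fields_, nll_, aic_, bic_, converged_, species_ : fitted summaries.
    """

    def __init__(self, n_factors_spatial: int = 1,
                 n_factors_spatiotemporal: int = 1,
                 factor_counts: Optional[dict] = None,
                 n_knots: int = 25, knot_layout: str = "regular",
                 grid: Optional[KnotGrid] = None,
                 family: str = "delta_gamma", offset_policy: str = "offset",
                 nu: float = 1.0, se: bool = False,
                 maxiter: int = 500, gtol: float = 1e-4,
                 inner_tol: float = 1e-8, outer_tol: float = 1e-6,
                 seed: int = 0):
        self.n_factors_spatial = n_factors_spatial
        self.n_factors_spatiotemporal = n_factors_spatiotemporal
        self.factor_counts = factor_counts
        self.n_knots = n_knots
        self.knot_layout = knot_layout
        self.grid = grid
        self.family = family
        self.offset_policy = offset_policy
        self.nu = nu
        self.se = se
        self.maxiter = maxiter
        self.gtol = gtol
        self.inner_tol = inner_tol
        self.outer_tol = outer_tol
        self.seed = seed

    # ------------------------------------------------------------------
    def _make_config(self, X: pd.DataFrame) -> ModelConfig:
        fc = dict(self.factor_counts or {})
        counts = {
            "n_factors_omega_p": fc.get("omega_p", self.n_factors_spatial),
            "n_factors_eps_p": fc.get("eps_p", self.n_factors_spatiotemporal),
            "n_factors_omega_r": fc.get("omega_r", self.n_factors_spatial),
            "n_factors_eps_r": fc.get("eps_r", self.n_factors_spatiotemporal),
        }
        years = np.sort(X["year"].unique())
        return ModelConfig(
            n_species=X["species"].nunique(),
            n_years=int(years[-1]) - int(years[0]) + 1,
            n_knots=self.n_knots if self.grid is None else len(self.grid),
            n_surveys=X["survey"].nunique(),
            family=self.family, offset_policy=self.offset_policy,
            nu=self.nu, start_year=int(years[0]),
            inner_tol=self.inner_tol, outer_tol=self.outer_tol,
            maxiter=self.maxiter, seed=self.seed, **counts,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "SpatialDynamicFactorAnalysis":
        """Estimate all fixed effects and latent field modes from ``X``."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a long-format station-catch DataFrame")
        config = self._make_config(X)
        grid = self.grid
        if grid is None:
            pad = 1e-6
            extent = (X["x_km"].min() - pad, X["x_km"].max() + pad,
                      X["y_km"].min() - pad, X["y_km"].max() + pad)
            grid = make_knot_grid(self.n_knots, extent,
                                  layout=self.knot_layout, seed=self.seed)
        data = prepare_data(X, grid, config)
        self.result_ = fit_model(data, se=self.se, seed=self.seed,
                                 maxiter=self.maxiter, gtol=self.gtol)
        self.grid_ = grid
        self.config_ = config
        self.params_ = self.result_.params
        self.fields_ = self.result_.fields
        self.species_ = list(data.species)
        self.nll_ = self.result_.nll
        self.aic_ = self.result_.aic
        self.bic_ = self.result_.bic
        self.converged_ = self.result_.converged
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise AttributeError("estimator is not fitted; call fit(X) first")

    def _row_predictors(self, X: pd.DataFrame):
        data = prepare_data(X, self.grid_, self.config_,
                            species=self.species_,
                            surveys=self.result_.data.surveys)
        rows = np.arange(data.n_obs)
        eta_r = _eta_component("r", self.params_, self.fields_, data, rows)
        eta_p = (_eta_component("p", self.params_, self.fields_, data, rows)
                 if self.config_.family == "delta_gamma" else None)
        return data, eta_p, eta_r

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Expected catch (kg) for each haul x species row of ``X``."""
        self._check_fitted()
        from scipy.special import expit
        _, eta_p, eta_r = self._row_predictors(X)
        if self.config_.family == "gaussian":
            return eta_r
        return expit(eta_p) * np.exp(eta_r)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean per-row log-likelihood of ``X`` at the fitted parameters."""
        self._check_fitted()
        from scipy.special import expit
        data, eta_p, eta_r = self._row_predictors(X)
        if self.config_.family == "gaussian":
            nll, _, _ = gaussian_nll_terms(eta_r, data.catch, self.params_.sigma)
            return float(-np.mean(nll))
        ll = delta_gamma_loglik(data.catch, expit(eta_p), np.exp(eta_r),
                                self.params_.k[data.species_idx])
        return float(np.mean(ll))
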