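"""Post-fit prediction surfaces and mixed-fishery decision products.

Expected density at a knot is the delta-gamma mean p * r evaluated at
reference catchability (all survey effects zero) and unit area, so maps
and abundance indices are gear-free.  Gear effects enter only through
``catch_composition``, which applies a survey/gear's catchability to
both predictors and renormalises across species — the "what would this
gear catch here" product.  The abundance index is the area-weighted sum
of density over knots per year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .params import unpack_params

__all__ = ["DensitySurface", "CatchComposition", "predict_density",
           "standardize_surface", "difference_map", "catch_composition",
           "abundance_index"]


@dataclass
class DensitySurface:
    """Per-knot expected density (kg/km2) and its two components."""

    species: str
    year: int
    density: np.ndarray          # p * r at each knot
    encounter_prob: np.ndarray
    positive_density: np.ndarray


@dataclass
class CatchComposition:
    """Expected per-species catch of one gear at one knot and year."""

    knot: int
    year: int
    gear: object
    species: list
    expected: np.ndarray
    proportions: np.ndarray
    defined: bool


def _resolve_species(fit, species) -> int:
    if isinstance(species, str):
        if species not in fit.data.species:
            raise KeyError(f"unknown species {species!r}")
        return fit.data.species.index(species)
    c = int(species)
    if not (0 <= c < fit.config.n_species):
        raise KeyError(f"species index {c} out of range")
    return c


def _resolve_year(fit, year) -> int:
    t = int(year) - fit.data.start_year
    if not (0 <= t < fit.config.n_years):
        raise KeyError(f"year {year} outside fitted range "
                       f"{fit.data.start_year}..{fit.data.start_year + fit.config.n_years - 1}")
    return t


def _knot_predictors(fit, c: int, t: int, survey: Optional[int] = None):
    """(eta_p, eta_r) at every knot for one species-year; delta terms only
    when a survey is given."""
    ps, fl = fit.params, fit.fields
    K = len(fit.data.grid)
    eta_p = np.full(K, np.nan)
    if fit.config.family == "delta_gamma":
        eta_p = np.full(K, float(ps.beta_p[c, t]))
        if ps.L_omega_p.shape[1]:
            eta_p += fl.omega_p @ ps.L_omega_p[c]
        if ps.L_eps_p.shape[1]:
            eta_p += fl.eps_p[:, :, t] @ ps.L_eps_p[c]
    eta_r = np.full(K, float(ps.beta_r[c, t]))
    if ps.L_omega_r.shape[1]:
        eta_r += fl.omega_r @ ps.L_omega_r[c]
    if ps.L_eps_r.shape[1]:
        eta_r += fl.eps_r[:, :, t] @ ps.L_eps_r[c]
    if survey is not None:
        v = int(survey)
        if not (0 <= v < fit.config.n_surveys):
            raise KeyError(f"gear/survey {survey} not among fitted surveys")
        if fit.config.family == "delta_gamma":
            eta_p += ps.delta_p[v] * fit.data.Q_p[c, v]
        eta_r += ps.delta_r[v] * fit.data.Q_r[c, v]
    return eta_p, eta_r


def predict_density(fit, species, year) -> DensitySurface:
    """Expected density surface p * r at reference catchability, unit area."""
    if fit.config.family != "delta_gamma":
        raise ValueError("density surfaces are defined for the delta-gamma family")
    c = _resolve_species(fit, species)
    t = _resolve_year(fit, year)
    eta_p, eta_r = _knot_predictors(fit, c, t)
    p = expit(eta_p)
    r = np.exp(eta_r)
    name = fit.data.species[c]
    return DensitySurface(species=name, year=int(year), density=p * r,
                          encounter_prob=p, positive_density=r)


def standardize_surface(ds, method: str = "z") -> np.ndarray:
    """Standardise a density surface across knots (z-score by default).

    A zero-variance surface is flagged with a warning and returns zeros.
    ``method="minmax"`` rescales to [0, 1] instead.
    """
    values = ds.density if isinstance(ds, DensitySurface) else np.asarray(ds, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 knots to standardise")
    if method == "z":
        sd = values.std()
        if sd == 0:
            warnings.warn("zero-variance surface; standardised map is all zeros",
                          stacklevel=2)
            return np.zeros_like(values)
        return (values - values.mean()) / sd
    if method == "minmax":
        rng = values.max() - values.min()
        if rng == 0:
            warnings.warn("zero-variance surface; standardised map is all zeros",
                          stacklevel=2)
            return np.zeros_like(values)
        return (values - values.min()) / rng
    raise ValueError(f"unknown standardisation method {method!r}")


def difference_map(fit, species_a, species_b, year, method: str = "z") -> np.ndarray:
    """Standardised density difference A - B per knot (antisymmetric in A, B)."""
    za = standardize_surface(predict_density(fit, species_a, year), method)
    zb = standardize_surface(predict_density(fit, species_b, year), method)
    return za - zb


def catch_composition(fit, gear, knot: int, year) -> CatchComposition:
    """Per-species expected catch and proportions for one gear at one knot."""
    t = _resolve_year(fit, year)
    K = len(fit.data.grid)
    if not (0 <= int(knot) < K):
        raise KeyError(f"knot {knot} out of range 0..{K - 1}")
    if gear not in fit.data.surveys:
        raise KeyError(f"gear {gear!r} not among fitted surveys {fit.data.surveys}")
    v = fit.data.surveys.index(gear)
    S = fit.config.n_species
    expected = np.empty(S)
    for c in range(S):
        eta_p, eta_r = _knot_predictors(fit, c, t, survey=v)
        expected[c] = expit(eta_p[int(knot)]) * np.exp(eta_r[int(knot)])
    total = expected.sum()
    defined = bool(total > 0)
    if not defined:
        warnings.warn("all expected catches are zero; composition undefined",
                      stacklevel=2)
        props = np.zeros(S)
    else:
        props = expected / total
    return CatchComposition(knot=int(knot), year=int(year), gear=gear,
                            species=list(fit.data.species),
                            expected=expected, proportions=props,
                            defined=defined)


def abundance_index(fit, species, n_draws: int = 200,
                    seed: Optional[int] = None) -> pd.DataFrame:
    """Area-weighted yearly abundance index, with Monte-Carlo SEs if possible.

    Index(t) = sum_s area_s * density(s, t).  SEs propagate fixed-effect
    uncertainty (fields held at their modes) by redrawing parameters from
    the asymptotic normal; they are NaN when the fit has no covariance.
    """
    c = _resolve_species(fit, species)
    area = fit.data.grid.area
    years = fit.data.start_year + np.arange(fit.config.n_years)
    index = np.array([
        float(area @ predict_density(fit, species, y).density) for y in years
    ])
    se = np.full(len(years), np.nan)
    if fit.param_cov is not None:
        rng = np.random.default_rng(seed)
        w, U = np.linalg.eigh(0.5 * (fit.param_cov + fit.param_cov.T))
        A = U * np.sqrt(np.maximum(w, 0.0))
        draws = np.empty((n_draws, len(years)))
        base_params = fit.params
        for d in range(n_draws):
            x_d = fit.x + A @ rng.standard_normal(len(fit.x))
            ps_d = unpack_params(x_d, fit.config)
            fit.params = ps_d
            try:
                draws[d] = [float(area @ predict_density(fit, species, y).density)
                            for y in years]
            finally:
                fit.params = base_params
        se = draws.std(axis=0, ddof=1)
    return pd.DataFrame({"year": years, "index": index, "se": se,
                         "species": fit.data.species[c]})
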