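"""Dimension-reduction summaries: rotated factors, species correlations,
assemblage clustering and correlation regressions.

Factor models are only identified up to orthogonal rotation, so factors
are reported after a PCA rotation (eigen-rotation of L L', equivalently
the SVD of L) that orders them by decreasing explained variance without
changing L L' or any model prediction.  Among-species correlations come
from the factor-implied covariance L L'; their uncertainty is propagated
by Monte Carlo from the asymptotic normal of the loading estimates, and
pairs whose 95% interval (point estimate +- 1.96 SE) spans zero are
masked as non-significant.  Assemblages are recovered by average-linkage
hierarchical clustering on the correlation distance 1 - corr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress, pearsonr

__all__ = [
    "RotatedFactors", "CorrelationSummary",
    "pca_rotate", "variance_explained", "species_correlations",
    "correlation_cis", "cluster_assemblages",
    "spatial_vs_spatiotemporal_regression", "covariate_correlation",
    "fisher_ci",
]


@dataclass
class RotatedFactors:
    """PCA-rotated loadings and counter-rotated factor coefficients."""

    L_rot: np.ndarray            # species x factors
    coeff_rot: np.ndarray        # knots x factors (x years for eps)
    var_explained: np.ndarray    # fraction per factor, non-increasing
    rotation: np.ndarray         # orthogonal matrix applied: L_rot = L @ rotation


@dataclass
class CorrelationSummary:
    """Species x species correlation matrix with optional CI machinery."""

    corr: np.ndarray
    se: Optional[np.ndarray] = None
    ci_lo: Optional[np.ndarray] = None
    ci_hi: Optional[np.ndarray] = None
    significant: Optional[np.ndarray] = None   # True where CI excludes zero
    undefined: Optional[np.ndarray] = None     # zero-variance species

    @property
    def masked(self) -> Optional[np.ndarray]:
        """Off-diagonal entries whose CI spans zero (left blank in plots)."""
        if self.significant is None:
            return None
        off = ~np.eye(self.corr.shape[0], dtype=bool)
        return (~self.significant) & off


def pca_rotate(L: np.ndarray, coeffs: Optional[np.ndarray] = None) -> RotatedFactors:
    """Rotate loadings to principal-component orientation.

    With SVD ``L = U S W'``, the rotated loadings are ``L W = U S``
    (columns ordered by decreasing singular value) and factor values are
    counter-rotated by ``W'`` so every predicted log-density is
    unchanged.  Each rotated column is sign-flipped so its
    largest-magnitude entry is positive.  ``coeffs`` may be knots x
    factors (spatial) or knots x factors x years (spatiotemporal).
    """
    L = np.asarray(L, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("loadings must be finite")
    S, F = L.shape
    _, sv, Wt = np.linalg.svd(L, full_matrices=True)
    rot = Wt.T                              # (F, F) complete orthogonal matrix
    L_rot = L @ rot
    # sign convention: largest-magnitude loading of each factor positive
    flips = np.ones(F)
    for f in range(F):
        col = L_rot[:, f]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            flips[f] = -1.0
    L_rot = L_rot * flips
    rot = rot * flips

    if coeffs is None:
        coeff_rot = None
    else:
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.ndim == 2:
            coeff_rot = coeffs @ rot
        else:
            coeff_rot = np.einsum("kft,fg->kgt", coeffs, rot)

    power = np.concatenate([sv**2, np.zeros(F - len(sv))])
    total = power.sum()
    var = power / total if total > 0 else np.zeros(F)
    return RotatedFactors(L_rot=L_rot, coeff_rot=coeff_rot,
                          var_explained=var, rotation=rot)


def variance_explained(rf: RotatedFactors, k: int) -> float:
    """Fraction of between-species variance carried by the first k factors."""
    F = len(rf.var_explained)
    if not (1 <= k <= F):
        raise ValueError(f"k must be in [1, {F}], got {k}")
    return float(np.sum(rf.var_explained[:k]))


def species_correlations(L: np.ndarray) -> CorrelationSummary:
    """Point estimates of among-species correlations implied by L L'."""
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[1] < 1:
        raise ValueError("L must be species x factors with >= 1 factor")
    cov = L @ L.T
    var = np.diag(cov).copy()
    undefined = var <= 0
    sd = np.sqrt(np.where(undefined, 1.0, var))
    corr = cov / np.outer(sd, sd)
    corr[undefined, :] = np.nan
    corr[:, undefined] = np.nan
    np.fill_diagonal(corr, np.where(undefined, np.nan, 1.0))
    corr = np.clip(corr, -1.0, 1.0, out=corr)
    return CorrelationSummary(corr=corr, undefined=undefined)


def correlation_cis(fit, which: str = "L_eps_r", n_draws: int = 500,
                    seed: Optional[int] = None) -> CorrelationSummary:
    """Correlation matrix with Monte-Carlo-propagated SEs and a 95% mask.

    Loading parameters are drawn from their asymptotic normal (the
    relevant block of the outer covariance), correlations recomputed per
    draw, the SE taken as the draw standard deviation, and entries whose
    ``estimate +- 1.96 SE`` interval spans zero are marked
    non-significant.
    """
    if fit.param_cov is None:
        raise ValueError("fit has no parameter covariance; refit with se=True")
    if which not in fit.index:
        raise KeyError(f"no loading block {which!r} in this fit "
                       f"(available: {sorted(fit.index)})")
    from .params import tril_indices   # local import to avoid cycles

    sl = fit.index[which]
    mean = fit.x[sl]
    cov = fit.param_cov[sl, sl]
    S = fit.config.n_species
    kind, comp = which.split("_")[1], which.split("_")[2]
    F = fit.config.n_factors(kind, comp)
    rows, cols = tril_indices(S, F)

    point = species_correlations(fit.params.loading(kind, comp))

    rng = np.random.default_rng(seed)
    w, U = np.linalg.eigh(0.5 * (cov + cov.T))
    A = U * np.sqrt(np.maximum(w, 0.0))
    draws = mean[None, :] + rng.standard_normal((n_draws, len(mean))) @ A.T
    corrs = np.empty((n_draws, S, S))
    for d in range(n_draws):
        Ld = np.zeros((S, F))
        Ld[rows, cols] = draws[d]
        corrs[d] = species_correlations(Ld).corr
    se = np.nanstd(corrs, axis=0, ddof=1)
    np.fill_diagonal(se, 0.0)
    ci_lo = point.corr - 1.96 * se
    ci_hi = point.corr + 1.96 * se
    significant = (ci_lo > 0) | (ci_hi < 0)
    np.fill_diagonal(significant, True)
    return CorrelationSummary(corr=point.corr, se=se, ci_lo=ci_lo, ci_hi=ci_hi,
                              significant=significant, undefined=point.undefined)


def cluster_assemblages(cs, n_groups: int = 3, method: str = "average") -> np.ndarray:
    """Cut an average-linkage dendrogram on 1 - corr into assemblages.

    Accepts a ``CorrelationSummary`` or a bare correlation matrix.
    Undefined entries are imputed as 0 with a warning.  Returns integer
    labels 0..n_groups-1, renumbered by first appearance in species
    order (deterministic tie-breaking).
    """
    corr = cs.corr if isinstance(cs, CorrelationSummary) else np.asarray(cs, dtype=float)
    S = corr.shape[0]
    if n_groups > S:
        raise ValueError(f"n_groups={n_groups} exceeds number of species {S}")
    corr = corr.copy()
    if np.any(~np.isfinite(corr)):
        warnings.warn("undefined correlations imputed as 0 for clustering",
                      stacklevel=2)
        corr[~np.isfinite(corr)] = 0.0
    dist = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    Z = scipy_linkage(squareform(dist, checks=False), method=method)
    raw = fcluster(Z, t=n_groups, criterion="maxclust")
    # renumber by first appearance
    relabel, labels = {}, np.empty(S, dtype=int)
    for i, g in enumerate(raw):
        labels[i] = relabel.setdefault(g, len(relabel))
    return labels


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple:
    """Fisher-z confidence interval for a Pearson correlation."""
    from scipy.stats import norm
    if n <= 3:
        return (-1.0, 1.0)
    r = float(np.clip(r, -0.999999, 0.999999))
    z = np.arctanh(r)
    half = norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def _pairwise_field_correlations(field_species: np.ndarray) -> np.ndarray:
    """Upper-triangle pairwise correlations across knots of a knot x species field."""
    C = np.corrcoef(field_species.T)
    iu = np.triu_indices(C.shape[0], k=1)
    return C[iu]


def spatial_vs_spatiotemporal_regression(fit, comp: str = "p") -> dict:
    """Regress yearly spatiotemporal pair correlations on the spatial ones.

    For each species pair, the "average spatial" correlation is the
    across-knot correlation of the realized spatial fields (omega L'),
    and the per-year spatiotemporal correlation is the across-knot
    correlation of that year's realized field (eps_t L').  An OLS of the
    pooled yearly values on the spatial values measures how persistent
    pairwise associations are from year to year.
    """
    config = fit.config
    Lw = fit.params.loading("omega", comp)
    Le = fit.params.loading("eps", comp)
    if Lw.shape[1] == 0 or Le.shape[1] == 0:
        raise ValueError("both spatial and spatiotemporal factors are required")
    S = config.n_species
    n_pairs = S * (S - 1) // 2
    if n_pairs < 3:
        raise ValueError("need at least 3 species pairs")
    spatial = _pairwise_field_correlations(fit.fields.omega(comp) @ Lw.T)
    xs, ys = [], []
    for t in range(config.n_years):
        st = _pairwise_field_correlations(fit.fields.eps(comp)[:, :, t] @ Le.T)
        xs.append(spatial)
        ys.append(st)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    ok = np.isfinite(x) & np.isfinite(y)
    reg = linregress(x[ok], y[ok])
    r = float(reg.rvalue)
    return {
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "pearson_r": r,
        "ci": fisher_ci(r, int(ok.sum())),
        "r_squared": r * r,
        "n": int(ok.sum()),
    }


def covariate_correlation(coeffs: np.ndarray, covariate: np.ndarray,
                          level: float = 0.95) -> dict:
    """Pearson correlation of a factor-coefficient map with a knot covariate."""
    coeffs = np.asarray(coeffs, dtype=float).ravel()
    covariate = np.asarray(covariate, dtype=float).ravel()
    if coeffs.shape != covariate.shape:
        raise ValueError("coefficient and covariate vectors must align on knots")
    if not np.all(np.isfinite(covariate)):
        raise ValueError("covariate contains non-finite values")
    if np.std(covariate) == 0 or np.std(coeffs) == 0:
        return {"pearson_r": np.nan, "ci": (np.nan, np.nan),
                "undefined": True, "n": len(coeffs)}
    r, _ = pearsonr(coeffs, covariate)
    return {"pearson_r": float(r), "ci": fisher_ci(float(r), len(coeffs), level),
            "undefined": False, "n": len(coeffs)}
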