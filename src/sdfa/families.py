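"""Observation models: the delta-gamma hurdle and a Gaussian check family.

The delta-gamma (hurdle-gamma) model treats catch weight C at a station
as zero with probability 1 - p, and gamma-distributed given a positive
catch:

    Pr(C = 0)        = 1 - p
    Pr(C = c | c>0)  = p * lambda^k c^(k-1) exp(-lambda c) / Gamma(k)

with shape k and rate lambda.  The positive-density predictor r is the
*mean* of the positive distribution, so lambda = k / r (the standard
delta-model convention; the rate-form above never ties lambda to the
predictor on its own).

Both stages are log-concave in their linear predictors, which makes the
inner (random-effects) optimisation a convex problem:

    encounter, logit eta:  d2/deta2 log-lik = -p(1-p)  (either outcome)
    positive,  log eta:    d2/deta2 log-lik = -k C / r

The Gaussian family (identity link, known/estimated sigma) exists
because its marginal likelihood integrates in closed form, giving an
exact oracle for the Laplace approximation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln

__all__ = ["delta_gamma_loglik", "bernoulli_nll_terms", "gamma_nll_terms",
           "gaussian_nll_terms"]


def delta_gamma_loglik(catch, p, r, k):
    """Per-observation delta-gamma log-likelihood.

    ``catch = 0`` contributes ``log(1 - p)``; ``catch > 0`` contributes
    ``log p`` plus the Gamma(shape k, rate k/r) log-density at the catch.
    Vectorised over conforming array inputs.
    """
    catch = np.asarray(catch, dtype=float)
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(catch < 0):
        raise ValueError("catch must be non-negative")
    if np.any((p <= 0) | (p >= 1)) or np.any(r <= 0) or np.any(k <= 0):
        raise ValueError("require 0 < p < 1, r > 0, k > 0")
    catch_b, p, r, k = np.broadcast_arrays(catch, p, r, k)
    out = np.where(catch_b == 0, np.log1p(-p), 0.0)
    pos = catch_b > 0
    if np.any(pos):
        c, pp, rr, kk = catch_b[pos], p[pos], r[pos], k[pos]
        lam = kk / rr
        out = out.copy()
        out[pos] = (np.log(pp) + kk * np.log(lam) + (kk - 1.0) * np.log(c)
                    - lam * c - gammaln(kk))
    return out if out.ndim else float(out)


def bernoulli_nll_terms(eta, enc):
    """NLL and first/second derivatives in eta for the encounter stage.

    ``enc`` is 1 where the catch was positive, 0 otherwise. Uses the
    numerically stable log1p(exp) form.
    """
    eta = np.asarray(eta, dtype=float)
    enc = np.asarray(enc, dtype=float)
    if not np.all(np.isfinite(eta)):
        bad = np.where(~np.isfinite(eta))[0]
        raise FloatingPointError(f"non-finite encounter predictor at rows {bad[:5]}")
    p = expit(eta)
    # -log Pr = log(1 + e^eta) - enc*eta, stable via logaddexp
    nll = np.logaddexp(0.0, eta) - enc * eta
    d1 = p - enc
    d2 = p * (1.0 - p)
    return nll, d1, d2


def gamma_nll_terms(eta, catch, k):
    """NLL and derivatives in eta for positive catches, mean r = exp(eta).

    ``-log f = -k(log k - eta) - (k-1) log C + k C e^-eta + log Gamma(k)``.
    """
    eta = np.asarray(eta, dtype=float)
    catch = np.asarray(catch, dtype=float)
    k = np.asarray(k, dtype=float)
    if not np.all(np.isfinite(eta)):
        bad = np.where(~np.isfinite(eta))[0]
        raise FloatingPointError(f"non-finite density predictor at rows {bad[:5]}")
    ce = catch * np.exp(-eta)
    nll = -k * (np.log(k) - eta) - (k - 1.0) * np.log(catch) + k * ce + gammaln(k)
    d1 = k * (1.0 - ce)
    d2 = k * ce
    return nll, d1, d2


def gaussian_nll_terms(eta, y, sigma):
    """NLL and derivatives in eta for ``y ~ N(eta, sigma^2)``."""
    eta = np.asarray(eta, dtype=float)
    y = np.asarray(y, dtype=float)
    resid = eta - y
    nll = 0.5 * np.log(2.0 * np.pi * sigma**2) + 0.5 * (resid / sigma) ** 2
    d1 = resid / sigma**2
    d2 = np.full_like(eta, 1.0 / sigma**2)
    return nll, d1, d2
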