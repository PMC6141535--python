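"""Delta-gamma spatial dynamic factor model: likelihood and estimation.

Each species c at haul i (knot s, year t, survey v) has two linear
predictors,

    logit p_i = beta_p(c,t) + sum_f L_omega_p(c,f) omega_p(s,f)
              + sum_f L_eps_p(c,f) eps_p(s,f,t) + delta_p(v) Q_p(c,v)
    log   r_i = beta_r(c,t) + ... (r-component terms) [+ log swept area]

feeding a delta-gamma observation model.  Latent factor fields are
Gaussian Markov random fields over knots with anisotropic Matérn
correlation R; factor columns are a priori iid N(0, R), so the implied
species-level field covariance is R ⊗ L L' (the matrix-normal law).

Estimation maximises the Laplace-approximated marginal likelihood

    nll_marg(theta) = joint_nll(theta, u*) + 1/2 log det H - n_u/2 log 2pi

with u* the inner mode over all latent fields and H the inner Hessian.
The inner problem is convex (both observation stages are log-concave in
their predictors) and is solved by Newton iterations that exploit the
Hessian's arrowhead sparsity: spatial factors couple to every year's
spatiotemporal factors through the data, but different years never
couple, so each solve is a sequence of per-year factorisations plus one
Schur complement on the spatial block.

The outer optimisation uses the exact gradient of the Laplace objective,

    dL/dtheta = df/dtheta + 1/2 tr(G dH/dtheta) - 1/2 w' d2f/du dtheta,
    w = G J'(d3 * leverage),   G = H^{-1},

which requires third derivatives of the observation terms and selected
blocks of the inverse inner Hessian; both come cheaply from the same
arrowhead factorisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import digamma, expit

from .config import ModelConfig
from .families import bernoulli_nll_terms, gamma_nll_terms, gaussian_nll_terms
from .gmrf import build_correlation_matrix
from .params import (FieldSet, ParameterSet, pack_params, param_index,
                     tril_indices, unpack_params)
from .synthetic import KnotGrid, assign_knots

__all__ = ["ModelData", "FitResult", "prepare_data", "predictor_encounter",
           "predictor_density", "joint_nll", "joint_nll_grad_fields",
           "laplace_marginal_nll", "laplace_marginal_nll_grad", "fit",
           "information_criteria"]


# ---------------------------------------------------------------------------
# data preparation

@dataclass
class ModelData:
    """Observation table coded to integer indices against a knot grid."""

    config: ModelConfig
    grid: KnotGrid
    species: list
    surveys: list
    knot_idx: np.ndarray
    year_idx: np.ndarray
    species_idx: np.ndarray
    survey_idx: np.ndarray
    log_area: np.ndarray
    catch: np.ndarray
    start_year: int
    Q_p: np.ndarray = None
    Q_r: np.ndarray = None

    @property
    def n_obs(self) -> int:
        return len(self.catch)

    @property
    def positive(self) -> np.ndarray:
        return self.catch > 0


def prepare_data(table, grid: KnotGrid, config: ModelConfig,
                 species: Optional[list] = None, surveys: Optional[list] = None,
                 Q_p: Optional[np.ndarray] = None, Q_r: Optional[np.ndarray] = None,
                 strict: bool = False) -> ModelData:
    """Validate a long-format station-catch table and code it to indices."""
    required = {"haul_id", "x_km", "y_km", "year", "survey", "swept_area_km2",
                "species", "catch_kg"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"station table missing columns {sorted(missing)}")
    if np.any(table["catch_kg"].to_numpy() < 0):
        raise ValueError("negative catches in station table")
    if np.any(table["swept_area_km2"].to_numpy() <= 0):
        raise ValueError("swept areas must be positive")

    if species is None:
        species = sorted(table["species"].unique())
    if surveys is None:
        surveys = sorted(table["survey"].unique())
    sp_code = {s: i for i, s in enumerate(species)}
    sv_code = {s: i for i, s in enumerate(surveys)}
    if len(species) != config.n_species:
        raise ValueError(f"table has {len(species)} species, config expects "
                         f"{config.n_species}")
    if len(surveys) != config.n_surveys:
        raise ValueError(f"table has {len(surveys)} surveys, config expects "
                         f"{config.n_surveys}")

    years = np.sort(table["year"].unique())
    start_year = int(years[0])
    if int(years[-1]) - start_year + 1 != config.n_years:
        raise ValueError(
            f"years {start_year}..{int(years[-1])} span "
            f"{int(years[-1]) - start_year + 1} years; config expects {config.n_years}"
        )

    knot_idx = assign_knots(grid, table["x_km"].to_numpy(),
                            table["y_km"].to_numpy(), strict=strict)
    S, V = config.n_species, config.n_surveys
    return ModelData(
        config=config, grid=grid, species=list(species), surveys=list(surveys),
        knot_idx=knot_idx,
        year_idx=table["year"].to_numpy() - start_year,
        species_idx=table["species"].map(sp_code).to_numpy(),
        survey_idx=table["survey"].map(sv_code).to_numpy(),
        log_area=np.log(table["swept_area_km2"].to_numpy(dtype=float)),
        catch=table["catch_kg"].to_numpy(dtype=float),
        start_year=start_year,
        Q_p=np.ones((S, V)) if Q_p is None else np.asarray(Q_p, dtype=float),
        Q_r=np.ones((S, V)) if Q_r is None else np.asarray(Q_r, dtype=float),
    )


# ---------------------------------------------------------------------------
# linear predictors

def _eta_component(comp: str, ps: ParameterSet, fl: FieldSet, data: ModelData,
                   rows: np.ndarray) -> np.ndarray:
    """Vectorised linear predictor for one component on selected rows."""
    c = data.species_idx[rows]
    t = data.year_idx[rows]
    s = data.knot_idx[rows]
    v = data.survey_idx[rows]
    if len(v) and v.max() >= len(ps.delta(comp)):
        raise ValueError("unknown survey id in data")
    eta = ps.beta(comp)[c, t].astype(float).copy()
    Lw, Le = ps.loading("omega", comp), ps.loading("eps", comp)
    if Lw.shape[1]:
        eta += np.einsum("if,if->i", fl.omega(comp)[s], Lw[c])
    if Le.shape[1]:
        eta += np.einsum("if,if->i", fl.eps(comp)[s, :, t], Le[c])
    Q = data.Q_p if comp == "p" else data.Q_r
    eta += ps.delta(comp)[v] * Q[c, v]
    if comp == "r":
        policy = data.config.offset_policy
        if policy == "offset":
            eta = eta + data.log_area[rows]
        elif policy == "covariate":
            eta = eta + ps.area_coef_r * data.log_area[rows]
    return eta


def predictor_encounter(ps: ParameterSet, fl: FieldSet, haul: dict, species: int,
                        Q: Optional[np.ndarray] = None) -> float:
    """Logit-scale encounter predictor for one haul x species.

    ``haul`` must already be mapped to a knot: keys ``knot``, ``year``
    (0-based index) and ``survey`` (coded index).
    """
    v = int(haul.get("survey", 0))
    if v >= len(ps.delta_p):
        raise ValueError(f"unknown survey id {v}")
    eta = float(ps.beta_p[species, haul["year"]])
    if ps.L_omega_p.shape[1]:
        eta += float(ps.L_omega_p[species] @ fl.omega_p[haul["knot"]])
    if ps.L_eps_p.shape[1]:
        eta += float(ps.L_eps_p[species] @ fl.eps_p[haul["knot"], :, haul["year"]])
    q = 1.0 if Q is None else float(Q[species, v])
    return eta + float(ps.delta_p[v]) * q


def predictor_density(ps: ParameterSet, fl: FieldSet, haul: dict, species: int,
                      Q: Optional[np.ndarray] = None,
                      offset_policy: str = "offset") -> float:
    """Log-scale positive-density predictor, with swept-area offset policy."""
    v = int(haul.get("survey", 0))
    if v >= len(ps.delta_r):
        raise ValueError(f"unknown survey id {v}")
    eta = float(ps.beta_r[species, haul["year"]])
    if ps.L_omega_r.shape[1]:
        eta += float(ps.L_omega_r[species] @ fl.omega_r[haul["knot"]])
    if ps.L_eps_r.shape[1]:
        eta += float(ps.L_eps_r[species] @ fl.eps_r[haul["knot"], :, haul["year"]])
    q = 1.0 if Q is None else float(Q[species, v])
    eta += float(ps.delta_r[v]) * q
    area = float(haul.get("swept_area", 1.0))
    if offset_policy == "offset":
        eta += np.log(area)
    elif offset_policy == "covariate":
        eta += ps.area_coef_r * np.log(area)
    return eta


# ---------------------------------------------------------------------------
# arrowhead factorisation of the inner Hessian

class _Factorization:
    """Cholesky factorisation of the arrowhead inner Hessian.

    Blocks: spatial A (nW x nW), per-year D_t (nE x nE) and couplings
    B_t (nW x nE).  Provides solves, the log-determinant and the
    selected-inverse blocks needed by the outer gradient.
    """

    def __init__(self, K: int, Fw: int, Fe: int, T: int, A, Bs, Ds):
        self.K, self.Fw, self.Fe, self.T = K, Fw, Fe, T
        self.Bs = Bs
        self.logdet = 0.0
        self.cDs = None
        self.cM = None
        self.Ys = None
        if Fe:
            self.cDs = [cho_factor(D, lower=True) for D in Ds]
            for cD in self.cDs:
                self.logdet += 2.0 * float(np.sum(np.log(np.diag(cD[0]))))
        if Fw:
            M = A.copy()
            self.Ys = []
            if Fe:
                for t in range(T):
                    Y = cho_solve(self.cDs[t], Bs[t].T)        # (nE, nW)
                    M -= Bs[t] @ Y
                    self.Ys.append(Y)
            self.cM = cho_factor(M, lower=True)
            self.logdet += 2.0 * float(np.sum(np.log(np.diag(self.cM[0]))))

    def solve(self, gW: np.ndarray, gE: np.ndarray):
        """Solve H [xW, xE] = [gW, gE]; shapes (K,Fw) and (K,Fe,T)."""
        K, Fw, Fe, T = self.K, self.Fw, self.Fe, self.T
        xW = np.zeros((K, Fw))
        xE = np.zeros((K, Fe, T))
        if Fw:
            rhs = gW.ravel().copy()
            if Fe:
                for t in range(T):
                    rhs -= self.Bs[t] @ cho_solve(self.cDs[t], gE[:, :, t].ravel())
            xw = cho_solve(self.cM, rhs)
            xW = xw.reshape(K, Fw)
            if Fe:
                for t in range(T):
                    xe = cho_solve(self.cDs[t], gE[:, :, t].ravel()) - self.Ys[t] @ xw
                    xE[:, :, t] = xe.reshape(K, Fe)
        elif Fe:
            for t in range(T):
                xE[:, :, t] = cho_solve(self.cDs[t],
                                        gE[:, :, t].ravel()).reshape(K, Fe)
        return xW, xE

    def selected_inverse(self):
        """Per-(year, knot) diagonal blocks of H^-1 and factor-traced K x K maps.

        Returns ``(Gblk, TrF_W, TrF_E)`` where Gblk[t, s] is the
        (Fw+Fe) x (Fw+Fe) block of H^-1 at the omega/eps_t coordinates of
        knot s, TrF_W[s, s'] = sum_f G[(s,f),(s',f)] over the omega block
        and TrF_E[t] likewise for each year's eps block.
        """
        K, Fw, Fe, T = self.K, self.Fw, self.Fe, self.T
        F = Fw + Fe
        idx = np.arange(K)
        Gblk = np.zeros((max(T, 1), K, F, F))
        TrF_W = np.zeros((K, K))
        TrF_E: List[np.ndarray] = []
        G_WW = None
        if Fw:
            G_WW = cho_solve(self.cM, np.eye(K * Fw))
            GW4 = G_WW.reshape(K, Fw, K, Fw)
            TrF_W = np.einsum("afbf->ab", GW4)
            Gblk[:, :, :Fw, :Fw] = GW4[idx, :, idx, :][None]
        for t in range(T if Fe else 0):
            Dinv = cho_solve(self.cDs[t], np.eye(K * Fe))
            if Fw:
                SY = cho_solve(self.cM, self.Ys[t].T)          # (nW, nE)
                G_EE = Dinv + self.Ys[t] @ SY
                G_WE = -SY                                     # (nW, nE)
                GWE4 = G_WE.reshape(K, Fw, K, Fe)
                cross = GWE4[idx, :, idx, :]                   # (K, Fw, Fe)
                Gblk[t, :, :Fw, Fw:] = cross
                Gblk[t, :, Fw:, :Fw] = np.transpose(cross, (0, 2, 1))
            else:
                G_EE = Dinv
            GE4 = G_EE.reshape(K, Fe, K, Fe)
            TrF_E.append(np.einsum("afbf->ab", GE4))
            Gblk[t, :, Fw:, Fw:] = GE4[idx, :, idx, :]
        return Gblk, TrF_W, TrF_E


# ---------------------------------------------------------------------------
# per-component inner problem

class _ComponentProblem:
    """Inner (random-effects) optimisation for one model component."""

    def __init__(self, comp: str, ps: ParameterSet, data: ModelData,
                 R: np.ndarray):
        config = data.config
        self.comp = comp
        self.config = config
        self.ps = ps
        self.data = data
        self.K = len(data.grid)
        self.T = config.n_years
        self.Fw = config.n_factors("omega", comp)
        self.Fe = config.n_factors("eps", comp)
        self.n_u = self.K * self.Fw + self.K * self.Fe * self.T

        if comp == "p" or config.family == "gaussian":
            rows = np.arange(data.n_obs)
        else:
            rows = np.where(data.positive)[0]
        self.rows = rows
        self.s = data.knot_idx[rows]
        self.t = data.year_idx[rows]
        self.c = data.species_idx[rows]
        self.v = data.survey_idx[rows]
        Q = data.Q_p if comp == "p" else data.Q_r
        self.q_obs = Q[self.c, self.v]
        self.log_area = data.log_area[rows]

        # fixed part of eta: everything except the latent fields
        zero_fields = FieldSet.zeros(config, self.K)
        self.fixed_eta = _eta_component(comp, ps, zero_fields, data, rows)
        self.Lw_obs = ps.loading("omega", comp)[self.c]
        self.Le_obs = ps.loading("eps", comp)[self.c]

        if comp == "p":
            self.enc = (data.catch[rows] > 0).astype(float)
        else:
            self.catch = data.catch[rows]
            self.k_obs = ps.k[self.c]
            self.sigma = ps.sigma

        cR = cho_factor(R, lower=True)
        self.R = R
        self.R_inv = cho_solve(cR, np.eye(self.K))
        self.R_logdet = 2.0 * float(np.sum(np.log(np.diag(cR[0]))))
        self.family = config.family

    # -- pieces ----------------------------------------------------------
    def eta(self, W: np.ndarray, E: np.ndarray) -> np.ndarray:
        eta = self.fixed_eta.copy()
        if self.Fw:
            eta += np.einsum("if,if->i", W[self.s], self.Lw_obs)
        if self.Fe:
            eta += np.einsum("if,if->i", E[self.s, :, self.t], self.Le_obs)
        return eta

    def obs_terms(self, eta: np.ndarray):
        if self.comp == "p":
            return bernoulli_nll_terms(eta, self.enc)
        if self.family == "gaussian":
            return gaussian_nll_terms(eta, self.catch, self.sigma)
        return gamma_nll_terms(eta, self.catch, self.k_obs)

    def obs_d3(self, eta: np.ndarray, d2: np.ndarray) -> np.ndarray:
        """Third derivative of the per-observation NLL in eta."""
        if self.comp == "p":
            return d2 * (1.0 - 2.0 * expit(eta))
        if self.family == "gaussian":
            return np.zeros_like(d2)
        return -d2

    def prior_nll(self, W: np.ndarray, E: np.ndarray) -> float:
        F_tot = self.Fw + self.Fe * self.T
        quad = 0.0
        if self.Fw:
            quad += float(np.sum(W * (self.R_inv @ W)))
        if self.Fe:
            for t in range(self.T):
                quad += float(np.sum(E[:, :, t] * (self.R_inv @ E[:, :, t])))
        return 0.5 * (quad + F_tot * self.R_logdet
                      + self.n_u * np.log(2.0 * np.pi))

    def objective(self, W: np.ndarray, E: np.ndarray) -> float:
        nll, _, _ = self.obs_terms(self.eta(W, E))
        return float(np.sum(nll)) + self.prior_nll(W, E)

    def grad(self, W: np.ndarray, E: np.ndarray):
        _, d1, _ = self.obs_terms(self.eta(W, E))
        return self._field_scatter(d1, W, E, include_prior=True)

    def _field_scatter(self, weight: np.ndarray, W, E, include_prior: bool):
        """J' weight (+ prior gradient), shaped like the fields."""
        gW = self.R_inv @ W if (include_prior and self.Fw) else np.zeros((self.K, self.Fw))
        if self.Fw:
            np.add.at(gW, self.s, weight[:, None] * self.Lw_obs)
        gE = np.zeros((self.K, self.Fe, self.T))
        if self.Fe:
            if include_prior:
                for t in range(self.T):
                    gE[:, :, t] = self.R_inv @ E[:, :, t]
            np.add.at(gE, (self.s, slice(None), self.t),
                      weight[:, None] * self.Le_obs)
        return gW, gE

    # -- Newton machinery ------------------------------------------------
    def factorize(self, d2: np.ndarray) -> _Factorization:
        K, Fw, Fe, T = self.K, self.Fw, self.Fe, self.T
        idx = np.arange(K)
        A = Bs = Ds = None
        if Fw:
            S_ww = np.zeros((K, Fw, Fw))
            np.add.at(S_ww, self.s,
                      np.einsum("i,if,ig->ifg", d2, self.Lw_obs, self.Lw_obs))
            A = np.kron(self.R_inv, np.eye(Fw))
            A.reshape(K, Fw, K, Fw)[idx, :, idx, :] += S_ww
        if Fe:
            S_ee = np.zeros((T, K, Fe, Fe))
            np.add.at(S_ee, (self.t, self.s),
                      np.einsum("i,if,ig->ifg", d2, self.Le_obs, self.Le_obs))
            Ds = []
            for t in range(T):
                D = np.kron(self.R_inv, np.eye(Fe))
                D.reshape(K, Fe, K, Fe)[idx, :, idx, :] += S_ee[t]
                Ds.append(D)
        if Fw and Fe:
            S_we = np.zeros((T, K, Fw, Fe))
            np.add.at(S_we, (self.t, self.s),
                      np.einsum("i,if,ig->ifg", d2, self.Lw_obs, self.Le_obs))
            Bs = []
            for t in range(T):
                B = np.zeros((K, Fw, K, Fe))
                B[idx, :, idx, :] = S_we[t]
                Bs.append(B.reshape(K * Fw, K * Fe))
        return _Factorization(K, Fw, Fe, T, A, Bs, Ds)

    def solve(self, W0: np.ndarray, E0: np.ndarray, tol: float,
              maxiter: int = 200):
        """Inner Newton minimisation.

        Returns ``(W, E, fact, f_mode, grad_norm, n_iter)`` with ``fact``
        the factorisation of the Hessian at the mode.
        """
        W, E = W0.copy(), E0.copy()
        if self.n_u == 0:
            nll, _, _ = self.obs_terms(self.eta(W, E))
            return W, E, None, float(np.sum(nll)), 0.0, 0
        f = self.objective(W, E)
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            gW, gE = self.grad(W, E)
            gnorm = max(np.abs(gW).max() if self.Fw else 0.0,
                        np.abs(gE).max() if self.Fe else 0.0)
            if gnorm < tol:
                n_iter -= 1
                break
            _, d1, d2 = self.obs_terms(self.eta(W, E))
            fact = self.factorize(d2)
            dW, dE = fact.solve(gW, gE)
            slope = float(np.sum(gW * dW) + np.sum(gE * dE))
            # Newton decrement at the numerical floor: accept the mode
            if slope < 1e-14 * (1.0 + abs(f)):
                n_iter -= 1
                break
            step = 1.0
            for _ in range(40):
                f_new = self.objective(W - step * dW, E - step * dE)
                if f_new <= f - 1e-4 * step * slope:
                    break
                step *= 0.5
            else:
                if gnorm < 1e-4:
                    n_iter -= 1
                    break
                raise RuntimeError(
                    f"inner line search failed for component {self.comp!r} "
                    f"(gradient norm {gnorm:.2e})")
            W, E = W - step * dW, E - step * dE
            # objective change at the roundoff floor with a small gradient:
            # treat as converged (ill-conditioned R can leave the gradient
            # above the nominal tolerance at machine precision)
            if f - f_new < 1e-13 * (1.0 + abs(f)) and gnorm < 1e-4:
                f = f_new
                n_iter -= 1
                break
            f = f_new
        else:
            gW, gE = self.grad(W, E)
            gnorm = max(np.abs(gW).max() if self.Fw else 0.0,
                        np.abs(gE).max() if self.Fe else 0.0)
            raise RuntimeError(
                f"inner optimisation for component {self.comp!r} did not reach "
                f"gradient norm {tol:.1e} in {maxiter} iterations "
                f"(current {gnorm:.2e})")
        gW, gE = self.grad(W, E)
        gnorm = max(np.abs(gW).max() if self.Fw else 0.0,
                    np.abs(gE).max() if self.Fe else 0.0)
        f = self.objective(W, E)
        _, _, d2 = self.obs_terms(self.eta(W, E))
        fact = self.factorize(d2)
        return W, E, fact, f, gnorm, n_iter

    # -- outer gradient ---------------------------------------------------
    def gradient_blocks(self, fact: Optional[_Factorization], W, E,
                        dR: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
        """Exact gradient of this component's Laplace contribution.

        ``dR`` maps spatial-parameter names ("log_kappa", "h1", "h2") to
        dR/dtheta matrices.  Returns a dict of gradient blocks keyed by
        packed-parameter names.
        """
        comp = self.comp
        config = self.config
        S = config.n_species
        eta = self.eta(W, E)
        nll, d1, d2 = self.obs_terms(eta)
        d3 = self.obs_d3(eta, d2)
        n = len(self.rows)

        if fact is not None and self.n_u:
            Gblk, TrF_W, TrF_E = fact.selected_inverse()
            jsp = np.concatenate([self.Lw_obs, self.Le_obs], axis=1)  # (n, F)
            t_idx = self.t if self.Fe else np.zeros(n, dtype=int)
            Gobs = Gblk[t_idx, self.s]                                # (n, F, F)
            mvec = np.einsum("ifg,ig->if", Gobs, jsp)                 # G_block j
            lev = np.einsum("if,if->i", jsp, mvec)                    # leverage
            qW, qE = self._field_scatter(d3 * lev, W, E, include_prior=False)
            wW, wE = fact.solve(qW, qE)
            jw = np.zeros(n)
            if self.Fw:
                jw += np.einsum("if,if->i", wW[self.s], self.Lw_obs)
            if self.Fe:
                jw += np.einsum("if,if->i", wE[self.s, :, self.t], self.Le_obs)
            wsup = np.concatenate(
                [wW[self.s] if self.Fw else np.zeros((n, 0)),
                 wE[self.s, :, self.t] if self.Fe else np.zeros((n, 0))], axis=1)
        else:
            lev = jw = np.zeros(n)
            mvec = wsup = np.zeros((n, 0))
            wW = np.zeros((self.K, self.Fw))
            wE = np.zeros((self.K, self.Fe, self.T))
            TrF_W, TrF_E = np.zeros((self.K, self.K)), []

        out: Dict[str, np.ndarray] = {}
        # generic per-obs weight for parameters entering eta linearly with
        # observation-level weight phi: dL = sum_i phi_i * base_i
        base = d1 + 0.5 * d3 * lev - 0.5 * d2 * jw

        g_beta = np.zeros((S, self.T))
        np.add.at(g_beta, (self.c, self.t), base)
        out[f"beta_{comp}"] = g_beta.ravel()

        V = config.n_surveys
        if V > 1:
            g_delta = np.zeros(V)
            np.add.at(g_delta, self.v, self.q_obs * base)
            out[f"delta_{comp}"] = g_delta[1:]

        for kind, F, fields_obs, slot in (
                ("omega", self.Fw, W[self.s] if self.Fw else None, 0),
                ("eps", self.Fe, E[self.s, :, self.t] if self.Fe else None,
                 self.Fw)):
            if F == 0:
                name = f"L_{kind}_{comp}"
                out[name] = np.zeros(0)
                continue
            gL = np.zeros((S, F))
            m_part = mvec[:, slot:slot + F] if mvec.shape[1] else np.zeros((n, F))
            w_part = wsup[:, slot:slot + F] if wsup.shape[1] else np.zeros((n, F))
            contrib = (fields_obs * base[:, None]
                       + d2[:, None] * m_part
                       - 0.5 * d1[:, None] * w_part)
            np.add.at(gL, self.c, contrib)
            r_idx, c_idx = tril_indices(S, F)
            out[f"L_{kind}_{comp}"] = gL[r_idx, c_idx]

        if comp == "r" and self.family == "delta_gamma":
            k = self.k_obs
            dnll_dk = (-np.log(k) - 1.0 + eta - np.log(self.catch)
                       + self.catch * np.exp(-eta) + digamma(k))
            per_obs = k * dnll_dk + 0.5 * d2 * lev - 0.5 * d1 * jw
            g_k = np.zeros(S)
            np.add.at(g_k, self.c, per_obs)
            out["log_k"] = g_k

        if comp == "r" and self.family == "gaussian":
            resid2 = (eta - self.catch) ** 2 / self.sigma**2
            out["log_sigma"] = np.array([
                float(np.sum(1.0 - resid2) - np.sum(d2 * lev) + np.sum(d1 * jw))])

        if comp == "r" and config.offset_policy == "covariate":
            out["area_coef_r"] = np.array([float(np.sum(self.log_area * base))])

        # spatial-correlation parameters (prior + log-det trace + cross)
        F_tot = self.Fw + self.Fe * self.T
        for name, dRm in dR.items():
            dRinv = -self.R_inv @ dRm @ self.R_inv
            val = 0.5 * F_tot * float(np.sum(self.R_inv * dRm))   # d logdet R
            quad = 0.0
            tr = 0.0
            cross = 0.0
            if self.Fw:
                quad += float(np.sum(W * (dRinv @ W)))
                tr += float(np.sum(dRinv * TrF_W))
                cross += float(np.sum(wW * (dRinv @ W)))
            if self.Fe:
                for t in range(self.T):
                    quad += float(np.sum(E[:, :, t] * (dRinv @ E[:, :, t])))
                    tr += float(np.sum(dRinv * TrF_E[t]))
                    cross += float(np.sum(wE[:, :, t] * (dRinv @ E[:, :, t])))
            val += 0.5 * quad + 0.5 * tr - 0.5 * cross
            out[name] = np.array([val])
        return out


def _component_R(comp: str, ps: ParameterSet, data: ModelData) -> np.ndarray:
    return build_correlation_matrix(data.grid, ps.matern(comp, data.config.nu))


def _spatial_derivatives(comp: str, ps: ParameterSet, data: ModelData,
                         step: float = 1e-5) -> Dict[str, np.ndarray]:
    """dR/dtheta for log kappa and the anisotropy parameters (central FD).

    R is a smooth function of its three scalar parameters; differencing
    the matrix itself keeps the rest of the gradient exact.
    """
    from .gmrf import MaternParams

    kappa = ps.kappa_p if comp == "p" else ps.kappa_r
    nu = data.config.nu

    def R_of(log_kappa, h1, h2):
        return build_correlation_matrix(
            data.grid, MaternParams(np.exp(log_kappa), nu, h1, h2), jitter=0.0)

    lk = np.log(kappa)
    out = {}
    out[f"log_kappa_{comp}"] = (R_of(lk + step, ps.h1, ps.h2)
                                - R_of(lk - step, ps.h1, ps.h2)) / (2 * step)
    dh1 = (R_of(lk, ps.h1 + step, ps.h2) - R_of(lk, ps.h1 - step, ps.h2)) / (2 * step)
    dh2 = (R_of(lk, ps.h1, ps.h2 + step) - R_of(lk, ps.h1, ps.h2 - step)) / (2 * step)
    out["h1"] = dh1
    out["h2"] = dh2
    return out


# ---------------------------------------------------------------------------
# joint likelihood and Laplace approximation

def joint_nll(ps: ParameterSet, fl: FieldSet, data: ModelData) -> float:
    """Negative joint log-likelihood: observations plus GMRF field priors."""
    config = data.config
    fl.validate(config, len(data.grid))
    total = 0.0
    for comp in config.components:
        prob = _ComponentProblem(comp, ps, data, _component_R(comp, ps, data))
        total += prob.objective(fl.omega(comp), fl.eps(comp))
    return total


def joint_nll_grad_fields(ps: ParameterSet, fl: FieldSet, data: ModelData) -> FieldSet:
    """Analytic gradient of ``joint_nll`` with respect to every latent field."""
    config = data.config
    out = FieldSet.zeros(config, len(data.grid))
    for comp in config.components:
        prob = _ComponentProblem(comp, ps, data, _component_R(comp, ps, data))
        gW, gE = prob.grad(fl.omega(comp), fl.eps(comp))
        out.set_omega(comp, gW)
        out.set_eps(comp, gE)
    return out


def laplace_marginal_nll(ps: ParameterSet, data: ModelData,
                         inner_tol: Optional[float] = None,
                         warm_fields: Optional[FieldSet] = None):
    """Laplace-approximated marginal NLL over the fixed effects.

    Returns ``(value, field_modes, info)`` where ``info`` carries the
    per-component inner gradient norms and iteration counts.
    """
    config = data.config
    if inner_tol is None:
        inner_tol = config.inner_tol
    fields = (warm_fields or FieldSet.zeros(config, len(data.grid))).copy()
    total = 0.0
    info: Dict[str, dict] = {}
    for comp in config.components:
        prob = _ComponentProblem(comp, ps, data, _component_R(comp, ps, data))
        W, E, fact, f_mode, gnorm, n_iter = prob.solve(
            fields.omega(comp), fields.eps(comp), inner_tol)
        fields.set_omega(comp, W)
        fields.set_eps(comp, E)
        logdet = fact.logdet if fact is not None else 0.0
        total += f_mode + 0.5 * logdet - 0.5 * prob.n_u * np.log(2.0 * np.pi)
        info[comp] = {"grad_norm": gnorm, "iterations": n_iter,
                      "n_random": prob.n_u}
    return total, fields, info


def laplace_marginal_nll_grad(ps: ParameterSet, data: ModelData,
                              inner_tol: Optional[float] = None,
                              warm_fields: Optional[FieldSet] = None):
    """Laplace marginal NLL and its exact gradient in the packed parameters.

    Returns ``(value, gradient, field_modes, info)``.
    """
    config = data.config
    if inner_tol is None:
        inner_tol = config.inner_tol
    fields = (warm_fields or FieldSet.zeros(config, len(data.grid))).copy()
    idx = param_index(config)
    grad = np.zeros(idx["__total__"].stop)
    total = 0.0
    info: Dict[str, dict] = {}
    for comp in config.components:
        prob = _ComponentProblem(comp, ps, data, _component_R(comp, ps, data))
        W, E, fact, f_mode, gnorm, n_iter = prob.solve(
            fields.omega(comp), fields.eps(comp), inner_tol)
        fields.set_omega(comp, W)
        fields.set_eps(comp, E)
        logdet = fact.logdet if fact is not None else 0.0
        total += f_mode + 0.5 * logdet - 0.5 * prob.n_u * np.log(2.0 * np.pi)
        info[comp] = {"grad_norm": gnorm, "iterations": n_iter,
                      "n_random": prob.n_u}
        dR = _spatial_derivatives(comp, ps, data)
        blocks = prob.gradient_blocks(fact, W, E, dR)
        for name, g in blocks.items():
            if name in ("h1", "h2"):
                sl = idx.get("h")
                if sl is not None:
                    grad[sl.start + (0 if name == "h1" else 1)] += float(g[0])
            elif name in idx:
                grad[idx[name]] += g
    return total, grad, fields, info


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitResult:
    """Estimates, predicted field modes and fit diagnostics."""

    config: ModelConfig
    data: ModelData
    params: ParameterSet
    fields: FieldSet
    x: np.ndarray                      # packed fixed effects at the optimum
    index: Dict[str, slice]
    nll: float
    aic: float
    bic: float
    n_fixed: int
    n_obs: int
    converged: bool
    grad_norm: float
    n_outer_iter: int
    message: str = ""
    param_cov: Optional[np.ndarray] = None
    hessian_pd: Optional[bool] = None
    inner_info: dict = field(default_factory=dict)

    @property
    def se(self) -> Optional[np.ndarray]:
        if self.param_cov is None:
            return None
        return np.sqrt(np.maximum(np.diag(self.param_cov), 0.0))

    def se_block(self, name: str) -> Optional[np.ndarray]:
        if self.param_cov is None or name not in self.index:
            return None
        return self.se[self.index[name]]


def _initial_params(data: ModelData, rng: np.random.Generator) -> ParameterSet:
    """Moment-based starting values: empirical rates, small random loadings."""
    config = data.config
    ps = ParameterSet.zeros(config)
    S, T = config.n_species, config.n_years
    pos = data.positive
    # density on the offset scale: catch per unit of the applied offset
    if config.offset_policy in ("offset", "covariate"):
        dens = data.catch / np.exp(data.log_area)
    else:
        dens = data.catch
    for c in range(S):
        for t in range(T):
            m = (data.species_idx == c) & (data.year_idx == t)
            if config.family == "delta_gamma":
                rate = data.catch[m] > 0 if m.any() else np.array([0.5])
                pr = np.clip(np.mean(rate), 0.02, 0.98)
                ps.beta_p[c, t] = np.log(pr / (1 - pr))
                mp = m & pos
                mean_dens = np.mean(dens[mp]) if mp.any() else np.nan
                ps.beta_r[c, t] = np.log(mean_dens) if np.isfinite(mean_dens) \
                    and mean_dens > 0 else 0.0
            else:
                mean_dens = np.mean(dens[m]) if m.any() else np.nan
                ps.beta_r[c, t] = mean_dens if np.isfinite(mean_dens) else 0.0
    for kind in ("omega", "eps"):
        for comp in config.components:
            F = config.n_factors(kind, comp)
            L = np.zeros((S, F))
            r, c = tril_indices(S, F)
            L[r, c] = 0.1 * rng.standard_normal(len(r))
            setattr(ps, f"L_{kind}_{comp}", L)
    # kappa such that correlation is ~10% at half the domain diameter
    diam = float(np.hypot(data.grid.x.max() - data.grid.x.min(),
                          data.grid.y.max() - data.grid.y.min()))
    kappa0 = 8.0 / max(diam, 1e-6)
    ps.kappa_p = ps.kappa_r = kappa0
    ps.h1 = ps.h2 = 0.0
    if config.family == "gaussian":
        ps.log_sigma = float(np.log(np.std(data.catch) + 1e-6))
    return ps


def _fd_hessian_from_grad(grad_fun, x: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Central finite differences of an (exact) gradient; symmetrised."""
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = steps[i]
        H[i] = (grad_fun(x + e) - grad_fun(x - e)) / (2.0 * steps[i])
    return 0.5 * (H + H.T)


def _covariance_from_hessian(H: np.ndarray):
    """Invert an outer Hessian; fall back to a magnitude-eigenvalue
    pseudo-inverse if indefinite (flagged).

    Near symmetry points (e.g. loadings close to zero, where the
    objective is invariant to column sign flips) the outer Hessian can
    have negative curvature directions; inverting eigenvalue magnitudes
    keeps the implied uncertainty in those directions large but finite
    without letting any single clipped direction dominate the draws.
    """
    try:
        c = cho_factor(H, lower=True)
        return cho_solve(c, np.eye(H.shape[0])), True
    except np.linalg.LinAlgError:
        pass
    w, U = np.linalg.eigh(H)
    w_floor = max(1e-8, 1e-10 * float(np.abs(w).max()))
    w_clip = np.maximum(np.abs(w), w_floor)
    return (U / w_clip) @ U.T, False


def fit(data: ModelData, init: Optional[ParameterSet] = None,
        se: bool = False, seed: Optional[int] = None,
        maxiter: Optional[int] = None, gtol: float = 1e-3) -> FitResult:
    """Maximise the Laplace marginal likelihood over all fixed effects.

    The outer optimiser is L-BFGS-B with the exact gradient of the
    Laplace objective; the inner field optimisation is warm-started
    between evaluations.  ``se=True`` adds a finite-difference Hessian
    of the outer gradient; if it is indefinite the covariance comes from
    an eigenvalue-clipped pseudo-inverse and ``hessian_pd`` is False.
    """
    config = data.config
    if config.n_years < 2 and (config.n_factors_eps_p or config.n_factors_eps_r):
        raise ValueError("spatiotemporal factors require at least 2 years of data")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ps0 = init if init is not None else _initial_params(data, rng)
    x0 = pack_params(ps0, config)
    idx = param_index(config)
    warm = {"fields": None}

    def objective(x: np.ndarray):
        try:
            ps = unpack_params(x, config)
            val, g, fields, _ = laplace_marginal_nll_grad(
                ps, data, warm_fields=warm["fields"])
            if not np.isfinite(val):
                return 1e10, np.zeros_like(x)
            warm["fields"] = fields
            return val, g
        except (np.linalg.LinAlgError, RuntimeError, FloatingPointError,
                ValueError):
            return 1e10, np.zeros_like(x)

    res = minimize(objective, x0, method="L-BFGS-B", jac=True,
                   options={"maxiter": maxiter or config.maxiter,
                            "maxfun": 50 * (maxiter or config.maxiter),
                            "ftol": 1e-12, "gtol": gtol})
    x_hat = res.x
    ps_raw = unpack_params(x_hat, config)
    ps_hat = ps_raw.canonicalized()
    # flip warm-start field columns along with the canonicalized loadings
    warm_canon = warm["fields"].copy() if warm["fields"] is not None else None
    if warm_canon is not None:
        for kind in ("omega", "eps"):
            for comp in config.components:
                L_old = ps_raw.loading(kind, comp)
                L_new = ps_hat.loading(kind, comp)
                for f in range(L_old.shape[1]):
                    if f < L_old.shape[0] and L_old[f, f] < 0 and L_new[f, f] > 0:
                        if kind == "omega":
                            warm_canon.omega(comp)[:, f] *= -1.0
                        else:
                            warm_canon.eps(comp)[:, f, :] *= -1.0
    nll, fields, inner_info = laplace_marginal_nll(ps_hat, data,
                                                   warm_fields=warm_canon)
    n_fixed = len(x_hat)
    n_obs = data.n_obs
    aic = 2.0 * n_fixed + 2.0 * nll
    bic = np.log(n_obs) * n_fixed + 2.0 * nll
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan

    param_cov = None
    hessian_pd = None
    if se:
        steps = 1e-4 * np.maximum(1.0, np.abs(x_hat))

        def grad_only(x):
            return objective(x)[1]

        H = _fd_hessian_from_grad(grad_only, x_hat, steps)
        param_cov, hessian_pd = _covariance_from_hessian(H)
        if not hessian_pd:
            warnings.warn("outer Hessian not positive definite; standard errors "
                          "use an eigenvalue-clipped pseudo-inverse", stacklevel=2)

    return FitResult(
        config=config, data=data, params=ps_hat, fields=fields, x=x_hat,
        index=idx, nll=float(nll), aic=float(aic), bic=float(bic),
        n_fixed=n_fixed, n_obs=n_obs,
        converged=bool(res.success), grad_norm=grad_norm,
        n_outer_iter=int(res.nit), message=str(res.message),
        param_cov=param_cov, hessian_pd=hessian_pd, inner_info=inner_info,
    )


def information_criteria(fit_result: FitResult):
    """(AIC, BIC) with ``n_obs`` = number of haul x species rows."""
    k, nll = fit_result.n_fixed, fit_result.nll
    return (2.0 * k + 2.0 * nll,
            np.log(fit_result.n_obs) * k + 2.0 * nll)
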