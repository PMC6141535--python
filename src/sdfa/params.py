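"""Parameter and latent-field containers, and the packing used by the optimizer.

``ParameterSet`` holds every fixed effect: species-by-year intercepts for
both components, the four factor-loading matrices, survey-catchability
effects, per-species gamma shapes and the Matérn/anisotropy parameters.
``FieldSet`` holds the latent factor values at knots: spatial factors
``omega`` (knots x factors) and spatiotemporal factors ``eps``
(knots x factors x years).  Factor fields have unit marginal variance by
construction; the loadings carry scale, so the species-level field for a
component has among-species covariance L L'.

Packing maps the free fixed effects to/from a flat vector for the outer
optimizer: loadings are lower-triangular (rotational identifiability),
the first survey's catchability is the reference level (fixed at 0), and
positivity-constrained parameters (gamma shapes, Matérn kappas, the
Gaussian sigma) travel on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .config import ModelConfig
from .gmrf import MaternParams

__all__ = ["ParameterSet", "FieldSet", "pack_params", "unpack_params", "param_index"]


def tril_indices(n_species: int, n_factors: int):
    """Row/col indices of the free (lower-triangular) loading entries."""
    rows, cols = np.tril_indices(n_species, k=0)
    keep = cols < n_factors
    return rows[keep], cols[keep]


@dataclass
class ParameterSet:
    """All fixed effects of the model (see module docstring)."""

    beta_p: Optional[np.ndarray]          # (S, T) or None for gaussian family
    beta_r: np.ndarray                    # (S, T)
    L_omega_p: np.ndarray                 # (S, F) lower-triangular
    L_eps_p: np.ndarray
    L_omega_r: np.ndarray
    L_eps_r: np.ndarray
    delta_p: np.ndarray                   # (n_surveys,), [0] == 0 reference
    delta_r: np.ndarray
    log_k: np.ndarray                     # (S,) gamma shape, log scale
    kappa_p: float
    kappa_r: float
    h1: float = 0.0
    h2: float = 0.0
    log_sigma: float = 0.0                # gaussian family only
    area_coef_r: float = 1.0              # estimated under offset_policy="covariate"

    def matern(self, comp: str, nu: float = 1.0) -> MaternParams:
        kappa = self.kappa_p if comp == "p" else self.kappa_r
        return MaternParams(kappa=kappa, nu=nu, h1=self.h1, h2=self.h2)

    def loading(self, kind: str, comp: str) -> np.ndarray:
        return getattr(self, f"L_{kind}_{comp}")

    def beta(self, comp: str) -> np.ndarray:
        return self.beta_p if comp == "p" else self.beta_r

    def delta(self, comp: str) -> np.ndarray:
        return self.delta_p if comp == "p" else self.delta_r

    @property
    def k(self) -> np.ndarray:
        return np.exp(self.log_k)

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma))

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            beta_p=None if self.beta_p is None else self.beta_p.copy(),
            beta_r=self.beta_r.copy(),
            L_omega_p=self.L_omega_p.copy(), L_eps_p=self.L_eps_p.copy(),
            L_omega_r=self.L_omega_r.copy(), L_eps_r=self.L_eps_r.copy(),
            delta_p=self.delta_p.copy(), delta_r=self.delta_r.copy(),
            log_k=self.log_k.copy(), kappa_p=self.kappa_p, kappa_r=self.kappa_r,
            h1=self.h1, h2=self.h2, log_sigma=self.log_sigma,
            area_coef_r=self.area_coef_r,
        )

    @classmethod
    def zeros(cls, config: ModelConfig) -> "ParameterSet":
        S, T, V = config.n_species, config.n_years, config.n_surveys
        has_p = config.family == "delta_gamma"
        return cls(
            beta_p=np.zeros((S, T)) if has_p else None,
            beta_r=np.zeros((S, T)),
            L_omega_p=np.zeros((S, config.n_factors_omega_p)),
            L_eps_p=np.zeros((S, config.n_factors_eps_p)),
            L_omega_r=np.zeros((S, config.n_factors_omega_r)),
            L_eps_r=np.zeros((S, config.n_factors_eps_r)),
            delta_p=np.zeros(V), delta_r=np.zeros(V),
            log_k=np.zeros(S),
            kappa_p=config.sim.kappa_p, kappa_r=config.sim.kappa_r,
        )

    def canonicalized(self) -> "ParameterSet":
        """Flip loading columns so diagonal entries are non-negative.

        The likelihood is invariant to sign flips of whole factor
        columns (the field column flips with it), so this enforces the
        non-negative-diagonal identifiability convention losslessly.
        """
        out = self.copy()
        for name in ("L_omega_p", "L_eps_p", "L_omega_r", "L_eps_r"):
            L = getattr(out, name)
            for f in range(L.shape[1]):
                if f < L.shape[0] and L[f, f] < 0:
                    L[:, f] = -L[:, f]
        return out

    def to_dict(self) -> dict:
        d = {}
        for name in ("beta_p", "beta_r", "L_omega_p", "L_eps_p", "L_omega_r",
                     "L_eps_r", "delta_p", "delta_r", "log_k"):
            v = getattr(self, name)
            d[name] = None if v is None else np.asarray(v).tolist()
        for name in ("kappa_p", "kappa_r", "h1", "h2", "log_sigma", "area_coef_r"):
            d[name] = float(getattr(self, name))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        arr = {k: (None if d[k] is None else np.asarray(d[k], dtype=float))
               for k in ("beta_p", "beta_r", "L_omega_p", "L_eps_p", "L_omega_r",
                         "L_eps_r", "delta_p", "delta_r", "log_k")}
        scal = {k: float(d[k]) for k in ("kappa_p", "kappa_r", "h1", "h2",
                                         "log_sigma", "area_coef_r")}
        return cls(**arr, **scal)


@dataclass
class FieldSet:
    """Latent factor values at knots for both components."""

    omega_p: np.ndarray                   # (K, F_omega_p)
    eps_p: np.ndarray                     # (K, F_eps_p, T)
    omega_r: np.ndarray
    eps_r: np.ndarray

    def omega(self, comp: str) -> np.ndarray:
        return self.omega_p if comp == "p" else self.omega_r

    def eps(self, comp: str) -> np.ndarray:
        return self.eps_p if comp == "p" else self.eps_r

    def set_omega(self, comp: str, value: np.ndarray) -> None:
        setattr(self, f"omega_{comp}", value)

    def set_eps(self, comp: str, value: np.ndarray) -> None:
        setattr(self, f"eps_{comp}", value)

    def copy(self) -> "FieldSet":
        return FieldSet(self.omega_p.copy(), self.eps_p.copy(),
                        self.omega_r.copy(), self.eps_r.copy())

    def validate(self, config: ModelConfig, n_knots: int) -> None:
        K, T = n_knots, config.n_years
        expect = {
            "omega_p": (K, config.n_factors_omega_p),
            "eps_p": (K, config.n_factors_eps_p, T),
            "omega_r": (K, config.n_factors_omega_r),
            "eps_r": (K, config.n_factors_eps_r, T),
        }
        for name, shape in expect.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @classmethod
    def zeros(cls, config: ModelConfig, n_knots: int) -> "FieldSet":
        K, T = n_knots, config.n_years
        return cls(
            omega_p=np.zeros((K, config.n_factors_omega_p)),
            eps_p=np.zeros((K, config.n_factors_eps_p, T)),
            omega_r=np.zeros((K, config.n_factors_omega_r)),
            eps_r=np.zeros((K, config.n_factors_eps_r, T)),
        )


# ---------------------------------------------------------------------------
# packing for the outer optimizer

def param_index(config: ModelConfig) -> Dict[str, slice]:
    """Slices of each free fixed-effect block in the packed vector."""
    S, T, V = config.n_species, config.n_years, config.n_surveys
    has_p = config.family == "delta_gamma"
    idx: Dict[str, slice] = {}
    pos = 0

    def add(name: str, size: int):
        nonlocal pos
        if size > 0:
            idx[name] = slice(pos, pos + size)
            pos += size

    if has_p:
        add("beta_p", S * T)
    add("beta_r", S * T)
    if has_p:
        add("L_omega_p", len(tril_indices(S, config.n_factors_omega_p)[0]))
        add("L_eps_p", len(tril_indices(S, config.n_factors_eps_p)[0]))
    add("L_omega_r", len(tril_indices(S, config.n_factors_omega_r)[0]))
    add("L_eps_r", len(tril_indices(S, config.n_factors_eps_r)[0]))
    if has_p:
        add("delta_p", V - 1)
    add("delta_r", V - 1)
    if has_p:
        add("log_k", S)
        add("log_kappa_p", 1)
    add("log_kappa_r", 1)
    add("h", 2)
    if not has_p:
        add("log_sigma", 1)
    if config.offset_policy == "covariate":
        add("area_coef_r", 1)
    idx["__total__"] = slice(0, pos)
    return idx


def pack_params(ps: ParameterSet, config: ModelConfig) -> np.ndarray:
    idx = param_index(config)
    x = np.zeros(idx["__total__"].stop)
    S = config.n_species

    def put(name: str, values):
        if name in idx:
            x[idx[name]] = np.asarray(values, dtype=float).ravel()

    put("beta_p", ps.beta_p if ps.beta_p is not None else [])
    put("beta_r", ps.beta_r)
    for kind in ("omega", "eps"):
        for comp in config.components:
            name = f"L_{kind}_{comp}"
            r, c = tril_indices(S, config.n_factors(kind, comp))
            put(name, ps.loading(kind, comp)[r, c])
    put("delta_p", ps.delta_p[1:])
    put("delta_r", ps.delta_r[1:])
    put("log_k", ps.log_k)
    put("log_kappa_p", [np.log(ps.kappa_p)])
    put("log_kappa_r", [np.log(ps.kappa_r)])
    put("h", [ps.h1, ps.h2])
    put("log_sigma", [ps.log_sigma])
    put("area_coef_r", [ps.area_coef_r])
    return x


def unpack_params(x: np.ndarray, config: ModelConfig) -> ParameterSet:
    idx = param_index(config)
    S, T, V = config.n_species, config.n_years, config.n_surveys
    ps = ParameterSet.zeros(config)

    def get(name: str):
        return x[idx[name]] if name in idx else None

    if (b := get("beta_p")) is not None:
        ps.beta_p = b.reshape(S, T).copy()
    ps.beta_r = get("beta_r").reshape(S, T).copy()
    for kind in ("omega", "eps"):
        for comp in config.components:
            name = f"L_{kind}_{comp}"
            F = config.n_factors(kind, comp)
            L = np.zeros((S, F))
            if (v := get(name)) is not None:
                r, c = tril_indices(S, F)
                L[r, c] = v
            setattr(ps, name, L)
    for comp, attr in (("p", "delta_p"), ("r", "delta_r")):
        d = np.zeros(V)
        if (v := get(attr)) is not None:
            d[1:] = v
        setattr(ps, attr, d)
    if (v := get("log_k")) is not None:
        ps.log_k = v.copy()
    if (v := get("log_kappa_p")) is not None:
        ps.kappa_p = float(np.exp(v[0]))
    ps.kappa_r = float(np.exp(get("log_kappa_r")[0]))
    ps.h1, ps.h2 = (float(h) for h in get("h"))
    if (v := get("log_sigma")) is not None:
        ps.log_sigma = float(v[0])
    if (v := get("area_coef_r")) is not None:
        ps.area_coef_r = float(v[0])
    return ps
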