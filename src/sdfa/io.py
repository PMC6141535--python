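"""Readers, writers and survey preprocessing.

Station-catch tables travel as long-format CSV (one row per haul x
species, zeros explicit); knot grids as CSV; simulation truths and fit
results as JSON (parameters) plus CSV (latent fields).  Readers validate
rather than coerce: negative catches, missing columns or non-numeric
fields are rejected with the offending 1-based data-row numbers.

Preprocessing mirrors standard trawl-survey practice: station filtering
against explicit plausibility rules, allometric length-weight conversion
``W = a L^b``, and aggregation of length samples into juvenile/adult
size classes at a per-species cutoff length (at-cutoff fish count as
adult).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import ModelConfig
from .params import FieldSet, ParameterSet
from .synthetic import STATION_COLUMNS, KnotGrid, SimulationTruth

__all__ = [
    "read_station_table", "write_station_table", "read_knot_grid",
    "write_knot_grid", "write_truth", "read_truth", "save_fit_params",
    "load_fit", "filter_stations", "length_to_weight", "fit_length_weight",
    "SizeClassRule", "aggregate_size_classes", "lonlat_to_km",
]


# ---------------------------------------------------------------------------
# coordinates

#: kilometres per degree of latitude (spherical earth)
KM_PER_DEG_LAT = 111.195


def lonlat_to_km(lon, lat, lon0: float, lat0: float):
    """Equirectangular projection of lon/lat to planar km about (lon0, lat0).

    Adequate at the ~100 km correlation scales of a shelf-sea domain;
    the projection origin and central latitude should be recorded with
    any files written in these coordinates.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = (lon - lon0) * KM_PER_DEG_LAT * np.cos(np.deg2rad(lat0))
    y = (lat - lat0) * KM_PER_DEG_LAT
    return x, y


# ---------------------------------------------------------------------------
# station tables

def read_station_table(path) -> pd.DataFrame:
    """Read and validate a long-format station-catch CSV."""
    df = pd.read_csv(path)
    missing = set(STATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x_km", "y_km", "year", "swept_area_km2", "catch_kg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.where(vals.isna() & df[col].notna())[0]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col} on data row(s) {[int(b) + 1 for b in bad[:5]]}")
        df[col] = vals
    neg = np.where(df["catch_kg"].to_numpy() < 0)[0]
    if len(neg):
        raise ValueError(
            f"{path}: negative catch_kg on data row(s) {[int(b) + 1 for b in neg[:5]]}")
    nonpos = np.where(df["swept_area_km2"].to_numpy() <= 0)[0]
    if len(nonpos):
        raise ValueError(
            f"{path}: non-positive swept_area_km2 on data row(s) "
            f"{[int(b) + 1 for b in nonpos[:5]]}")
    return df[STATION_COLUMNS]


def write_station_table(df: pd.DataFrame, path) -> None:
    df[STATION_COLUMNS].to_csv(path, index=False)


def read_knot_grid(path) -> KnotGrid:
    return KnotGrid.from_frame(pd.read_csv(path))


def write_knot_grid(grid: KnotGrid, path) -> None:
    grid.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# simulation truth round-trip

def _fields_to_frame(fields: FieldSet) -> pd.DataFrame:
    rows = []
    for comp in ("p", "r"):
        W = fields.omega(comp)
        for f in range(W.shape[1]):
            for k in range(W.shape[0]):
                rows.append(("omega", comp, k, f, -1, W[k, f]))
        E = fields.eps(comp)
        for t in range(E.shape[2]):
            for f in range(E.shape[1]):
                for k in range(E.shape[0]):
                    rows.append(("eps", comp, k, f, t, E[k, f, t]))
    return pd.DataFrame(rows, columns=["kind", "component", "knot", "factor",
                                       "year_index", "value"])


def _fields_from_frame(df: pd.DataFrame, config: ModelConfig,
                       n_knots: int) -> FieldSet:
    fields = FieldSet.zeros(config, n_knots)
    for _, row in df.iterrows():
        comp, k, f = row["component"], int(row["knot"]), int(row["factor"])
        if row["kind"] == "omega":
            fields.omega(comp)[k, f] = row["value"]
        else:
            fields.eps(comp)[k, f, int(row["year_index"])] = row["value"]
    return fields


def write_truth(truth: SimulationTruth, out_dir) -> None:
    """Serialise a simulation truth: JSON parameters + CSV fields/grid."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "config": truth.config.to_dict(),
        "params": truth.params.to_dict(),
        "seed": truth.seed,
        "assemblage_map": truth.assemblage_map,
        "species": list(truth.species),
    }
    (out / "truth.json").write_text(json.dumps(doc, indent=1))
    _fields_to_frame(truth.fields).to_csv(out / "truth_fields.csv", index=False)
    write_knot_grid(truth.grid, out / "knots.csv")


def read_truth(in_dir) -> SimulationTruth:
    src = Path(in_dir)
    doc = json.loads((src / "truth.json").read_text())
    config = ModelConfig.from_dict(doc["config"])
    grid = read_knot_grid(src / "knots.csv")
    fields = _fields_from_frame(pd.read_csv(src / "truth_fields.csv"),
                                config, len(grid))
    return SimulationTruth(
        config=config, grid=grid,
        params=ParameterSet.from_dict(doc["params"]),
        fields=fields, seed=doc["seed"],
        assemblage_map={k: int(v) for k, v in doc["assemblage_map"].items()},
        species=doc["species"],
    )


def save_fit_params(fit_result, out_dir) -> None:
    """Write fitted parameters, field modes and diagnostics to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "config": fit_result.config.to_dict(),
        "params": fit_result.params.to_dict(),
        "species": list(fit_result.data.species),
        "surveys": [int(s) for s in fit_result.data.surveys],
        "nll": fit_result.nll, "aic": fit_result.aic, "bic": fit_result.bic,
        "n_fixed": fit_result.n_fixed, "n_obs": fit_result.n_obs,
        "converged": fit_result.converged, "grad_norm": fit_result.grad_norm,
        "n_outer_iter": fit_result.n_outer_iter,
        "hessian_pd": fit_result.hessian_pd,
        "start_year": int(fit_result.data.start_year),
    }
    (out / "fit.json").write_text(json.dumps(doc, indent=1))
    _fields_to_frame(fit_result.fields).to_csv(out / "fit_fields.csv", index=False)
    if fit_result.param_cov is not None:
        np.savetxt(out / "param_cov.csv", fit_result.param_cov, delimiter=",")


def load_fit(fit_dir, knots_path=None):
    """Rebuild a prediction-capable fit object from ``save_fit_params`` output.

    The returned ``FitResult`` carries parameters, field modes and the
    grid/species/survey coding (with an empty observation block); it
    supports every prediction and summary operation that does not need
    the raw observations.
    """
    from .model import FitResult, ModelData
    from .params import pack_params, param_index

    src = Path(fit_dir)
    doc = json.loads((src / "fit.json").read_text())
    config = ModelConfig.from_dict(doc["config"])
    grid = read_knot_grid(knots_path if knots_path is not None
                          else src.parent / "knots.csv")
    params = ParameterSet.from_dict(doc["params"])
    fields = _fields_from_frame(pd.read_csv(src / "fit_fields.csv"),
                                config, len(grid))
    S, V = config.n_species, config.n_surveys
    empty = np.zeros(0, dtype=int)
    data = ModelData(
        config=config, grid=grid, species=list(doc["species"]),
        surveys=list(doc["surveys"]), knot_idx=empty, year_idx=empty,
        species_idx=empty, survey_idx=empty, log_area=np.zeros(0),
        catch=np.zeros(0), start_year=int(doc["start_year"]),
        Q_p=np.ones((S, V)), Q_r=np.ones((S, V)),
    )
    cov_path = src / "param_cov.csv"
    cov = np.loadtxt(cov_path, delimiter=",") if cov_path.exists() else None
    if cov is not None and cov.ndim == 0:
        cov = cov.reshape(1, 1)
    x = pack_params(params, config)
    return FitResult(
        config=config, data=data, params=params, fields=fields, x=x,
        index=param_index(config), nll=float(doc["nll"]),
        aic=float(doc["aic"]), bic=float(doc["bic"]),
        n_fixed=int(doc["n_fixed"]), n_obs=int(doc["n_obs"]),
        converged=bool(doc["converged"]), grad_norm=float(doc["grad_norm"]),
        n_outer_iter=int(doc["n_outer_iter"]), param_cov=cov,
        hessian_pd=doc.get("hessian_pd"),
    )


# ---------------------------------------------------------------------------
# station filtering

def filter_stations(table: pd.DataFrame, rules: Optional[dict] = None
                    ) -> Tuple[pd.DataFrame, dict]:
    """Remove hauls violating explicit plausibility rules.

    ``rules`` has two optional keys: ``"bounds"`` mapping column ->
    (lo, hi) inclusive plausibility bounds, and ``"required"`` listing
    columns that must be non-missing.  Any violating row removes its
    whole haul.  Returns the kept table and a report with per-rule row
    counts; kept plus rejected rows partition the input.
    """
    rules = rules or {}
    viol = np.zeros(len(table), dtype=bool)
    report: Dict[str, int] = {}
    for col in rules.get("required", []):
        if col not in table.columns:
            raise ValueError(f"required column {col!r} absent from table")
        bad = table[col].isna().to_numpy()
        report[f"missing_{col}"] = int(bad.sum())
        viol |= bad
    for col, (lo, hi) in rules.get("bounds", {}).items():
        if col not in table.columns:
            raise ValueError(f"bounded column {col!r} absent from table")
        vals = pd.to_numeric(table[col], errors="coerce").to_numpy()
        bad = np.isnan(vals) | (vals < lo) | (vals > hi)
        report[f"bounds_{col}"] = int(bad.sum())
        viol |= bad
    bad_hauls = set(table.loc[viol, "haul_id"]) if "haul_id" in table.columns else set()
    drop = table["haul_id"].isin(bad_hauls).to_numpy() if bad_hauls else viol
    kept = table.loc[~drop].copy()
    report["rows_flagged"] = int(viol.sum())
    report["rows_removed"] = int(drop.sum())
    report["hauls_removed"] = len(bad_hauls)
    report["rows_kept"] = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# length-weight and size classes

def length_to_weight(length, a: float, b: float):
    """Allometric length-weight conversion ``W = a * L^b``."""
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("lengths must be positive")
    out = a * length**b
    return float(out) if out.ndim == 0 else out


def fit_length_weight(lengths, weights) -> Tuple[float, float]:
    """Estimate (a, b) of ``W = a L^b`` by log-log least squares."""
    lengths = np.asarray(lengths, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(lengths <= 0) or np.any(weights <= 0):
        raise ValueError("lengths and weights must be positive")
    b, log_a = np.polyfit(np.log(lengths), np.log(weights), 1)
    return float(np.exp(log_a)), float(b)


@dataclass
class SizeClassRule:
    """Juvenile/adult split at each species' minimum conservation
    reference size; fish at exactly the cutoff count as adult."""

    cutoffs: Dict[str, float]

    def __post_init__(self) -> None:
        for sp, cut in self.cutoffs.items():
            if not (np.isfinite(cut) and cut > 0):
                raise ValueError(f"cutoff for {sp!r} must be positive")

    def classify(self, species: str, length: float) -> str:
        return "adult" if length >= self.cutoffs[species] else "juvenile"


def aggregate_size_classes(lengths: pd.DataFrame, rule: SizeClassRule,
                           ab: Dict[str, Tuple[float, float]]) -> pd.DataFrame:
    """Aggregate length samples into juvenile/adult biomass per haul x species.

    ``lengths`` needs columns haul_id, species, length_cm and optionally
    count (default 1).  Biomass is conserved: juvenile + adult equals the
    total length-weight biomass.
    """
    for sp in lengths["species"].unique():
        if sp not in rule.cutoffs:
            raise ValueError(f"species {sp!r} has no size-class cutoff")
        if sp not in ab:
            raise ValueError(f"species {sp!r} has no length-weight coefficients")
    df = lengths.copy()
    count = df["count"] if "count" in df.columns else 1.0
    a = df["species"].map({s: v[0] for s, v in ab.items()})
    b = df["species"].map({s: v[1] for s, v in ab.items()})
    df["biomass"] = a * df["length_cm"].astype(float) ** b * count
    cut = df["species"].map(rule.cutoffs)
    df["size_class"] = np.where(df["length_cm"].astype(float) >= cut,
                                "adult", "juvenile")
    out = (df.groupby(["haul_id", "species", "size_class"], sort=True)["biomass"]
             .sum().reset_index())
    return out
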