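"""Per-region driver selection, mosaicking, and perturbation sensitivity.

The driver search is a deterministic greedy backward elimination: starting
from the full candidate set, each single-driver removal is retrained and
scored, the removal with the highest aggregate score P is kept, and the
process iterates down to one driver. Every evaluated spec is logged in a
catalog. The "minimal model" is the fewest-driver spec whose score is
within 3.0 points of the best; vegetation-type fractions (including
cropland) are always part of the inputs and are never candidates for
removal.

Sensitivity analysis perturbs one driver in raw units (temperature
additively, e.g. +1 degC; vapour pressure multiplicatively, e.g. x1.01),
re-standardizes, and re-predicts: S = dBA/dT per cell-month, reported as
per-cell annual means, and S_pct = 100 * S / BA. Vegetation fractions are
held fixed under the perturbation.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import FeatureSpec, LOG_TRANSFORMED, log1p_transform
from .grid import GridSpec, MonthlyField, VegetationFractions, KM2_PER_MHA
from .metrics import MetricReport, MetricWeights, aggregate_score, compute_metrics
from .model import (BurnedAreaModel, TrainConfig, fit_burned_area_model,
                    predict_field)

logger = logging.getLogger(__name__)

MINIMAL_MODEL_TOLERANCE = 3.0  # max P loss accepted for a smaller model


@dataclass
class RegionData:
    """Everything the search needs for one region: the assembled feature
    matrix (all candidate columns present), the observed burned-area field,
    the region's cell mask, and a fixed train/val/test split shared by every
    candidate spec."""

    region: str
    df: pd.DataFrame
    obs: MonthlyField
    mask: np.ndarray
    split: dict


@dataclass
class CatalogEntry:
    drivers: tuple
    model: BurnedAreaModel
    report: MetricReport
    score: float


@dataclass
class ModelCatalog:
    """Every spec evaluated during a region's search, in evaluation order."""

    region: str
    entries: list = field(default_factory=list)

    def best(self) -> CatalogEntry:
        # highest P; ties toward fewer drivers, then lexicographic spec order
        return max(self.entries,
                   key=lambda e: (e.score, -len(e.drivers),
                                  tuple(-ord(c) for c in ",".join(e.drivers))))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            r = e.report
            rows.append({
                "region": self.region, "n_drivers": len(e.drivers),
                "r_T": r.r_T, "r_IA": r.r_IA, "r_S": r.r_S,
                "BA": r.BA_pred_total, "LT": r.LT_pred, "r_An": r.r_An,
                "r_BA": r.r_BA, "r_I": r.r_I, "P": e.score,
                "variables": ", ".join(e.drivers),
            })
        return pd.DataFrame(rows)


def _spec_seed(base_seed: int, region: str, drivers) -> int:
    """Stable per-spec training seed (crc32; independent of process hashing)."""
    key = f"{base_seed}|{region}|{','.join(drivers)}".encode()
    return zlib.crc32(key) % (2 ** 31)


def _evaluate_spec(data: RegionData, drivers, base_columns, train_config,
                   weights, area_weighting) -> CatalogEntry:
    features = list(drivers) + base_columns
    cfg = replace(train_config,
                  seed=_spec_seed(train_config.seed, data.region, drivers))
    model = fit_burned_area_model(data.df, data.split, cfg,
                                  features=features, region=data.region)
    pred = predict_field(model, data.df, data.obs.grid,
                         data.obs.years, data.obs.months)
    report = compute_metrics(pred, data.obs, data.mask, weights,
                             area_weighting=area_weighting)
    return CatalogEntry(tuple(drivers), model, report,
                        aggregate_score(report, weights))


def search_models(data: RegionData, candidate_drivers,
                  train_config: TrainConfig,
                  weights: MetricWeights | None = None,
                  area_weighting: bool = True) -> ModelCatalog:
    """Greedy backward elimination over driver subsets for one region.

    Vegetation-fraction columns present in ``data.df`` are base features of
    every model. Deterministic given the training seed: each spec gets a
    seed derived from (seed, region, spec).
    """
    weights = weights or MetricWeights()
    if len(data.df) == 0:
        warnings.warn(f"region {data.region!r} has no samples: search skipped")
        return ModelCatalog(data.region)
    base_columns = [c for c in data.df.columns if c.startswith("veg_")]
    catalog = ModelCatalog(data.region)
    current = tuple(candidate_drivers)

    entry = _evaluate_spec(data, current, base_columns, train_config,
                           weights, area_weighting)
    catalog.entries.append(entry)
    logger.info("search[%s]: full set %s -> P=%.2f", data.region, current,
                entry.score)
    while len(current) > 1:
        trials = []
        for drop in current:
            remaining = tuple(d for d in current if d != drop)
            e = _evaluate_spec(data, remaining, base_columns, train_config,
                               weights, area_weighting)
            catalog.entries.append(e)
            trials.append(e)
        # keep the removal with highest P; ties lexicographic by spec
        best_trial = max(trials, key=lambda e: (e.score,
                                                tuple(-ord(c) for c in ",".join(e.drivers))))
        logger.info("search[%s]: drop -> %s P=%.2f", data.region,
                    best_trial.drivers, best_trial.score)
        current = best_trial.drivers
    return catalog


def minimal_model(catalog: ModelCatalog,
                  tolerance: float = MINIMAL_MODEL_TOLERANCE) -> CatalogEntry:
    """Fewest-driver entry within ``tolerance`` score points of the best.

    Ties at equal driver count go to the higher score.
    """
    if not catalog.entries:
        raise ValueError("empty catalog")
    p_best = max(e.score for e in catalog.entries)
    eligible = [e for e in catalog.entries if p_best - e.score <= tolerance]
    return min(eligible, key=lambda e: (len(e.drivers), -e.score,
                                        ",".join(e.drivers)))


def mosaic(regional_predictions, grid: GridSpec, years, months) -> MonthlyField:
    """Assemble a global field from per-region predictions on disjoint masks.

    ``regional_predictions`` is a list of ``(mask, MonthlyField)``. Cells in
    no region stay missing; overlapping masks are an error.
    """
    out = np.full((len(years), grid.n_lat, grid.n_lon), np.nan)
    claimed = np.zeros((grid.n_lat, grid.n_lon), dtype=bool)
    for mask, fld in regional_predictions:
        if np.any(claimed & mask):
            raise ValueError("overlapping region masks in mosaic")
        claimed |= mask
        out[:, mask] = fld.values[:, mask]
    return MonthlyField(grid, out, np.asarray(years), np.asarray(months),
                        "ba_mosaic", "fraction")


@dataclass
class SensitivityMap:
    """Perturbation sensitivity of predicted burned area.

    ``S`` is the per-cell annual-mean change in burned-area fraction per
    unit perturbation (fraction/degC for temperature); ``S_pct`` is
    100 * S / baseline BA (NaN where the baseline is zero); ``monthly_S``
    retains the per-(time, cell) values.
    """

    grid: GridSpec
    S: np.ndarray  # (lat, lon)
    S_pct: np.ndarray  # (lat, lon)
    monthly_S: np.ndarray  # (time, lat, lon)
    baseline: np.ndarray  # (lat, lon) annual-mean predicted BA
    variable: str
    delta: float


def _perturb_column(df: pd.DataFrame, variable: str, *, additive=None,
                    factor=None) -> pd.DataFrame:
    """Perturb one driver column in raw units.

    Log-transformed columns are inverted, perturbed, and re-transformed so
    the perturbation acts on physical values.
    """
    out = df.copy()
    col = df[variable].to_numpy(dtype=float)
    if variable in LOG_TRANSFORMED:
        raw = 10.0 ** col - 1.0
        raw = raw + additive if additive is not None else raw * factor
        out[variable] = log1p_transform(np.clip(raw, 0.0, None))
    else:
        out[variable] = col + additive if additive is not None else col * factor
    return out


def _sensitivity(model: BurnedAreaModel, df: pd.DataFrame, grid: GridSpec,
                 variable: str, perturbed: pd.DataFrame, delta: float,
                 eps_ba: float = 0.0) -> SensitivityMap:
    base = model.predict_ba(df)
    pert = model.predict_ba(perturbed)
    nt = int(df["time_idx"].max()) + 1
    monthly = np.full((nt, grid.n_lat, grid.n_lon), np.nan)
    base_grid = np.full((nt, grid.n_lat, grid.n_lon), np.nan)
    ti = df["time_idx"].to_numpy()
    ii = df["ilat"].to_numpy()
    jj = df["ilon"].to_numpy()
    if delta != 0:
        monthly[ti, ii, jj] = (pert - base) / delta
    else:
        monthly[ti, ii, jj] = 0.0
    base_grid[ti, ii, jj] = base
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        S = np.nanmean(monthly, axis=0)
        baseline = np.nanmean(base_grid, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        S_pct = np.where(baseline > eps_ba, 100.0 * S / baseline, np.nan)
    return SensitivityMap(grid, S, S_pct, monthly, baseline, variable, delta)


def temperature_sensitivity(model: BurnedAreaModel, df: pd.DataFrame,
                            grid: GridSpec, delta_t: float = 1.0) -> SensitivityMap:
    """S = (BA(T + dT) - BA(T)) / dT with all other drivers held fixed.

    The model must include temperature (``ts``); callers whose selected
    model dropped it should pass the next-best model that retains it.
    """
    if "ts" not in model.feature_names:
        raise ValueError(
            "model does not use 'ts'; supply a fallback model that includes it")
    perturbed = _perturb_column(df, "ts", additive=delta_t)
    return _sensitivity(model, df, grid, "ts", perturbed, delta_t)


def multiplicative_sensitivity(model: BurnedAreaModel, df: pd.DataFrame,
                               grid: GridSpec, variable: str,
                               factor: float = 1.01) -> SensitivityMap:
    """Sensitivity to a relative perturbation (default +1%) of one driver.

    S is reported per 1% change of the variable.
    """
    if variable not in model.feature_names:
        raise ValueError(
            f"model does not use {variable!r}; supply a fallback model")
    perturbed = _perturb_column(df, variable, factor=factor)
    delta_pct = (factor - 1.0) * 100.0
    return _sensitivity(model, df, grid, variable, perturbed, delta_pct)


def aggregate_sensitivity_by_vegtype(smap: SensitivityMap,
                                     veg: VegetationFractions,
                                     dominance_threshold: float = 0.5,
                                     flat_area: bool = False) -> pd.DataFrame:
    """Tabulate sensitivity by dominant vegetation type.

    A cell's type is the vegetation class with the largest fraction if that
    fraction is at least ``dominance_threshold``, else "mixed vegetation".
    Rows report cell count, total baseline burned area (Mha/yr with
    spherical areas), and the baseline-BA-weighted mean S_pct; the final row
    is the global total.
    """
    grid = smap.grid
    frac = veg.fractions
    dom_idx = frac.argmax(axis=0)
    dom_frac = frac.max(axis=0)
    labels = np.where(dom_frac >= dominance_threshold,
                      np.array(veg.types, dtype=object)[dom_idx],
                      "mixed vegetation")
    areas = grid.cell_areas(flat=flat_area) / (1.0 if flat_area else KM2_PER_MHA)
    ba_total = np.where(np.isfinite(smap.baseline),
                        smap.baseline * 12.0 * areas, np.nan)  # Mha/yr

    rows = []
    order = [t for t in veg.types] + ["mixed vegetation"]
    for label in order:
        sel = labels == label
        if not sel.any():
            continue
        rows.append(_vegtype_row(label, sel, ba_total, smap))
    rows.append(_vegtype_row("total", np.ones_like(labels, dtype=bool),
                             ba_total, smap))
    return pd.DataFrame(rows)


def _vegtype_row(label, sel, ba_total, smap):
    ba = ba_total[sel]
    s_pct = smap.S_pct[sel]
    ok = np.isfinite(ba) & np.isfinite(s_pct)
    weight = ba[ok]
    mean_s = (float(np.sum(s_pct[ok] * weight) / np.sum(weight))
              if np.sum(weight) > 0 else float("nan"))
    return {"veg_type": label, "n_cells": int(sel.sum()),
            "BA_Mha": float(np.nansum(ba)), "sensitivity_pct_per_unit": mean_s}
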