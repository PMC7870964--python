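"""Derived fire predictors and per-sample feature matrices.

Builds the engineered fuel proxies (``gppl1`` — 12-month cumulative GPP up
to the previous month; ``gppm1``/``gppm1s`` — previous growing-year GPP,
hemisphere-resolved) and assembles one row per retained (cell, month) with
the burned-area target, sample metadata, and optional vegetation-type
fraction columns. Precipitation, population density, and road density are
log10(1 + x)-transformed; other drivers enter in raw units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import MonthlyField, RegionPartition, VegetationFractions, GridSpec

logger = logging.getLogger(__name__)

#: Driver codes accepted in a feature spec.
KNOWN_DRIVERS = ["ts", "pr", "cld", "vp", "gpp", "gppl1", "gppm1", "gppm1s",
                 "pop", "rdtot", "ltn"]
#: Drivers entering the model as log10(1 + x).
LOG_TRANSFORMED = {"pr", "pop", "rdtot"}
#: Metadata columns of an assembled feature matrix (everything else except
#: the ``ba`` target is a feature column).
META_COLUMNS = ["cell_id", "ilat", "ilon", "lat", "lon", "year", "month",
                "time_idx", "region"]

#: ``gppm1`` is resolved per cell by hemisphere: northern cells use the
#: previous Jan-Dec calendar year, southern cells the Jul-Jun window ending
#: in the current calendar year ("the calendar year shifted by 6 months").
GROWING_SEASON_CODES = {"gppm1", "gppm1s"}


class FeatureError(ValueError):
    """Raised for invalid feature specs or missing driver fields."""


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered driver codes plus vegetation-fraction switches."""

    drivers: tuple
    include_veg_fractions: bool = True
    include_cropland: bool = True

    def __post_init__(self):
        drivers = tuple(self.drivers)
        object.__setattr__(self, "drivers", drivers)
        if len(set(drivers)) != len(drivers):
            raise FeatureError("driver codes must be unique")
        unknown = [d for d in drivers if d not in KNOWN_DRIVERS]
        if unknown:
            raise FeatureError(f"unknown driver codes: {unknown}")

    def column_names(self, veg_types) -> list:
        cols = list(self.drivers)
        if self.include_veg_fractions:
            for t in veg_types:
                if t == "croplands" and not self.include_cropland:
                    continue
                cols.append(f"veg_{t}")
        return cols


def log1p_transform(x):
    """log10(1 + x) for non-negative x (the paper-standard skew transform)."""
    x = np.asarray(x, dtype=float)
    if np.any(x[np.isfinite(x)] < 0):
        raise ValueError("log1p_transform requires non-negative input")
    return np.log10(1.0 + x)


def cumulative_gpp(gpp: MonthlyField) -> MonthlyField:
    """Sum of GPP over the 12 months up to (excluding) the current month.

    The first 12 months of the series have insufficient history and are
    returned missing.
    """
    v = gpp.values
    out = np.full_like(v, np.nan)
    csum = np.nancumsum(v, axis=0)
    # window [t-12, t-1]: csum[t-1] - csum[t-13]
    for t in range(12, v.shape[0]):
        lo = csum[t - 13] if t >= 13 else 0.0
        out[t] = csum[t - 1] - lo
    return gpp.like(out, name="gppl1")


def growing_season_gpp(gpp: MonthlyField, hemisphere: str) -> MonthlyField:
    """Previous growing-year GPP, constant within each calendar year.

    Northern cells (``hemisphere="north"``): for any month of calendar year
    y, the sum over Jan-Dec of year y-1. Southern cells (``"south"``): the
    calendar year is shifted by six months, so the window is the Jul-Jun
    block ending in June of year y (Jul(y-1)..Jun(y)). Years without the
    full window available are returned missing.
    """
    if hemisphere not in ("north", "south"):
        raise FeatureError("hemisphere must be 'north' or 'south'")
    v = gpp.values
    out = np.full_like(v, np.nan)
    years = gpp.years
    months = gpp.months
    for y in np.unique(years):
        rows = years == y
        if hemisphere == "north":
            window = years == y - 1
            complete = window.sum() == 12
        else:
            window = ((years == y - 1) & (months >= 7)) | ((years == y) & (months <= 6))
            complete = window.sum() == 12
        if complete:
            out[rows] = v[window].sum(axis=0)[None]
    name = "gppm1" if hemisphere == "north" else "gppm1s"
    return gpp.like(out, name=name)


def hemisphere_resolved_growing_season(gpp: MonthlyField) -> MonthlyField:
    """Per-cell growing-season GPP: northern rule for cells with
    lat >= 0 (equator rows count as northern), southern rule otherwise."""
    north = growing_season_gpp(gpp, "north").values
    south = growing_season_gpp(gpp, "south").values
    is_north = gpp.grid.lat_centers >= 0.0
    out = np.where(is_north[None, :, None], north, south)
    return gpp.like(out, name="gppm1")


def assemble(spec: FeatureSpec, drivers: dict, veg: VegetationFractions,
             mask: np.ndarray, ba: MonthlyField,
             regions: RegionPartition | None = None) -> pd.DataFrame:
    """Build the per-sample feature matrix.

    One row per (cell, month) with the cell inside ``mask``; feature columns
    follow the spec order, vegetation fractions are appended when enabled.
    Rows with any missing feature or target are dropped (counted in the
    log). Returns a DataFrame with :data:`META_COLUMNS`, the feature
    columns, and the ``ba`` target.
    """
    grid = ba.grid
    nt = ba.n_time

    columns = {}
    for code in spec.drivers:
        f = _resolve_driver(code, drivers)
        vals = f.values
        if code in LOG_TRANSFORMED:
            vals = log1p_transform(np.clip(vals, 0.0, None))
        columns[code] = vals

    ilat, ilon = np.where(mask)
    n_cells = len(ilat)
    if n_cells == 0:
        warnings.warn("all cells masked out: empty feature matrix")
    t_idx = np.repeat(np.arange(nt), n_cells)
    ci = np.tile(ilat, nt)
    cj = np.tile(ilon, nt)

    data = {
        "cell_id": ci * grid.n_lon + cj,
        "ilat": ci,
        "ilon": cj,
        "lat": grid.lat_centers[ci],
        "lon": grid.lon_centers[cj],
        "year": ba.years[t_idx],
        "month": ba.months[t_idx],
        "time_idx": t_idx,
        "region": (regions.codes[ci, cj] if regions is not None
                   else np.full(len(ci), "", dtype=object)),
    }
    for code in spec.drivers:
        data[code] = columns[code][t_idx, ci, cj]
    if spec.include_veg_fractions:
        for t, name in enumerate(veg.types):
            if name == "croplands" and not spec.include_cropland:
                continue
            data[f"veg_{name}"] = veg.fractions[t][ci, cj]
    data["ba"] = ba.values[t_idx, ci, cj]

    df = pd.DataFrame(data)
    feature_cols = spec.column_names(veg.types) + ["ba"]
    keep = ~df[feature_cols].isna().any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("assemble: dropped %d of %d rows with missing values",
                    dropped, len(df))
    return df.loc[keep].reset_index(drop=True)


def feature_columns(df: pd.DataFrame) -> list:
    """The feature columns of an assembled matrix (everything but metadata
    and target)."""
    return [c for c in df.columns if c not in META_COLUMNS and c != "ba"]


def _resolve_driver(code: str, drivers: dict) -> MonthlyField:
    """Fetch a driver field, deriving GPP-based features on demand."""
    if code in drivers:
        return drivers[code]
    if code == "gppl1":
        if "gpp" not in drivers:
            raise FeatureError("gppl1 requested but 'gpp' field absent")
        return cumulative_gpp(drivers["gpp"])
    if code in GROWING_SEASON_CODES:
        if "gpp" not in drivers:
            raise FeatureError(f"{code} requested but 'gpp' field absent")
        return hemisphere_resolved_growing_season(drivers["gpp"])
    raise FeatureError(f"driver field {code!r} absent")


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on training rows only.

    Vegetation-fraction columns (``veg_*``) are left unscaled in [0, 1];
    zero-variance columns get scale 1 with a warning. Uses the population
    standard deviation.
    """

    columns: list = field(default_factory=list)
    location: np.ndarray | None = None
    scale: np.ndarray | None = None

    def fit(self, df: pd.DataFrame, columns: list | None = None) -> "Standardizer":
        cols = [c for c in (columns or feature_columns(df))
                if not c.startswith("veg_")]
        x = df[cols].to_numpy(dtype=float)
        loc = x.mean(axis=0)
        sd = x.std(axis=0)
        degenerate = sd <= 0
        if np.any(degenerate):
            warnings.warn(
                f"zero-variance feature column(s) {list(np.array(cols)[degenerate])}; "
                "scale set to 1")
            sd = np.where(degenerate, 1.0, sd)
        self.columns, self.location, self.scale = cols, loc, sd
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        if self.columns:
            out[self.columns] = (df[self.columns].to_numpy(dtype=float)
                                 - self.location) / self.scale
        return out

    def inverse_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        if self.columns:
            out[self.columns] = (df[self.columns].to_numpy(dtype=float)
                                 * self.scale + self.location)
        return out

    def to_dict(self) -> dict:
        return {"columns": list(self.columns),
                "location": np.asarray(self.location).tolist(),
                "scale": np.asarray(self.scale).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(list(d["columns"]),
                   np.asarray(d["location"], dtype=float),
                   np.asarray(d["scale"], dtype=float))
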