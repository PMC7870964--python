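"""Skill metrics, the weighted aggregate score, null model, and niche
diagnostics.

Five metrics summarize a model's agreement with observed burned area on a
region: the Pearson correlation of spatially aggregated monthly series
(r_T), of yearly series (r_IA), of pooled per-cell yearly anomalies (r_An),
of per-cell time means across cells (r_S), and the fractional-deviation
score r_BA = 1 - |1 - BA_pred/BA_obs| on mean yearly totals. They combine
into P = 100 * sqrt(sum w_i r_i^2 / sum w_i), in [0, 100] with ideal
metrics scoring exactly 100; the interannual weight defaults to 4 to
privilege interannual predictability (the spatial extent of the data dwarfs
its temporal extent). The pooled cell-level correlation r_I is reported but
never enters P. Correlations are Pearson throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grid import MonthlyField, KM2_PER_MHA


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class MetricWeights:
    """Non-negative weights for (r_T, r_IA, r_An, r_S, r_BA)."""

    w_T: float = 1.0
    w_IA: float = 4.0
    w_An: float = 1.0
    w_S: float = 1.0
    w_BA: float = 1.0

    def __post_init__(self):
        vals = self.as_tuple()
        if any(w < 0 for w in vals):
            raise MetricError("weights must be non-negative")
        if sum(vals) == 0:
            raise MetricError("weights must not all be zero")

    def as_tuple(self):
        return (self.w_T, self.w_IA, self.w_An, self.w_S, self.w_BA)


@dataclass
class MetricReport:
    """All skill numbers for one model on one region."""

    r_T: float
    r_IA: float
    r_An: float
    r_S: float
    r_BA: float
    r_I: float
    BA_pred_total: float  # mean yearly total (Mha/yr if area-weighted)
    BA_obs_total: float
    LT_pred: float  # OLS slope of yearly totals vs year
    LT_obs: float
    n_samples: int

    def scored_metrics(self):
        return (self.r_T, self.r_IA, self.r_An, self.r_S, self.r_BA)


def corr(x, y) -> float:
    """Pearson correlation; constant input yields NaN with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise MetricError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise MetricError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant series: correlation undefined, returning NaN")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def aggregate_series(fld: MonthlyField, mask: np.ndarray,
                     area_weighting: bool = True):
    """Spatially aggregated monthly and yearly burned-area series.

    With area weighting the monthly total is the sum over masked cells of
    fraction x cell area (in Mha when the grid is spherical); without it,
    the plain mean over masked cells. Yearly totals sum each complete
    year's 12 monthly totals; incomplete years are excluded.
    Returns ``(monthly, years, yearly)``.
    """
    v = np.where(mask[None], fld.values, np.nan)
    if area_weighting:
        areas = fld.grid.cell_areas() / KM2_PER_MHA  # Mha
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            monthly = np.nansum(v * areas[None], axis=(1, 2))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            monthly = np.nanmean(v, axis=(1, 2))
    yrs = []
    yearly = []
    for y in np.unique(fld.years):
        sel = fld.years == y
        if sel.sum() == 12:
            yrs.append(int(y))
            yearly.append(monthly[sel].sum())
        else:
            warnings.warn(f"year {y} incomplete ({sel.sum()} months): excluded "
                          "from yearly series")
    return monthly, np.asarray(yrs), np.asarray(yearly)


def _ols_slope(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def compute_metrics(pred: MonthlyField, obs: MonthlyField, mask: np.ndarray,
                    weights: MetricWeights | None = None,
                    area_weighting: bool = True) -> MetricReport:
    """All skill metrics of a predicted field against observations.

    Cell-months missing in either field are excluded throughout; per-cell
    statistics (r_S, r_An) use each cell's own valid months/years.
    """
    if pred.values.shape != obs.values.shape:
        raise MetricError("prediction and observation fields are not aligned")
    valid = mask[None] & ~pred.missing_mask & ~obs.missing_mask
    p = np.where(valid, pred.values, np.nan)
    o = np.where(valid, obs.values, np.nan)
    pf = pred.like(p, "pred")
    of = obs.like(o, "obs")

    mon_p, yrs, year_p = aggregate_series(pf, mask, area_weighting)
    mon_o, _, year_o = aggregate_series(of, mask, area_weighting)
    ok = np.isfinite(mon_p) & np.isfinite(mon_o)
    r_T = corr(mon_p[ok], mon_o[ok])
    r_IA = corr(year_p, year_o)

    # spatial correlation of per-cell time means
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_p = np.nanmean(p, axis=0)
        mean_o = np.nanmean(o, axis=0)
    cells = mask & np.isfinite(mean_p) & np.isfinite(mean_o)
    r_S = corr(mean_p[cells], mean_o[cells])

    # pooled cell-month correlation
    pool = np.isfinite(p) & np.isfinite(o)
    r_I = corr(p[pool], o[pool])

    # per-cell yearly anomalies, pooled over (cell, year)
    years_list = [int(y) for y in np.unique(obs.years)
                  if (obs.years == y).sum() == 12]
    cy_p = np.stack([np.nansum(np.where(np.isfinite(p) & np.isfinite(o),
                                        p, np.nan)[obs.years == y], axis=0)
                     for y in years_list])
    cy_o = np.stack([np.nansum(np.where(np.isfinite(p) & np.isfinite(o),
                                        o, np.nan)[obs.years == y], axis=0)
                     for y in years_list])
    an_p = (cy_p - cy_p.mean(axis=0))[:, cells]
    an_o = (cy_o - cy_o.mean(axis=0))[:, cells]
    r_An = corr(an_p.ravel(), an_o.ravel())

    ba_p = float(np.mean(year_p))
    ba_o = float(np.mean(year_o))
    if ba_o == 0:
        warnings.warn("zero observed burned-area total: r_BA undefined")
        r_BA = float("nan")
    else:
        r_BA = 1.0 - abs(1.0 - ba_p / ba_o)

    return MetricReport(
        r_T=r_T, r_IA=r_IA, r_An=r_An, r_S=r_S, r_BA=r_BA, r_I=r_I,
        BA_pred_total=ba_p, BA_obs_total=ba_o,
        LT_pred=_ols_slope(yrs, year_p), LT_obs=_ols_slope(yrs, year_o),
        n_samples=int(pool.sum()))


def aggregate_score(report: MetricReport, weights: MetricWeights | None = None,
                    printed_normalization: bool = False) -> float:
    """Weighted aggregate skill score P in [0, 100].

    P = 100 * sqrt(sum w_i r_i^2 / sum w_i): ideal metrics give exactly 100.
    ``printed_normalization=True`` divides by 4 * sum(w_i) instead (capping
    P at 50). Negative correlations enter squared. r_I never enters P.
    """
    weights = weights or MetricWeights()
    names = ("r_T", "r_IA", "r_An", "r_S", "r_BA")
    rs = report.scored_metrics()
    for name, r in zip(names, rs):
        if not np.isfinite(r):
            raise MetricError(f"metric {name} is missing/undefined")
    ws = weights.as_tuple()
    num = sum(w * r * r for w, r in zip(ws, rs))
    den = sum(ws) * (4.0 if printed_normalization else 1.0)
    return 100.0 * float(np.sqrt(num / den))


def history_null_model(ba: MonthlyField, mask: np.ndarray | None = None):
    """Predict each cell-month from the same calendar month in other years.

    The leave-one-year-out mean of burned area for that (cell, month-of-
    year) is the prediction. Returns ``(field, r_I)`` with r_I the pooled
    correlation between prediction and truth over valid samples.
    """
    years = np.unique(ba.years)
    if len(years) < 2:
        raise MetricError("history null model needs at least 2 years")
    if len(years) < 3:
        warnings.warn("history null model with < 3 years is very noisy")
    v = ba.values
    pred = np.full_like(v, np.nan)
    for m in range(1, 13):
        sel = ba.months == m
        sub = v[sel]  # (n_years_m, lat, lon)
        n = sub.shape[0]
        if n < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            total = np.nansum(sub, axis=0)
            count = np.sum(np.isfinite(sub), axis=0)
            loo = (total[None] - np.where(np.isfinite(sub), sub, 0.0)) / np.maximum(
                count[None] - np.isfinite(sub), 1)
        loo = np.where(count[None] - np.isfinite(sub) >= 1, loo, np.nan)
        pred[sel] = loo
    if mask is not None:
        pred = np.where(mask[None], pred, np.nan)
    ok = np.isfinite(pred) & np.isfinite(v)
    if mask is not None:
        ok &= mask[None]
    r = corr(pred[ok], v[ok])
    return ba.like(pred, "ba_history_null"), r


def niche_histogram(driver_a, driver_b, ba, bins=20):
    """Joint occurrence counts and conditional mean burned area.

    Returns ``(counts, mean_ba, a_edges, b_edges)``; bins with no samples
    are NaN in the mean grid. This is the driver-pair "fire niche"
    diagnostic: where in (a, b) space samples fall, and how much burns
    there on average.
    """
    a = np.asarray(driver_a, dtype=float).ravel()
    b = np.asarray(driver_b, dtype=float).ravel()
    z = np.asarray(ba, dtype=float).ravel()
    if not (a.shape == b.shape == z.shape):
        raise MetricError("driver and burned-area samples must be aligned")
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(z)
    a, b, z = a[ok], b[ok], z[ok]
    try:
        counts, a_edges, b_edges = np.histogram2d(a, b, bins=bins)
    except ValueError as err:
        raise MetricError(f"degenerate bin specification: {err}") from err
    sums, _, _ = np.histogram2d(a, b, bins=(a_edges, b_edges), weights=z)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
    return counts, mean, a_edges, b_edges
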