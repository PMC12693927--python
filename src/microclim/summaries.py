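"""Descriptive, comparative and economic summaries.

Covers the reporting side of the analysis: per-stage descriptive
statistics of T/RH/VPD by sensor (overall mean, absolute extrema, and
means of daily minima/maxima), one-way ANOVA across sensors as the
spatial-heterogeneity test, internal-vs-external climate comparisons,
the PAR transmission coefficient of the cover, and the yield /
economics indicators (quality-category shares, yield per plant, gross
profit, benefit-cost ratio).
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .suitability import PhenologyCalendar

logger = logging.getLogger(__name__)

__all__ = [
    "descriptive_table", "AnovaResult", "one_way_anova",
    "internal_external_comparison", "transmission_coefficient",
    "EconomicSummary", "economics", "largest_remainder_round",
]

_VAR_COLS = {"T": "temp_c", "RH": "rh_pct", "VPD": "vpd_kpa"}

#: Study-cycle economic inputs for greenhouse tomato (local market):
#: quality-category yields in kg/ha, planting density in plants/m^2,
#: season cost and income in USD/ha.
DEFAULT_ECONOMIC_INPUTS = {
    "category_weights": {"first": 37_507.7, "second": 29_591.8,
                         "third": 16_295.6, "fourth": 4_607.3},
    "plant_density": 1.14,
    "total_cost": 30_800.9,
    "gross_income": 44_001.3,
}


def descriptive_table(combined: pd.DataFrame, calendar: PhenologyCalendar,
                      min_day_coverage: float = 0.5) -> pd.DataFrame:
    """Per (stage, variable, sensor) descriptive statistics.

    ``combined`` holds all sensors' records (columns sensor_id,
    timestamp, temp_c, rh_pct, vpd_kpa).  Daily minima/maxima come only
    from days with at least ``min_day_coverage`` non-missing records;
    excluded days are logged.  Empty cells are omitted with a warning.
    """
    df = combined.copy()
    ts = pd.to_datetime(df["timestamp"])
    dat = (ts.dt.normalize()
           - pd.Timestamp(calendar.transplant_date)).dt.days
    stage = pd.Series(index=df.index, dtype=object)
    for s in calendar.stages:
        stage[(dat >= s.start_dat) & (dat <= s.end_dat)] = s.name
    df["_stage"] = stage
    df["_date"] = ts.dt.date

    rows = []
    stage_names = [s.name for s in calendar.stages]
    for stg in stage_names:
        sub = df[df["_stage"] == stg]
        for var, col in _VAR_COLS.items():
            if col not in df.columns:
                continue
            for sensor, grp in sub.groupby("sensor_id"):
                vals = grp[col].astype(float)
                if vals.notna().sum() == 0:
                    warnings.warn(f"empty cell {stg}/{var}/{sensor}; "
                                  "row omitted", UserWarning)
                    continue
                daily = grp.groupby("_date")[col].agg(
                    ["min", "max", "count", "size"])
                cov = daily["count"] / daily["size"]
                kept = daily[cov >= min_day_coverage]
                dropped = len(daily) - len(kept)
                if dropped:
                    logger.info("%s/%s/%s: %d day(s) below %.0f%% coverage "
                                "excluded from daily extrema", stg, var,
                                sensor, dropped, 100 * min_day_coverage)
                rows.append({
                    "stage": stg, "variable": var, "sensor": sensor,
                    "mean": vals.mean(),
                    "min_absolute": vals.min(),
                    "max_absolute": vals.max(),
                    "mean_of_min": kept["min"].mean(),
                    "mean_of_max": kept["max"].mean(),
                })
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    F: float
    p: float

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within


def one_way_anova(groups) -> AnovaResult:
    """Fixed-effects one-way ANOVA from the between/within
    sum-of-squares decomposition; p from the F distribution."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    n_total = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(np.sum((a - a.mean()) ** 2) for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            raise ValueError("all values identical; F undefined")
        F = np.inf
        p = 0.0
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(_stats.f.sf(F, df_b, df_w))
    return AnovaResult(df_between=df_b, df_within=df_w,
                       ss_between=float(ss_between),
                       ss_within=float(ss_within), F=float(F), p=p)


def internal_external_comparison(internal: pd.DataFrame,
                                 external_daily: pd.DataFrame,
                                 calendar: PhenologyCalendar,
                                 day_start: _dt.time = _dt.time(6, 0),
                                 day_end: _dt.time = _dt.time(18, 0)
                                 ) -> dict:
    """Internal-minus-external contrasts and RH exceedance shares.

    The external station reports daily values, so sub-daily contrasts
    use proxies: the external daytime temperature is taken as the daily
    maximum and the nighttime one as the daily minimum; external RH
    uses the daily mean throughout.  Returns mean temperature
    differences (overall, by period, by stage) and the proportion of
    records on which internal RH exceeds the external daily mean
    (overall, by period, by stage).
    """
    df = internal.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["_date"] = ts.dt.date
    tod = ts.dt.time
    df["_period"] = np.where((tod >= day_start) & (tod < day_end),
                             "day", "night")
    dat = (ts.dt.normalize()
           - pd.Timestamp(calendar.transplant_date)).dt.days
    df["_stage"] = None
    for s in calendar.stages:
        df.loc[(dat >= s.start_dat) & (dat <= s.end_dat), "_stage"] = s.name

    ext = external_daily.copy()
    ext["date"] = pd.to_datetime(ext["date"]).dt.date
    merged = df.merge(ext, left_on="_date", right_on="date", how="inner")
    if merged.empty:
        raise ValueError("no overlapping dates between internal and "
                         "external records")

    ext_t = np.where(merged["_period"] == "day",
                     merged["tmax_c"], merged["tmin_c"])
    merged["_dT"] = merged["temp_c"] - ext_t
    merged["_dT_mean"] = merged["temp_c"] - merged["tmean_c"]
    merged["_rh_exceeds"] = (merged["rh_pct"]
                             > merged["rhmean_pct"]).astype(float)
    merged.loc[merged["rh_pct"].isna(), "_rh_exceeds"] = np.nan

    def _mean(series):
        return float(series.mean())

    out = {
        "mean_dT_overall": _mean(merged["_dT_mean"]),
        "mean_dT_by_period": {
            per: _mean(grp["_dT"])
            for per, grp in merged.groupby("_period")},
        "mean_dT_by_stage": {
            stg: _mean(grp["_dT_mean"])
            for stg, grp in merged.groupby("_stage")},
        "pct_rh_exceeds_overall": 100.0 * _mean(merged["_rh_exceeds"]),
        "pct_rh_exceeds_by_period": {
            per: 100.0 * _mean(grp["_rh_exceeds"])
            for per, grp in merged.groupby("_period")},
        "pct_rh_exceeds_by_stage": {
            stg: 100.0 * _mean(grp["_rh_exceeds"])
            for stg, grp in merged.groupby("_stage")},
    }
    return out


def transmission_coefficient(par_inside, par_outside) -> float:
    """Cover transmission: mean of pairwise inside/outside PAR ratios.

    Pairs with a nonpositive outside reading are dropped with a
    warning.
    """
    inside = np.asarray(par_inside, dtype=float)
    outside = np.asarray(par_outside, dtype=float)
    if inside.shape != outside.shape:
        raise ValueError("paired series must have equal length")
    ok = outside > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} pair(s) with "
                      "nonpositive outside PAR", UserWarning)
    if not ok.any():
        raise ValueError("no valid PAR pairs")
    return float(np.mean(inside[ok] / outside[ok]))


def largest_remainder_round(values, decimals: int = 1,
                            total: float = 100.0) -> np.ndarray:
    """Round percentages to ``decimals`` places so they sum exactly to
    ``total`` (largest-remainder allocation)."""
    v = np.asarray(values, dtype=float)
    scale = 10 ** decimals
    scaled = v * scale
    floor = np.floor(scaled)
    short = int(round(total * scale - floor.sum()))
    order = np.argsort(-(scaled - floor), kind="stable")
    out = floor.copy()
    out[order[:short]] += 1
    return out / scale


@dataclass
class EconomicSummary:
    category_weights: dict          # kg/ha by quality category
    shares_pct: dict                # raw shares, %
    shares_pct_rounded: dict        # sum-preserving 1-decimal shares
    total_yield_kg_ha: float
    yield_per_plant_kg: float
    marketable_share_pct: float     # first + second categories
    total_cost: float
    gross_income: float
    gross_profit: float
    benefit_cost_ratio: float


def economics(category_weights: dict, plant_density: float,
              total_cost: float, gross_income: float,
              marketable_categories: tuple = ("first", "second")
              ) -> EconomicSummary:
    """Yield and profitability indicators.

    ``category_weights`` maps quality category to kg/ha;
    ``plant_density`` is plants per m^2.  Yield per plant uses the
    exact 10,000 m^2/ha conversion.  Shares are reported both raw and
    sum-preserving rounded to one decimal.
    """
    if any(w < 0 for w in category_weights.values()):
        raise ValueError("weights must be nonnegative")
    total = float(sum(category_weights.values()))
    if total <= 0:
        raise ValueError("total yield must be positive")
    if plant_density <= 0 or total_cost <= 0:
        raise ValueError("plant density and cost must be positive")
    cats = list(category_weights)
    raw = {c: 100.0 * category_weights[c] / total for c in cats}
    rounded = {c: float(v) for c, v in zip(
        cats, largest_remainder_round([raw[c] for c in cats]))}
    marketable = 100.0 * sum(
        category_weights.get(c, 0.0) for c in marketable_categories) / total
    return EconomicSummary(
        category_weights=dict(category_weights),
        shares_pct=raw,
        shares_pct_rounded=rounded,
        total_yield_kg_ha=total,
        yield_per_plant_kg=total / (plant_density * 10_000.0),
        marketable_share_pct=marketable,
        total_cost=float(total_cost),
        gross_income=float(gross_income),
        gross_profit=float(gross_income - total_cost),
        benefit_cost_ratio=float(gross_income / total_cost),
    )
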