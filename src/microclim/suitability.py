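"""Rule-based climatic suitability classification for greenhouse tomato.

Every 5-min record is compared against stage- and period-specific ranges
for air temperature (T), relative humidity (RH) and vapor pressure
deficit (VPD).  Each value falls in exactly one of three categories —
optimal, suboptimal, critical — with a side tag saying whether it missed
the optimal range from below or above.  Downstream aggregations:

* time-in-category shares per (sensor, stage, period) cell, with
  "Average" rows as the unweighted mean over the three stages;
* decomposition of critical time into critically-low vs critically-high
  drivers per variable;
* a daily composite microclimate status by majority rule: if at least
  two of the three variables spend more than half of the day in the same
  category, the day gets that category.

Boundary convention: the optimal interval is closed; the critical region
is strictly beyond the printed critical cuts; the suboptimal region is
everything in between (this closes the typographical gaps between e.g.
an optimal bound of 28 and a printed suboptimal bound of 28.1).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES", "VARIABLES", "Stage", "PhenologyCalendar",
    "ThresholdEntry", "ThresholdTable", "stage_of", "period_of",
    "classify_value", "classify_records", "aggregate_shares",
    "stage_average_rows", "critical_driver_decomposition",
    "daily_status", "daily_status_table",
]

#: Fixed category order, least to most severe.
CATEGORIES = ("optimal", "suboptimal", "critical")
VARIABLES = ("T", "RH", "VPD")

#: Column carrying each classified variable in a sensor frame.
VARIABLE_COLUMNS = {"T": "temp_c", "RH": "rh_pct", "VPD": "vpd_kpa"}


class OutOfCycleError(ValueError):
    """Date lies outside the crop cycle covered by the calendar."""


@dataclass(frozen=True)
class Stage:
    name: str
    start_dat: int
    end_dat: int
    duration_days: int


@dataclass(frozen=True)
class PhenologyCalendar:
    """Transplant date plus contiguous stage windows in days after
    transplant (DAT)."""

    transplant_date: _dt.date
    stages: tuple[Stage, ...]

    def __post_init__(self):
        names = [s.name for s in self.stages]
        if len(names) != len(set(names)):
            raise ValueError("duplicate stage names")
        prev_end = None
        for s in self.stages:
            if s.start_dat > s.end_dat:
                raise ValueError(f"stage {s.name}: start_dat > end_dat")
            if prev_end is not None and s.start_dat != prev_end + 1:
                raise ValueError("stages must be contiguous in DAT")
            prev_end = s.end_dat

    @property
    def total_duration_days(self) -> int:
        return sum(s.duration_days for s in self.stages)

    @property
    def max_dat(self) -> int:
        return self.stages[-1].end_dat

    def dat_of(self, date: _dt.date) -> int:
        return (date - self.transplant_date).days

    def stage_of_dat(self, dat: int) -> str:
        for s in self.stages:
            if s.start_dat <= dat <= s.end_dat:
                return s.name
        raise OutOfCycleError(f"DAT {dat} outside [0, {self.max_dat}]")


def stage_of(date, calendar: PhenologyCalendar) -> str:
    """Phenological stage containing ``date`` (whole days after transplant)."""
    if isinstance(date, pd.Timestamp):
        date = date.date()
    elif isinstance(date, _dt.datetime):
        date = date.date()
    return calendar.stage_of_dat(calendar.dat_of(date))


def period_of(timestamp, day_start: _dt.time = _dt.time(6, 0),
              day_end: _dt.time = _dt.time(18, 0)) -> str:
    """'day' iff the clock time lies in [day_start, day_end), else 'night'."""
    if day_start >= day_end:
        raise ValueError("day_start must precede day_end")
    ts = pd.Timestamp(timestamp)
    t = ts.time()
    return "day" if (day_start <= t < day_end) else "night"


@dataclass(frozen=True)
class ThresholdEntry:
    """Category bounds for one (stage, period, variable) cell."""

    optimal_lo: float
    optimal_hi: float
    critical_below: float
    critical_above: float

    def __post_init__(self):
        if not (self.critical_below <= self.optimal_lo
                <= self.optimal_hi <= self.critical_above):
            raise ValueError(
                "bounds must satisfy critical_below <= optimal_lo <= "
                f"optimal_hi <= critical_above, got {self}"
            )


@dataclass
class ThresholdTable:
    """Suitability ranges keyed by (stage, period, variable).

    Values are classified on their absolute value (relevant only for
    VPD, which is nonnegative for valid RH anyway).
    """

    entries: dict[tuple[str, str, str], ThresholdEntry] = field(
        default_factory=dict)

    def entry(self, stage: str, period: str, variable: str) -> ThresholdEntry:
        try:
            return self.entries[(stage, period, variable)]
        except KeyError:
            raise KeyError(
                f"no thresholds for ({stage}, {period}, {variable})"
            ) from None

    def stages(self) -> set[str]:
        return {k[0] for k in self.entries}


def classify_value(variable: str, value: float, stage: str, period: str,
                   thresholds: ThresholdTable) -> tuple[str, str]:
    """Classify one value; returns (category, side) with side in
    {'low', 'high', 'in'}."""
    e = thresholds.entry(stage, period, variable)
    v = abs(float(value))
    if not np.isfinite(v):
        raise ValueError("value must be finite")
    if e.optimal_lo <= v <= e.optimal_hi:
        return "optimal", "in"
    side = "low" if v < e.optimal_lo else "high"
    if v < e.critical_below or v > e.critical_above:
        return "critical", side
    return "suboptimal", side


def _classify_array(values: np.ndarray, e: ThresholdEntry):
    """Vectorized classify; NaN-safe (NaN stays NaN in both outputs)."""
    v = np.abs(values)
    cat = np.full(v.shape, np.nan, dtype=object)
    side = np.full(v.shape, np.nan, dtype=object)
    ok = np.isfinite(v)
    opt = ok & (v >= e.optimal_lo) & (v <= e.optimal_hi)
    crit = ok & ((v < e.critical_below) | (v > e.critical_above))
    sub = ok & ~opt & ~crit
    cat[opt], cat[crit], cat[sub] = "optimal", "critical", "suboptimal"
    side[opt] = "in"
    low = ok & ~opt & (v < e.optimal_lo)
    high = ok & ~opt & (v > e.optimal_hi)
    side[low], side[high] = "low", "high"
    return cat, side


_SEVERITY = {"optimal": 0, "suboptimal": 1, "critical": 2}


def classify_records(frame: pd.DataFrame, thresholds: ThresholdTable,
                     calendar: PhenologyCalendar,
                     day_start: _dt.time = _dt.time(6, 0),
                     day_end: _dt.time = _dt.time(18, 0)) -> pd.DataFrame:
    """Annotate a sensor frame with stage, period, per-variable category
    and side tags, and the composite (worst-across-variables) category.

    ``frame`` needs columns timestamp, temp_c, rh_pct, vpd_kpa.  Records
    outside the crop cycle raise :class:`OutOfCycleError`.
    """
    if day_start >= day_end:
        raise ValueError("day_start must precede day_end")
    out = frame.copy()
    ts = pd.to_datetime(out["timestamp"])
    dat = (ts.dt.normalize()
           - pd.Timestamp(calendar.transplant_date)).dt.days.to_numpy()
    if dat.min() < 0 or dat.max() > calendar.max_dat:
        raise OutOfCycleError(
            f"records span DAT [{dat.min()}, {dat.max()}], outside "
            f"[0, {calendar.max_dat}]")

    stage = np.empty(len(out), dtype=object)
    for s in calendar.stages:
        stage[(dat >= s.start_dat) & (dat <= s.end_dat)] = s.name
    out["stage"] = stage
    out["dat"] = dat

    tod = ts.dt.time
    is_day = (tod >= day_start) & (tod < day_end)
    out["period"] = np.where(is_day, "day", "night")

    sev = np.full(len(out), -1)
    any_missing = np.zeros(len(out), dtype=bool)
    for var in VARIABLES:
        col = VARIABLE_COLUMNS[var]
        vals = out[col].to_numpy(dtype=float)
        cat = np.full(len(out), np.nan, dtype=object)
        sidearr = np.full(len(out), np.nan, dtype=object)
        for (st, per), idx in out.groupby(["stage", "period"],
                                          observed=True).indices.items():
            e = thresholds.entry(st, per, var)
            c, sd = _classify_array(vals[idx], e)
            cat[idx] = c
            sidearr[idx] = sd
        out[f"cat_{var}"] = cat
        out[f"side_{var}"] = sidearr
        csev = np.array([_SEVERITY.get(c, -1) for c in cat])
        miss = csev < 0
        any_missing |= miss
        sev = np.maximum(sev, csev)

    composite = np.full(len(out), np.nan, dtype=object)
    okrow = ~any_missing
    inv = {v: k for k, v in _SEVERITY.items()}
    composite[okrow] = [inv[s] for s in sev[okrow]]
    out["cat_composite"] = composite
    return out


def _share_row(cats: pd.Series) -> dict:
    n = cats.notna().sum()
    row = {"n_records": int(n)}
    if n == 0:
        for c in CATEGORIES:
            row[f"pct_{c}"] = np.nan
        return row
    counts = cats.value_counts()
    for c in CATEGORIES:
        row[f"pct_{c}"] = 100.0 * counts.get(c, 0) / n
    return row


def aggregate_shares(classified: pd.DataFrame, variable: str = "composite",
                     sensor_col: str = "sensor_id",
                     include_average: bool = True) -> pd.DataFrame:
    """Time-in-category percentage shares per (sensor, stage, period).

    ``variable`` selects the composite per-record category (default) or
    one of T/RH/VPD for per-variable shares.  Percentages are over
    non-missing records in the cell.  With ``include_average``, each
    (sensor, period) additionally gets an "Average" row holding the
    unweighted mean of its per-stage percentages.
    """
    col = f"cat_{variable}" if variable != "composite" else "cat_composite"
    if col not in classified.columns:
        raise KeyError(f"column {col} not found; run classify_records first")
    rows = []
    stage_order = {s: i for i, s in enumerate(
        classified["stage"].drop_duplicates())}
    for (sensor, stg, per), grp in classified.groupby(
            [sensor_col, "stage", "period"], observed=True):
        row = {"sensor_id": sensor, "stage": stg, "period": per}
        row.update(_share_row(grp[col]))
        if row["n_records"] == 0:
            logger.warning("empty cell %s/%s/%s: percentages undefined",
                           sensor, stg, per)
        rows.append(row)
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["sensor_id", "period", "stage"],
        key=lambda s: s.map(stage_order) if s.name == "stage" else s,
    ).reset_index(drop=True)
    if include_average:
        out = pd.concat([out, stage_average_rows(out)], ignore_index=True)
    return out


def stage_average_rows(shares: pd.DataFrame) -> pd.DataFrame:
    """"Average" rows: per (sensor, period), the unweighted mean of the
    per-stage percentage values (cells with defined percentages only)."""
    rows = []
    for (sensor, per), grp in shares.groupby(["sensor_id", "period"],
                                             observed=True):
        grp = grp[grp["stage"] != "Average"]
        row = {"sensor_id": sensor, "stage": "Average", "period": per,
               "n_records": int(grp["n_records"].sum())}
        for c in CATEGORIES:
            row[f"pct_{c}"] = grp[f"pct_{c}"].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def critical_driver_decomposition(classified: pd.DataFrame,
                                  sensor_col: str = "sensor_id"
                                  ) -> pd.DataFrame:
    """Split each variable's critical share into critically-low vs
    critically-high time, per (sensor, stage, period, variable).

    pct_critical_low + pct_critical_high equals the variable's total
    critical share in that cell.
    """
    rows = []
    for (sensor, stg, per), grp in classified.groupby(
            [sensor_col, "stage", "period"], observed=True):
        for var in VARIABLES:
            cats = grp[f"cat_{var}"]
            sides = grp[f"side_{var}"]
            n = cats.notna().sum()
            row = {"sensor_id": sensor, "stage": stg, "period": per,
                   "variable": var, "n_records": int(n)}
            if n == 0:
                row["pct_critical_low"] = np.nan
                row["pct_critical_high"] = np.nan
            else:
                crit = cats == "critical"
                row["pct_critical_low"] = (
                    100.0 * (crit & (sides == "low")).sum() / n)
                row["pct_critical_high"] = (
                    100.0 * (crit & (sides == "high")).sum() / n)
            rows.append(row)
    return pd.DataFrame(rows)


def daily_status(day_frame: pd.DataFrame) -> dict:
    """Composite microclimate status for one calendar day of classified
    records.

    Computes the nine daily percentages (three categories for each of T,
    RH, VPD) and applies the majority rule: a category claimed by at
    least two variables with more than 50% of the day wins.  When no
    category reaches two such votes the fallback assigns the category
    with the largest mean share across the three variables, ties broken
    toward the more severe category, and flags ``rule_satisfied=False``.
    """
    pcts = {}
    for var in VARIABLES:
        cats = day_frame[f"cat_{var}"]
        n = cats.notna().sum()
        if n == 0:
            raise ValueError(f"variable {var} fully missing for this day")
        counts = cats.value_counts()
        for c in CATEGORIES:
            pcts[f"pct_{c}_{var}"] = 100.0 * counts.get(c, 0) / n

    votes = {c: sum(1 for var in VARIABLES if pcts[f"pct_{c}_{var}"] > 50.0)
             for c in CATEGORIES}
    winners = [c for c in CATEGORIES if votes[c] >= 2]
    if winners:
        status, satisfied = winners[0], True
    else:
        mean_share = {c: np.mean([pcts[f"pct_{c}_{var}"] for var in VARIABLES])
                      for c in CATEGORIES}
        best = max(mean_share.values())
        # tie toward severity: scan critical first
        status = next(c for c in reversed(CATEGORIES)
                      if mean_share[c] == best)
        satisfied = False
    return {**pcts, "status": status, "rule_satisfied": satisfied}


def daily_status_table(classified: pd.DataFrame) -> pd.DataFrame:
    """Daily-status rows for every date in a classified sensor frame.

    Days on which any variable is fully missing are excluded and logged.
    """
    ts = pd.to_datetime(classified["timestamp"])
    rows = []
    for date, grp in classified.groupby(ts.dt.date):
        try:
            row = daily_status(grp)
        except ValueError as exc:
            logger.warning("excluding %s: %s", date, exc)
            continue
        rows.append({"date": date, **row})
    return pd.DataFrame(rows)
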