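"""Iterative tree-ensemble imputation of sensor gaps.

Missing temperature / relative-humidity records are filled with the
missForest scheme: initialize gaps with column means, then repeatedly
re-impute each variable — in increasing order of missingness — from a
bagged ensemble of regression trees fitted on the currently completed
matrix, until the out-of-bag (OOB) normalized root mean squared error
(NRMSE) stops improving or the iteration cap is reached.  When the OOB
error rises relative to the previous sweep, the previous sweep's
values are kept.

Predictors are within-series: days after transplant, day of year,
sin/cos-encoded hour of day, phenological stage, a day/night
indicator, and the co-observed climate variable.  Observed values are
never altered.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .suitability import PhenologyCalendar
from .tree import grow_regression, predict_regression

logger = logging.getLogger(__name__)

__all__ = ["ImputationConfig", "ImputationResult", "nrmse", "impute",
           "build_feature_matrix"]


def nrmse(truth, estimate) -> float:
    """Root mean squared error normalized by the standard deviation of
    the truth (population variance convention): sqrt(MSE / var(truth)).

    0 for a perfect estimate; 1 when the estimate is the constant mean
    of the truth.  Zero-variance truth is an error.
    """
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if t.shape != e.shape:
        raise ValueError("truth and estimate must have equal length")
    if t.size < 2:
        raise ValueError("need at least 2 values")
    var = float(np.var(t))  # population (ddof=0)
    if var <= 0:
        raise ValueError("truth has zero variance; NRMSE undefined")
    return float(np.sqrt(np.mean((t - e) ** 2) / var))


@dataclass
class ImputationConfig:
    """Hyperparameters of the iterative ensemble imputer."""

    n_trees: int = 100
    max_iterations: int = 10
    mtry: int | None = None  # None = automatic floor(sqrt(p))
    seed: int = 0
    min_split: int = 5
    min_leaf: int = 2
    max_depth: int = 12

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ImputationResult:
    frame: pd.DataFrame
    iterations_run: int
    oob_nrmse_trace: list = field(default_factory=list)
    converged: bool = False


def build_feature_matrix(frame: pd.DataFrame, calendar: PhenologyCalendar,
                         day_start: _dt.time = _dt.time(6, 0),
                         day_end: _dt.time = _dt.time(18, 0)) -> np.ndarray:
    """Always-complete auxiliary predictors derived from the timestamp:
    DAT, day-of-year, hour sin/cos, stage code, day indicator."""
    ts = pd.to_datetime(frame["timestamp"])
    dat = (ts.dt.normalize()
           - pd.Timestamp(calendar.transplant_date)).dt.days.to_numpy()
    doy = ts.dt.dayofyear.to_numpy(dtype=float)
    hour = ts.dt.hour.to_numpy() + ts.dt.minute.to_numpy() / 60.0
    stage_code = np.zeros(len(frame))
    for i, s in enumerate(calendar.stages):
        stage_code[(dat >= s.start_dat) & (dat <= s.end_dat)] = i
    tod = ts.dt.time
    is_day = ((tod >= day_start) & (tod < day_end)).to_numpy(dtype=float)
    return np.column_stack([
        dat.astype(float), doy,
        np.sin(2 * np.pi * hour / 24.0), np.cos(2 * np.pi * hour / 24.0),
        stage_code, is_day,
    ])


def _bagged_fit_predict(X_obs, y_obs, X_mis, cfg: ImputationConfig,
                        rng: np.random.Generator):
    """Fit a bagged regression-tree ensemble; return (OOB predictions on
    the observed rows with NaN where never OOB, mean prediction on the
    missing rows)."""
    n = len(y_obs)
    p = X_obs.shape[1]
    mtry = cfg.mtry if cfg.mtry is not None else max(1, int(np.sqrt(p)))
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    mis_sum = np.zeros(len(X_mis))
    for _ in range(cfg.n_trees):
        boot = rng.integers(0, n, size=n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[boot] = True
        tree = grow_regression(X_obs[boot], y_obs[boot],
                               min_split=cfg.min_split,
                               min_leaf=cfg.min_leaf,
                               max_depth=cfg.max_depth,
                               mtry=mtry, rng=rng)
        oob = ~in_bag
        if oob.any():
            oob_sum[oob] += predict_regression(tree, X_obs[oob])
            oob_cnt[oob] += 1
        if len(X_mis):
            mis_sum += predict_regression(tree, X_mis)
    oob_pred = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), np.nan)
    mis_pred = mis_sum / cfg.n_trees if len(X_mis) else mis_sum
    return oob_pred, mis_pred


def impute(frame: pd.DataFrame, calendar: PhenologyCalendar,
           config: ImputationConfig | None = None,
           columns: tuple[str, ...] = ("temp_c", "rh_pct"),
           day_start: _dt.time = _dt.time(6, 0),
           day_end: _dt.time = _dt.time(18, 0)) -> ImputationResult:
    """Fill gaps in one sensor's series.

    ``frame`` needs a timestamp column plus the target columns; other
    columns pass through untouched.  Deterministic for a fixed
    ``config.seed``.  Raises when a target column is entirely missing
    or more than half missing.
    """
    cfg = config or ImputationConfig()
    out = frame.reset_index(drop=True).copy()
    aux = build_feature_matrix(out, calendar, day_start, day_end)

    miss_masks = {}
    for col in columns:
        vals = out[col].to_numpy(dtype=float)
        mask = ~np.isfinite(vals)
        frac = mask.mean()
        if frac >= 0.5:
            raise ValueError(
                f"{col}: {frac:.1%} missing; imputation requires < 50%")
        if mask.all():
            raise ValueError(f"{col} entirely missing; unimputable")
        miss_masks[col] = mask

    targets = [c for c in columns if miss_masks[c].any()]
    if not targets:
        return ImputationResult(frame=out, iterations_run=1,
                                oob_nrmse_trace=[], converged=True)
    # increasing-missingness sweep order
    targets.sort(key=lambda c: miss_masks[c].mean())

    if np.all(np.ptp(aux, axis=0) == 0):
        warnings.warn("all auxiliary predictors constant; falling back to "
                      "mean imputation", UserWarning)
        for col in targets:
            vals = out[col].to_numpy(dtype=float)
            vals[miss_masks[col]] = np.nanmean(vals)
            out[col] = vals
        return ImputationResult(frame=out, iterations_run=1,
                                oob_nrmse_trace=[], converged=True)

    # working matrix of target columns, mean-initialized
    work = {c: out[c].to_numpy(dtype=float).copy() for c in columns}
    for col in columns:
        m = miss_masks[col]
        if m.any():
            work[col][m] = np.nanmean(out[col].to_numpy(dtype=float))

    rng = np.random.default_rng(cfg.seed)
    trace: list[dict] = []
    prev_values = {c: work[c].copy() for c in targets}
    converged = False
    iterations_run = 0

    for it in range(cfg.max_iterations):
        iterations_run = it + 1
        iter_nrmse = {}
        for col in targets:
            m = miss_masks[col]
            others = [c for c in columns if c != col]
            X = np.column_stack([aux] + [work[c] for c in others])
            y_obs = out[col].to_numpy(dtype=float)[~m]
            oob_pred, mis_pred = _bagged_fit_predict(
                X[~m], y_obs, X[m], cfg, rng)
            have = np.isfinite(oob_pred)
            iter_nrmse[col] = (nrmse(y_obs[have], oob_pred[have])
                               if have.sum() >= 2 else np.nan)
            work[col][m] = mis_pred
        trace.append(iter_nrmse)
        logger.info("imputation iteration %d: OOB NRMSE %s", it + 1,
                    {k: round(v, 4) for k, v in iter_nrmse.items()})
        if it > 0:
            prev = sum(v for v in trace[-2].values() if np.isfinite(v))
            curr = sum(v for v in trace[-1].values() if np.isfinite(v))
            if curr > prev:
                # no further improvement: keep the previous sweep
                for col in targets:
                    work[col] = prev_values[col]
                converged = True
                break
        prev_values = {c: work[c].copy() for c in targets}

    for col in targets:
        vals = out[col].to_numpy(dtype=float)
        m = miss_masks[col]
        vals[m] = work[col][m]
        out[col] = vals
    return ImputationResult(frame=out, iterations_run=iterations_run,
                            oob_nrmse_trace=trace, converged=converged)
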