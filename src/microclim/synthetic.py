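"""Synthetic greenhouse sensor series and external weather.

Emulates the monitoring design the analysis assumes: four interior
temperature/relative-humidity sensors, one per greenhouse quadrant,
logging every 5 minutes over a 190-day tomato cycle, plus an external
station summarized daily.  The generated structure is

* a deterministic diurnal backbone — piecewise-cosine shape with the
  daily minimum at 06:00 and the maximum at 14:00 (equatorial site, no
  seasonal photoperiod drift) — whose level and day/night contrast are
  solved per phenological stage so the daytime and nighttime means hit
  the configured stage targets;
* RH generated anti-phase to temperature (pre-dawn humidity peak),
  clipped to [0, 100];
* additive per-sensor quadrant offsets (spatial heterogeneity);
* independent Gaussian record noise plus a slowly varying AR(1)
  day-level drift (realistic absolute extrema without radiation
  physics);
* MCAR missingness as geometric-length gaps, per-sensor fractions
  defaulting to the low single-percent range observed in practice.

The external series is built with a much smaller diurnal swing and
noise level than the interior ones, so interior variance dominates.
Everything is reproducible from the configured seed.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SimulationOutput", "simulate_greenhouse",
           "inject_missingness", "INTERNAL_SENSORS", "EXTERNAL_SENSOR"]

INTERNAL_SENSORS = ("S1-EQ", "S2-NQ", "S3-SQ", "S4-WQ")
EXTERNAL_SENSOR = "EXTERNAL"

_STAGES = ("vegetative", "reproductive", "harvest")


def _default_stage_day_means():
    # (T degC, RH %) daytime targets per stage
    return {"vegetative": (25.6, 62.0),
            "reproductive": (23.4, 75.0),
            "harvest": (23.8, 64.0)}


def _default_stage_night_means():
    return {"vegetative": (15.0, 88.0),
            "reproductive": (14.0, 92.0),
            "harvest": (14.0, 87.0)}


def _default_offsets():
    # additive (T, RH) offsets per quadrant sensor
    return {"S1-EQ": (0.0, 0.0), "S2-NQ": (0.4, -0.3),
            "S3-SQ": (-1.0, 2.0), "S4-WQ": (-0.1, -2.0)}


def _default_missing():
    return {"S1-EQ": 0.009, "S2-NQ": 0.007, "S3-SQ": 0.029, "S4-WQ": 0.023}


@dataclass
class SimulationConfig:
    transplant_date: _dt.date = _dt.date(2024, 3, 14)
    cycle_days: int = 190
    interval_minutes: int = 5
    stage_boundaries: dict = field(default_factory=lambda: {
        "vegetative": (0, 50), "reproductive": (51, 109),
        "harvest": (110, 190)})
    stage_day_means: dict = field(default_factory=_default_stage_day_means)
    stage_night_means: dict = field(
        default_factory=_default_stage_night_means)
    diurnal_amplitude_T: float = 6.0
    diurnal_amplitude_RH: float = 7.0
    quadrant_offsets: dict = field(default_factory=_default_offsets)
    noise_sd_T: float = 1.2
    noise_sd_RH: float = 3.5
    drift_sd_T: float = 0.7
    drift_sd_RH: float = 2.5
    drift_phi: float = 0.6
    external_day_mean_T: float = 17.2
    external_night_mean_T: float = 15.5
    external_day_mean_RH: float = 68.0
    external_night_mean_RH: float = 78.0
    external_amplitude_T: float = 2.0
    external_amplitude_RH: float = 3.0
    external_noise_sd_T: float = 0.3
    external_noise_sd_RH: float = 1.0
    missing_fraction: dict = field(default_factory=_default_missing)
    gap_length_mean: float = 6.0
    day_start_hour: float = 6.0
    day_end_hour: float = 18.0
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.transplant_date, _dt.date):
            raise ValueError("transplant_date must be a date")
        if self.cycle_days <= 0:
            raise ValueError("cycle_days must be positive")
        if self.interval_minutes <= 0 or 1440 % self.interval_minutes:
            raise ValueError("interval_minutes must divide 1440")
        for s, f in self.missing_fraction.items():
            if not 0.0 <= f < 0.5:
                raise ValueError(f"missing_fraction[{s}] must be in [0, 0.5)")

    @property
    def records_per_day(self) -> int:
        return 1440 // self.interval_minutes


@dataclass
class SimulationOutput:
    """Sensor frames with injected gaps, the gap-free truth, and the
    daily external weather table."""

    frames: dict           # sensor_id -> DataFrame with missingness
    complete: dict         # sensor_id -> gap-free DataFrame
    external_daily: pd.DataFrame

    def combined(self, with_missing: bool = True) -> pd.DataFrame:
        src = self.frames if with_missing else self.complete
        return pd.concat(src.values(), ignore_index=True)


def _diurnal_shape(hour: np.ndarray) -> np.ndarray:
    """Piecewise-cosine diurnal shape in [-1, 1]: minimum at 06:00,
    maximum at 14:00, smooth and continuous."""
    h = np.asarray(hour, dtype=float) % 24.0
    s = np.empty_like(h)
    rising = (h >= 6.0) & (h < 14.0)
    s[rising] = -np.cos(np.pi * (h[rising] - 6.0) / 8.0)
    falling = ~rising
    hf = (h[falling] - 14.0) % 24.0  # 0..16 across the wrap
    s[falling] = np.cos(np.pi * hf / 16.0)
    return s


def _day_weight(hour: np.ndarray, day_start: float, day_end: float
                ) -> np.ndarray:
    """Smoothed day indicator with 2-h raised-cosine transitions."""
    h = np.asarray(hour, dtype=float) % 24.0
    w = np.zeros_like(h)
    w[(h >= day_start + 1) & (h < day_end - 1)] = 1.0
    for edge, sign in ((day_start, 1.0), (day_end, -1.0)):
        band = (h >= edge - 1) & (h < edge + 1)
        ramp = (1.0 - np.cos(np.pi * (h[band] - edge + 1) / 2.0)) / 2.0
        w[band] = ramp if sign > 0 else 1.0 - ramp
    return w


def _solve_levels(day_mean, night_mean, amplitude, s, w, is_day):
    """Solve base and day-boost so period means of
    base + amplitude*s + boost*w hit the configured targets."""
    sd, sn = s[is_day].mean(), s[~is_day].mean()
    wd, wn = w[is_day].mean(), w[~is_day].mean()
    boost = ((day_mean - night_mean) - amplitude * (sd - sn)) / (wd - wn)
    base = night_mean - amplitude * sn - boost * wn
    return base, boost


def _ar1_daily(n_days: int, sd: float, phi: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) day-level drift with marginal SD ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    x = np.empty(n_days)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n_days):
        x[i] = phi * x[i - 1] + rng.normal(0.0, innov_sd)
    return x


def _grid(config: SimulationConfig):
    n = config.cycle_days * config.records_per_day
    start = pd.Timestamp(config.transplant_date)
    ts = start + pd.to_timedelta(
        np.arange(n) * config.interval_minutes, unit="min")
    return ts


def _stage_index(config: SimulationConfig, dat: np.ndarray) -> np.ndarray:
    out = np.full(len(dat), -1)
    for i, name in enumerate(_STAGES):
        lo, hi = config.stage_boundaries[name]
        out[(dat >= lo) & (dat <= hi)] = i
    if np.any(out < 0):
        raise ValueError("stage boundaries do not cover the cycle")
    return out


def _series_for(config: SimulationConfig, sensor: str,
                rng: np.random.Generator) -> pd.DataFrame:
    ts = _grid(config)
    hour = ts.hour + ts.minute / 60.0
    dat = np.arange(len(ts)) // config.records_per_day
    s = _diurnal_shape(hour)
    w = _day_weight(hour, config.day_start_hour, config.day_end_hour)
    is_day = (hour >= config.day_start_hour) & (hour < config.day_end_hour)

    external = sensor == EXTERNAL_SENSOR
    if external:
        amp_t, amp_rh = config.external_amplitude_T, config.external_amplitude_RH
        noise_t, noise_rh = (config.external_noise_sd_T,
                             config.external_noise_sd_RH)
        drift_t = drift_rh = 0.0
        off_t = off_rh = 0.0
    else:
        amp_t, amp_rh = config.diurnal_amplitude_T, config.diurnal_amplitude_RH
        noise_t, noise_rh = config.noise_sd_T, config.noise_sd_RH
        drift_t, drift_rh = config.drift_sd_T, config.drift_sd_RH
        off_t, off_rh = config.quadrant_offsets.get(sensor, (0.0, 0.0))

    t = np.empty(len(ts))
    rh = np.empty(len(ts))
    stage_idx = _stage_index(config, dat)
    for i, name in enumerate(_STAGES):
        m = stage_idx == i
        if not m.any():
            continue
        if external:
            dm_t, dm_rh = (config.external_day_mean_T,
                           config.external_day_mean_RH)
            nm_t, nm_rh = (config.external_night_mean_T,
                           config.external_night_mean_RH)
        else:
            dm_t, dm_rh = config.stage_day_means[name]
            nm_t, nm_rh = config.stage_night_means[name]
        base_t, boost_t = _solve_levels(dm_t, nm_t, amp_t,
                                        s[m], w[m], is_day[m])
        t[m] = base_t + amp_t * s[m] + boost_t * w[m]
        # RH runs anti-phase to temperature: pre-dawn peak
        base_rh, boost_rh = _solve_levels(dm_rh, nm_rh, -amp_rh,
                                          s[m], w[m], is_day[m])
        rh[m] = base_rh - amp_rh * s[m] + boost_rh * w[m]

    t += off_t
    rh += off_rh
    if drift_t > 0 or drift_rh > 0:
        day_drift_t = _ar1_daily(config.cycle_days, drift_t,
                                 config.drift_phi, rng)
        day_drift_rh = _ar1_daily(config.cycle_days, drift_rh,
                                  config.drift_phi, rng)
        t += day_drift_t[dat]
        rh += day_drift_rh[dat]
    if noise_t > 0:
        t = t + rng.normal(0.0, noise_t, len(ts))
    if noise_rh > 0:
        rh = rh + rng.normal(0.0, noise_rh, len(ts))
    rh = np.clip(rh, 0.0, 100.0)

    return pd.DataFrame({"timestamp": ts, "sensor_id": sensor,
                         "temp_c": t, "rh_pct": rh})


def inject_missingness(frame: pd.DataFrame, fraction: float,
                       gap_length_mean: float, seed: int,
                       columns: tuple[str, ...] = ("temp_c", "rh_pct")
                       ) -> pd.DataFrame:
    """Blank a fraction of records as MCAR gaps with geometric lengths.

    Gap lengths are drawn geometric with the given mean, so isolated
    single-record dropouts arise naturally alongside multi-record gaps.
    The realized missing share hits the request to within a fraction of
    a percentage point (the final gap is trimmed).  Present values are
    never modified.
    """
    if not 0.0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    out = frame.copy()
    if fraction == 0.0:
        return out
    n = len(out)
    target = int(round(fraction * n))
    if target == 0:
        return out
    rng = np.random.default_rng(seed)
    p = 1.0 / max(gap_length_mean, 1.0)
    missing = np.zeros(n, dtype=bool)
    count = 0
    while count < target:
        start = int(rng.integers(0, n))
        length = int(rng.geometric(p))
        length = min(length, target - count)  # trim to land on target
        stop = min(start + length, n)
        seg = missing[start:stop]
        count += int((~seg).sum())
        missing[start:stop] = True
    for col in columns:
        vals = out[col].to_numpy(dtype=float).copy()
        vals[missing] = np.nan
        out[col] = vals
    return out


def _external_daily(frame: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Daily external weather table: T/RH aggregates of the external
    series plus plausible precipitation, wind and radiation columns."""
    ts = pd.to_datetime(frame["timestamp"])
    g = frame.groupby(ts.dt.date)
    out = pd.DataFrame({
        "date": list(g.groups.keys()),
        "tmean_c": g["temp_c"].mean().to_numpy(),
        "tmin_c": g["temp_c"].min().to_numpy(),
        "tmax_c": g["temp_c"].max().to_numpy(),
        "rhmean_pct": g["rh_pct"].mean().to_numpy(),
    })
    n = len(out)
    # drizzle-dominated Andean regime: many dry days, occasional events
    wet = rng.random(n) < 0.35
    out["precip_lm2"] = np.where(wet, rng.gamma(1.2, 4.0, n), 0.0).round(1)
    out["wind_kmh"] = np.clip(rng.normal(5.5, 1.5, n), 0.5, None).round(1)
    out["rad_wm2"] = np.clip(rng.normal(189.0, 25.0, n), 50.0, None).round(0)
    return out


def simulate_greenhouse(config: SimulationConfig | None = None
                        ) -> SimulationOutput:
    """Generate the four quadrant series plus the external series.

    Deterministic for a fixed ``config.seed``.  Gap injection uses
    per-sensor seeds derived from the master seed, so the gap pattern
    of one sensor does not depend on the others.
    """
    cfg = config or SimulationConfig()
    master = np.random.default_rng(cfg.seed)
    child_seeds = master.integers(0, 2 ** 31 - 1,
                                  size=len(INTERNAL_SENSORS) * 2 + 2)
    complete = {}
    frames = {}
    for i, sensor in enumerate(INTERNAL_SENSORS):
        rng = np.random.default_rng(int(child_seeds[2 * i]))
        full = _series_for(cfg, sensor, rng)
        complete[sensor] = full
        frac = cfg.missing_fraction.get(sensor, 0.0)
        frames[sensor] = inject_missingness(
            full, frac, cfg.gap_length_mean, int(child_seeds[2 * i + 1]))
    rng_ext = np.random.default_rng(int(child_seeds[-2]))
    ext = _series_for(cfg, EXTERNAL_SENSOR, rng_ext)
    complete[EXTERNAL_SENSOR] = ext
    frames[EXTERNAL_SENSOR] = ext.copy()
    daily = _external_daily(ext, cfg,
                            np.random.default_rng(int(child_seeds[-1])))
    return SimulationOutput(frames=frames, complete=complete,
                            external_daily=daily)


def replace(config: SimulationConfig, **changes) -> SimulationConfig:
    """dataclasses.replace passthrough, for terse config tweaks."""
    return dataclasses.replace(config, **changes)
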