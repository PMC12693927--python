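# Methods

This note documents the models, conventions and design choices behind
`microclim`, in the spirit of a statistical package's methods
appendix. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Psychrometrics

Saturation vapor pressure follows a Tetens-type exponential,
SVP = 0.6108 · b^(17.27·T/(T+237.3)) kPa, with the base *b* defaulting
to the literal constant 2.7183 as conventionally typeset in agronomy
formulas; a keyword selects the exact natural base. Over 0–50 °C the
two differ by less than one part in 10⁴ (pinned by a property test).
VPD = SVP·(1 − RH/100) is nonnegative for valid RH; classification
uses |VPD|, a no-op under strict RH validation. RH outside [0, 100]
raises by default or is clamped when `strict=False`.

## Phenology calendar

The tomato cycle is 190 days from transplanting, split into
vegetative / reproductive / harvest stages. Stage lookup uses the
days-after-transplant (DAT) windows 0–50, 51–109, 110–190, matching
the published calendar verbatim; stage *durations* are stored as the
published day counts (50, 59, 81), which derive from the calendar
dates rather than the DAT windows (the windows contain 51/59/81
days — an off-by-one internal to the source calendar). Both views are
kept: window boundaries drive classification, durations drive the
cycle-length total.

## Suitability classification

Each record is classified per variable against stage- and
period-specific ranges. Boundary convention: the optimal interval is
**closed**; values strictly beyond the critical cuts are critical;
everything between is suboptimal. This closes the typographical gaps
in printed range tables (e.g. optimal up to 28 but suboptimal printed
from 28.1: a value of 28.05 is suboptimal/high here) and makes the
three categories a measurable partition — verified by a
10,000-probe sweep.

The day/night boundary is 06:00–18:00 local, half-open on the right
(18:00 is night), configurable; the site is equatorial with a ~12 h
photoperiod, and the source analysis never defines the split.

Two aggregation views exist because the integrated reading could be
produced either way: (a) a **composite** per-record category — the
worst of the three variables' categories (critical > suboptimal >
optimal) — aggregated per sensor × stage × period; and (b)
**per-variable** shares. Only the Average-row arithmetic (the
unweighted mean of the three per-stage percentages within a sensor ×
period) is treated as ground truth; it reproduces every published
Average cell at one-decimal rounding. Percentages are over non-missing
records; empty cells report undefined percentages (never 0) with
n_records = 0.

Daily status: from the nine daily percentages (3 categories × 3
variables), a category claimed by ≥2 variables with >50% of the day
wins. When no category reaches two such votes, the fallback assigns
the category with the largest mean share across variables, ties broken
toward severity, and flags the day (`rule_satisfied=False`); the
original rule is silent on this case and the fallback keeps the
response total and auditable. Days with a fully missing variable are
excluded and logged.

## Gap imputation

The imputer follows the missForest scheme: numeric gaps are
mean-initialized, variables are revisited in increasing-missingness
order, and each sweep refits a bagged ensemble of regression trees
(bootstrap per tree, per-node feature subsampling with mtry = ⌊√p⌋
when automatic) on the currently completed matrix. Out-of-bag NRMSE —
RMSE normalized by the **population** standard deviation of the
observed values (convention pinned by test) — is recorded per sweep;
when the summed OOB NRMSE rises relative to the previous sweep, the
previous sweep's values are returned. Defaults: 100 trees, ≤10
iterations, fixed seed.

Each sensor is imputed independently with within-series predictors:
DAT, day-of-year, sin/cos-encoded hour, stage code, day/night
indicator and the co-observed climate variable. The alternative —
pooling sensors as mutual predictors — was rejected because the
independent-per-dataset protocol is the stated operating mode and
keeps sensors exchangeable. Observed values are never altered
(asserted cell-by-cell), and a fully constant predictor set falls back
to mean imputation with a warning.

## CART

The classifier is written from scratch. Splits minimize weighted child
Gini over candidate thresholds at midpoints between consecutive
distinct sorted feature values; when rounding would collapse a
midpoint onto the right neighbor, the left value is used so both
children stay nonempty. Ties break deterministically: lowest feature
index, then lowest threshold; leaves predict the majority class with
ties toward the earlier class in the declared order (optimal,
suboptimal, critical). Stopping: min_split = 20, min_leaf = 7,
max_depth = 30 (conventional defaults for this algorithm family).

Cost-complexity pruning computes the weakest-link sequence: at each
step every internal node's link strength
g(t) = (R(t) − R(T_t))/(|leaves(T_t)| − 1) is evaluated on the current
subtree and all minimizers collapse, giving strictly increasing alphas
and nested subtrees (both asserted). The complexity parameter cp is
alpha normalized by the root's resubstitution risk (relative-error
convention, root error = 1), so the grid is scale-free; candidate cp
values are geometric midpoints of consecutive path cps.

Model selection is time-aware. Cross-validation uses an expanding
origin: after an initial window of 50% of the training rows, k = 5
contiguous validation blocks partition the tail (both configurable; no
shuffling anywhere). The 1-SE rule picks the largest cp whose mean CV
error is within one standard error of the minimum. Final evaluation
uses the last ⌈30%⌉ of rows as a temporal holdout. Metrics: overall
accuracy; balanced accuracy (mean recall over classes present in
truth); macro F1 (per-class F1 with empty denominators scored 0);
Cohen's κ (NaN with a warning when chance agreement is 1).

## Summaries and economics

One-way ANOVA uses the between/within sum-of-squares decomposition
with the p-value from the F distribution; it matches
`scipy.stats.f_oneway` to 1e-8 in tests (used there only as a
cross-check). Descriptive tables exclude days with <50% record
coverage from the daily-extrema means (partial days would bias minima
and maxima); exclusions are logged.

Internal–external comparisons align 5-min internal records against
daily external values of the same date. Because the external station
is daily, the daytime external temperature is proxied by the daily
maximum and the nighttime one by the daily minimum, and external RH by
the daily mean throughout — a documented limitation, not an estimate
of sub-daily external dynamics.

Economics: shares are weight/total·100, reported raw and rounded.
Rounded shares use **largest-remainder (sum-preserving) rounding** to
one decimal: plain half-up rounding of the published category weights
yields shares summing to 99.9 with the smallest category at 5.2,
whereas the published table sums to exactly 100.0 with 5.3 —
largest-remainder allocation reproduces every published cell. Yield
per plant uses the exact 10,000 m²/ha conversion. The PAR transmission
coefficient is the mean of pairwise inside/outside ratios, dropping
nonpositive outside readings with a warning.

## Synthetic generator

The generator emulates the study conditions every downstream stage
assumes: four quadrant sensors plus one external series on a complete
5-min grid over 190 days.

* **Diurnal backbone**: piecewise-cosine shape with the minimum at
  06:00 and maximum at 14:00 (asymmetric 8 h rise / 16 h fall), no
  seasonal photoperiod drift (equatorial site). Per stage, the curve's
  level and day/night contrast are solved exactly so daytime and
  nighttime means hit the configured targets; the default targets make
  the overall stage means land on field-typical values (e.g. a
  vegetative mean of ≈20.3 °C for the eastern quadrant, the
  calibration check in the tests).
* **Humidity** is generated anti-phase to temperature (pre-dawn RH
  peak) and clipped to [0, 100], reproducing the nocturnal humidity
  excess of passive greenhouses.
* **Noise**: independent Gaussian per record (1.2 °C / 3.5% RH) plus a
  stationary AR(1) day-level drift (0.7 °C / 2.5% RH, φ = 0.6), giving
  realistic absolute extrema without radiation physics.
* **Spatial heterogeneity**: constant additive per-quadrant offsets,
  recovered from realized sensor means in tests and large enough for
  ANOVA to flag.
* **Missingness**: MCAR gaps with geometric lengths (mean 6 records by
  default; singletons arise naturally), per-sensor fractions 0.9%,
  0.7%, 2.9%, 2.3% — the low single-percent regime of real
  deployments. The mechanism is a modeling choice: real dropouts are
  plausibly not completely at random (e.g. radio interference
  correlated with weather), so imputation results on synthetic data
  bound only the MCAR case.
* The **external** series uses a much smaller amplitude and noise, so
  internal variance dominates, and is aggregated into the daily
  weather table with synthetic precipitation/wind/radiation columns.

What the generator does **not** emulate: radiative and energy-balance
physics, ventilation dynamics, canopy feedback on sensor
micrositing, vertical stratification, and informative missingness.
Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and its statistical behavior under the assumed structure,
not performance claims about any particular real greenhouse.

## Problem sizes and determinism

The default test suite runs short cycles (8–12 days) for
imputation-heavy paths and the full 190-day cycle for calibration and
classification checks; the acceptance script uses a 10-day series for
the imputation demonstration and 400 synthetic days for the CART
recovery check — sizes chosen so the statistical properties under test
are comfortably identifiable. All randomness flows from explicit
seeds; the CLI's `all` subcommand is byte-stable across reruns with
the same seed (hash-asserted in tests).

## Known limitations

* The thresholds table is tomato-specific; other crops need a new YAML
  (all 18 stage × period × variable cells are validated on load).
* The imputer provides single (not multiple) imputation; no
  uncertainty propagation.
* No surrogate splits: CART features must be complete (imputation is
  upstream by design).
* The daily external weather alignment cannot resolve sub-daily
  external dynamics (proxy convention above).
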