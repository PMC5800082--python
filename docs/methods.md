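# Methods

This note documents the models the package implements, the defaults it
ships, the numerical choices behind the fits, and what the synthetic-data
tests do and do not demonstrate about real data.

## Egg cold tolerance

Hatch success after cold exposure is modelled per temperature on the percent
scale as a function of exposure duration `x` (days; hour-scale exposures are
fractional days, 6 h = 0.25 d):

- exponential decay `y = A·e^(−k·x) + c` with asymptotic minimal hatch `c`;
- falling logistic `y = L / (1 + B·e^(r·x))` with asymptotic minimal hatch 0
  (for `r > 0`).

Both families are estimated by bounded nonlinear least squares
(`scipy.optimize.curve_fit`, trust-region reflective) on the per-duration
*means of cup percentages* — cups are the replicate unit, so unequal egg
numbers do not reweight cells. Starting values are scale-free: `A` = range
of `y`, `k` = 1/median(`x`), `c` = min(`y`); logistic `L` = 1.05·max(`y`),
`r` = 1, `B` solved from the first point. The family is chosen by the
least-squares AIC `n·ln(RSS/n) + 2(p + 1)` (the +1 counts the residual
variance); ties break toward the exponential. Residuals for the AIC
comparison are on the percent scale by default; an `arcsine` flag compares
on the arcsin(√p) scale instead, while parameters are always reported on
the percent scale, the scale of the asymptote. The variance-stabilising
arcsine transform is also used in the exposure-effect F-test (per-duration
mean proportions regressed on exposure length by OLS).

Two numerical caveats are intentional behaviour:

- A constant hatch series makes `k` unidentifiable; the fit is returned
  flagged `degenerate` with the constant as asymptote.
- The minimal hatch is reported truncated to a whole percent (36.12 → 36),
  matching how such asymptotes are conventionally quoted.

The asymptote estimator on the 10-duration design is slightly left-skewed:
`k` and `c` trade off when the longest exposure has not fully reached the
plateau, so single-experiment estimates of `c` scatter with an SD of ~4–5
percentage points and a mean ~0.9 below the generating value. Averaged over
200 replicate experiments the recovered asymptote therefore sits within
about one percentage point of the generating curve's asymptote; this is an
estimator property, not an optimiser artefact (multi-start never improves
the residual sum of squares).

## Life-trait statistics

- Mortality is summarised per cup (mean ± SD across the 5 cups of a
  treatment) and arcsine-√-transformed for tests; the one-way ANOVA and all
  pairwise two-tailed t-tests (Bonferroni multiplier = number of pairs) run
  on cup-level values, the replicate structure the summary SDs imply.
- Sex ratio per temperature is a two-sided exact binomial test of p = 0.5 on
  counts pooled over cups (`scipy.stats.binomtest`).
- Mean ages at pupation, emergence and adult death per temperature are fitted
  with `age = A·e^(−k·T) + c` by bounded NLS (`A, k, c ≥ 0`); a flat age
  profile is returned flagged degenerate with `k = 0`.
- Body size (R1 wing-vein length) gets a two-way ANOVA (temperature × sex,
  type-II, statsmodels OLS). The dimorphism-free scale is the percentage
  difference to each sex's *maximal group mean*. The group-mean reference is
  deliberate: an individual-level observed maximum is a noisy order
  statistic whose error is shared by a whole sex, inflating the sex term's
  null distribution. Even with group means the reference is estimated, so
  the sex term retains some inflation; the test suite checks medians over
  replicates (median sex p > 0.05, sex F reduced more than 20-fold versus
  the raw scale) rather than a per-replicate significance rate.
- Ages are measured from day 0 of the experiment; the 0–24 h age of the
  starting larvae is ignored, so absolute ages may be slightly
  underestimated — a property of the emulated design, kept as-is.

## Thermal performance and cardinal temperatures

Performance ("cumulative female survival") at rearing temperature `T` is
survival-to-adult times female developmental rate (1 / mean female age at
emergence), in day⁻¹; temperatures with no emerged female get performance 0,
and those zeros stay in the fit — they carry the information that locates
the lower limit. The candidate zoo is Brière-1 with free shape `m`, Brière-1
with `m = 2` fixed, a clipped quadratic, a Gaussian, and a rectified linear
model; each is fitted by multi-start bounded NLS (limit starts offset ±2–4 °C
from the outermost positive-performance temperatures, amplitude from the
peak), non-convergent candidates receive infinite AIC and zero Akaike
weight, and weights are `exp(−Δᵢ/2)` normalised to 1.

For the Brière-1 curve `y = a·T·(T − T_min)·(T_max − T)^(1/m)` the optimum
solves dy/dT = 0, equivalent to the quadratic
`(2T − T_min)(T_max − T) − T(T − T_min)/m = 0`, which has exactly one root
in (max(T_min, 0), T_max); it is found by Brent bracketing (xtol 1e-10) and
agrees with the closed form
`T_opt = [2mT_max + (m+1)T_min + √(4m²T_max² + (m+1)²T_min² − 4m²T_minT_max)] / (4m+2)`.
At the shipped defaults (a = 6×10⁻⁶, m = 2.0, T_min = 7 °C, T_max = 31 °C)
T_opt = 25.61 °C, i.e. 26 °C to the nearest degree. `T_opt` is invariant to
rescaling `a`.

Parameter recovery at the 16 rearing temperatures under 5 % relative noise:
medians over 200 replicates land within ~5 % (a), ~7 % (m), ~3 % (T_min),
<1 % (T_max) of truth and T_opt within <0.1 °C. The `a`–`m` correlation
drives most of the spread; `m` is the weakly identified parameter of the
family.

## Generation time and voltinism

`G(T) = A·e^(−k·T) + c` days, defaults A = 290.75, k = 0.17 °C⁻¹,
c = 22.32 d. The constant includes a 14-day pre-oviposition shift
(copulation, blood meal, egg maturation) on top of the age-at-emergence fit;
`GenerationTimeModel.from_emergence_fit` performs exactly that shift, so the
emergence fit and the shipped G(T) are consistent by construction. `G` is
treated as a time in days — the only dimensionally consistent reading of the
fitted function.

Annual voltinism accumulates monthly blocks, Σ days_in_month / G(T_month),
with real month lengths on a 365-day calendar. No low-temperature cutoff is
applied by default — G is evaluated as printed even below the 7 °C
developmental minimum, where contributions are negligible but non-zero; a
`t_min_cutoff` option zeroes such months for sensitivity analysis. Scenario
layers given as monthly tmin/tmax are combined as midpoints. Point
extraction is nearest-cell (no interpolation), matching the coarse cell
size of the intended 2.5′ climatologies; points farther than half a cell
from the border are flagged out-of-extent.

Rasters are xarray DataArrays (dims month/lat/lon) stored as NetCDF3;
integer-packed storage (value = °C × 10) is supported via a scale factor.
No GeoTIFF support: NetCDF and CSV are the package's exchange formats.

## Frost events

A frost event is a maximal run of ≥ `min_run_days` (default 3) consecutive
days with daily mean temperature ≤ `threshold` (default 0 °C, inclusive).
Maximal runs count once regardless of length — biologically, a larval cohort
dies once. Calendar gaps must be explicit and split the series; a candidate
run may not bridge a gap. The per-year rate divides by the exact span in
days / 365.25 (leap days in real data are kept); a run spanning New Year is
attributed to its start year in the per-year breakdown.

Event *counts* are deliberately not monotone under cooling: lowering all
temperatures can merge two separate runs into one longer run and reduce the
count by one. The monotone invariants — which the tests assert — are that
cooling (or raising the threshold) never removes a day from event coverage
and never turns an event-affected series event-free. The gridded variant
vectorises the run-start test (`cold[i..i+r−1]` all true, `cold[i−1]` false)
across cells; any missing day marks the cell no-data.

## Synthetic data: what it does and does not emulate

The generator reproduces the experimental design (16 rearing temperatures ×
5 cups × 40 larvae; 4 cold temperatures × 10 exposure durations × 5 cups ×
20 eggs) and Germany-like climate structure (latitude-lapsed annual mean
~9 °C, seasonal amplitude ~9–10 °C, AR(1) daily noise with coefficient 0.7
and SD 2 °C).

Choices where the emulated study prints no value, fixed once:

- Survival-by-temperature is the Brière performance divided by the
  developmental rate, clipped to [0, 1] — the only factorisation consistent
  with the published product. With the printed `a` this yields low absolute
  survivals (the printed curve's magnitude is ~10× below what the mortality
  table and a 12-day emergence imply); nothing downstream depends on the
  absolute scale, and recovery studies generate performance points directly
  from the curve.
- Age noise is lognormal with CV 0.1 (positive, right-skewed, matching the
  character of reported cup-level SDs); stage ordering pupation < emergence
  < death is enforced by drawing positive stage increments.
- Pupation and adult-death truth curves (250·e^(−0.17T) + 6 and
  320·e^(−0.17T) + 28.32) place pupation ~2 d before emergence and adult
  death ~20 d after it at warm temperatures.
- Female R1 length declines linearly from 4.26 mm at 15 °C to 3.04 mm at
  31 °C; males are 12 % smaller; size CV 0.05.
- Individuals are independent within cups (no within-cup correlation is
  modelled; the emulated study reports none).
- Constant temperatures only: no diurnal or seasonal fluctuation effects on
  development.

Passing tests therefore demonstrate that the estimators recover known
generative truth under the design's sampling noise — not that the field data
satisfy the model, and not the Germany-wide map values, which depend on
external climatologies the package does not ship. On the synthetic
Germany-like climate the voltinism map means fall in the 3–6 generations/yr
envelope and frost events in 0–10 per year, the plausibility envelopes used
in place of those external reproductions.

## Problem sizes used in the shipped checks

Recovery studies run 200 replicates (egg asymptotes, Brière parameters);
unit smoke tests use 40 replicates at a correspondingly wider 15 % band.
Raster property checks use 100×100 monthly grids and 5-year daily grids on
up to 6×6 cells; the frost oracle comparison covers 1000 random series.
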