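# Methods

`vegdyn` analyses per-pixel annual vegetation-index series in three stages —
trend estimation, driver attribution, persistence analysis — and ships a
synthetic-scenario generator that provides ground truth for all three.
This note records the models, the parameter choices that matter, and the
limits of what the synthetic tests demonstrate.

## Per-pixel trend model

For each pixel, growing-season NDVI is regressed on the time index
i = 1..n by ordinary least squares; the closed-form slope

    slope = [n Σ(i·y_i) − Σi · Σy_i] / [n Σi² − (Σi)²]

is the trend in NDVI/yr (annual steps). Significance is the two-sided
t-test on the slope with n − 2 degrees of freedom; for simple regression
this is numerically identical to testing the Pearson correlation, so the
choice between the two framings is immaterial. The default significance
threshold is p < 0.1, configurable.

Slopes are binned into five classes at ±0.001 and ±0.005 NDVI/yr
(notable/slight degradation, stable, slight/notable improvement); the
interval ends follow the convention that ±0.001 belongs to "stable" and
±0.005 to the "slight" classes. A degenerate perfect-line fit (residual
sum of squares at float-noise level, below 1e−14 of the total sum of
squares) reports p = 0 when the slope is nonzero and p = 1 when it is
exactly constant.

No Mann–Kendall/Theil–Sen variants and no autocorrelation correction are
provided: the pipeline is a linear-regression trend map by design.

## Attribution by residual analysis

Per pixel, NDVI is regressed on annual mean temperature T and annual
precipitation P:

    NDVI_pre = a·T + b·P + c,    NDVI_res = NDVI_obs − NDVI_pre.

The trend of NDVI_pre is read as the climate-driven change, the trend of
NDVI_res as the human-driven change. `slope_res` is computed as
`slope_obs − slope_pre` rather than re-fit: the OLS slope is linear in
the series, so this decomposition is exact and the three slopes can never
be mutually inconsistent.

The six-condition contribution scheme converts the three slope signs into
percentages: when all three slopes share a sign, CC = 100·slope_pre /
slope_obs and HA = 100·slope_res/slope_obs (shares of a same-signed sum,
each automatically in [0, 100]); when the components disagree in sign,
100% goes to the component whose sign matches the observed trend. A
component slope of exactly zero is handled by the same winner-take-all
rule (the other component carries the whole observed trend). Pixels with
|slope_obs| ≤ 1e−8 NDVI/yr are left undefined — percentage shares of a
near-zero trend are meaningless ratios — and are excluded from area means
but counted separately. Area means are unweighted pixel means over
defined valid pixels, computed over all defined pixels (not only
significant-trend ones).

A rank-deficient design (T and P collinear, or both constant) falls back
to the minimum-norm least-squares solution with a collinearity flag.

### Known limitation: finite-sample leakage

Residual attribution identifies the human component only through the
contrast between the time signature of the climate regressors and the
time index itself. Two consequences, both demonstrated by
`vegdyn recover`:

1. Even with zero observation noise, the climate fit absorbs roughly k/n
   of any deterministic human trend (k = 2 regressors, n years) through
   chance sample correlation between the time index and the realised
   climate series — about 8 percentage points of CC-share bias under the
   default scenario. This bias belongs to the method's estimand, not to
   estimation noise, so `recover` reports accuracy both against the
   generator truth and against the method's own noise-free estimand (the
   latter is exactly zero at zero noise and isolates the effect of
   observation noise).
2. When the climate trend is large relative to interannual climate
   variability, the regressors become nearly collinear with the time
   index and the human trend is increasingly credited to climate. The
   default scenario keeps variability dominant (see below) so that the
   attribution problem is identified.

## R/S Hurst analysis

For window size r, the series splits into g = ⌊n/r⌋ non-overlapping
consecutive groups (trailing remainder discarded). Per group: mean,
cumulative deviations X, range R = max X − min X, population standard
deviation S (divisor r), rescaled range R/S; RS̄(r) is the mean over
groups, dropping any group with S = 0. H is the least-squares slope of
ln RS̄ on ln r. H > 0.5 marks a persistent series, H < 0.5 an
anti-persistent one, H = 0.5 no long-range memory; H is binned into seven
persistence classes at 0.2 / 0.35 / 0.5 / 0.65 / 0.8, with H = 0.5 an
exact-equality "random" class that is measure-zero on floats and kept
only for taxonomy fidelity.

Window grids: for short annual series the default is r = 2..⌊n/2⌋ (r =
2..10 at n = 21); for long validation series, power-of-two windows in
[16, n/8] tame the small-window bias. Plain R/S carries a known upward
bias on short memoryless series (≈ 0.55 instead of 0.5 on white noise at
n = 4096 with the power-of-two grid); no Anis–Lloyd correction is
applied, and validation tolerances of ±0.1 absorb the bias. Estimating H
from 21 points is statistically fragile; the implementation is faithful
to the short-series protocol but exposes the window grid so users can
judge sensitivity. Estimates outside (0, 1) are clamped into the open
interval for classification only, flagged, and reported unclamped.

The combined past/future classification crosses three past-trend
categories (degradation < −0.001, stable within ±0.001, improvement >
0.001 NDVI/yr — the trend significance does not enter this cut) with the
persistence classes; when every H falls in (0.2, 1) and never exactly
0.5, five persistence classes are reachable and the label space has 15
members. Hotspot masks flag pixels needing attention: significant
(p < 0.1) past degradation with H > 0.5 (expected to continue), and
significant past improvement with H < 0.5 (expected to reverse); the two
masks are disjoint by construction.

## Synthetic scenarios

Per pixel: T_t = T0 + temp_trend·t + ε_T, P_t = P0 + precip_trend·t +
ε_P, NDVI_t = a·T_t + b·P_t + c + human_rate·t + η, with t = 1..n,
independent Gaussian noise per pixel, NDVI clipped to [0, 1] (a warning
fires if clipping touches > 10% of values; defaults never clip).
Randomness derives from one seed, split by variable then pixel
(row-major), so enlarging the grid never reshuffles existing pixels.

Defaults (one 25×20 grid, 21 years): T0 = 3 °C, P0 = 550 mm — an
alpine-meadow-like baseline; warming 0.02 °C/yr and wetting 1.0 mm/yr —
modest secular drifts; interannual sd 0.6 °C and 60 mm — realistic
year-to-year weather variability that deliberately dominates the drift,
the identifiability condition discussed above; sensitivities a = 0.02
NDVI/°C, b = 2e−4 NDVI/mm, baseline c = 0.30, observation noise sd 0.01
NDVI. The human-activity field is four equal column bands at −0.003,
+0.0015, +0.0025, +0.0035 NDVI/yr — a degrading band plus three grades of
restoration-driven greening, mirroring a region where most project areas
green at slight-improvement rates while a minority degrades. Every
band's deterministic observed trend lies outside the ±0.001 stable band,
so the percentage attribution is well-conditioned on all pixels.

Ground truth: the climate-component slope is the OLS trend of the
realised a·T_t + b·P_t — the climate forcing the pixel actually
experienced, weather noise included; only the NDVI observation noise η is
excluded. The alternative (the ensemble trend a·temp_trend +
b·precip_trend) differs from the realised trend by a sd of ≈ 6e−4 NDVI/yr
under the defaults and would charge that difference to the estimator as
fake error. The true CC share applies the same six-condition scheme to
(slope_climate, human_rate), so truth and estimate share one definition.

What the generator does **not** emulate: spatial autocorrelation (pixels
are independent, so zonal statistics on synthetic data understate
real-map variance of area shares), sub-annual phenology, non-linear or
lagged vegetation–climate responses, disturbance events, and
autocorrelated observation noise. Passing recovery tests therefore shows
the estimators are correct and well-calibrated under the model's own
assumptions — not that residual attribution is unbiased on real
landscapes where those assumptions fail.

Fractional Gaussian noise (the persistence test-bed) is generated by
circulant embedding with the exact fGn autocovariance γ(k) = ½(|k+1|^2H −
2|k|^2H + |k−1|^2H), falling back to the O(n²) sequential conditional
(Durbin–Levinson) recursion if an embedding eigenvalue is negative;
H = 0.5 short-circuits to i.i.d. Gaussian draws.

## I/O conventions

Cubes travel as TIFF files (multi-page, one band per year, or one
single-band file per year) with years, the 6-parameter affine transform
and the nodata value stored as JSON in the ImageDescription tag. A pixel
that is nodata in any year is excluded entirely: every per-pixel
statistic assumes gap-free series. The growing season is April 1 –
October 31 inclusive; annual compositing is the unweighted arithmetic
mean of in-window layers, averaged in date order so the result is
independent of input ordering; a year with no in-window layer is a hard
error. Pixels are excluded when their multi-year mean growing-season
NDVI falls below 0.1 — the period-mean rule keeps series gap-free, and a
per-year variant is available (`rule="per_year"`); the 0.1 boundary is
inclusive (≥ 0.1 is valid). Grids are row-major, origin upper-left,
0-based internally; no reprojection or resampling is performed — inputs
must be grid-aligned.

## Problem sizes used in the shipped checks

Recovery and conservation checks run on 25×20 (500-pixel) and 50×50
scenarios with 21-year series. Hurst calibration uses 100 replicates of
length 4096 (white noise) and 2048 (fGn), with power-of-two windows;
fGn second-order statistics use 200 replicates of length 1024. These
sizes give Monte-Carlo error comfortably inside the stated tolerances
while keeping the full suite in the tens of seconds.
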