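# vegdyn

Per-pixel analysis of vegetation dynamics from annual raster time series:
where is vegetation greening or browning, how much of that change is
driven by climate versus human activities, and will the observed trends
persist?

The package is aimed at ecological remote-sensing work that starts from a
growing-season NDVI cube (one value per pixel per year) plus matching
annual mean-temperature and precipitation cubes, and ends in maps and
zonal tables of trend classes, driver contributions, and persistence —
for example, evaluating ecological restoration projects on a
vegetated plateau. It ships a synthetic-scenario generator with full
ground truth, so every stage of the pipeline is testable end to end.

## Methods at a glance

**Trend.** Per pixel, the OLS slope of NDVI on the year index i = 1..n,

  slope = (n Σ i·NDVI_i − Σi ΣNDVI_i) / (n Σ i² − (Σi)²),

with a two-sided t-test (df = n−2, default threshold p < 0.1) and five
trend classes cut at ±0.001 and ±0.005 NDVI·yr⁻¹.

**Attribution (residual analysis).** Per pixel, fit NDVI_pre = a·T + b·P + c
and form NDVI_res = NDVI_obs − NDVI_pre. The trend of NDVI_pre is the
climate-change (CC) signal, the trend of NDVI_res the human-activity (HA)
signal. Six sign conditions convert the slope triple into percentage
contributions: same-signed triples split proportionally
(CC = 100·slope_pre/slope_obs), mixed signs assign 100% to the component
matching the observed trend's sign.

**Persistence.** Rescaled-range (R/S) analysis: for each window size r the
series is cut into ⌊n/r⌋ groups; per group the range of cumulative
deviations is divided by the population standard deviation; H is the
log–log slope of the group-mean R/S against r. H > 0.5 means the past
trend tends to continue, H < 0.5 that it tends to reverse. Seven
persistence classes (cuts at 0.2/0.35/0.5/0.65/0.8) combine with three
trend categories (±0.001 NDVI·yr⁻¹) into at most 15 observed
past-and-future labels, and two hotspot masks flag significant
degradation expected to persist and significant improvement expected to
reverse.

See `docs/methods.md` for assumptions, parameter defaults, and known
limitations (notably the finite-sample leakage bias of residual
attribution).

## Worked example

Simulate a default scenario (25×20 pixels, 21 years, four human-pressure
bands at −0.003…+0.0035 NDVI/yr on top of a warming, wetting climate) and
run the full pipeline:

```sh
vegdyn simulate --seed 7 --out scen/
vegdyn analyze --scenario scen/ --out results/
```

`analyze` writes slope/p-value/CC%/HA%/Hurst/hotspot rasters, summary
CSVs, and prints `report.json`:

```json
{
 "n_valid_pixels": 500,
 "mean_slope": 0.0017105432767098945,
 "trend_class_shares": {
  "frac_slight_degradation": 0.246,
  "frac_stable": 0.032,
  "frac_slight_improvement": 0.698,
  "frac_notable_improvement": 0.024,
  "frac_slope_positive": 0.75,
  "frac_significant_p0.1": 0.946
 },
 "mean_cc_pct": 23.92,
 "mean_ha_pct": 76.08,
 "hurst": {"mean": 0.705, "min": 0.455, "max": 0.910, "frac_gt_0.5": 0.994},
 "combined_class_shares": {
  "improvement_medium_sust": 0.47,
  "improvement_weak_sust": 0.166,
  "degradation_medium_sust": 0.162
 },
 "hotspots": {"sustained_degradation": 119, "unsustainable_improvement": 2}
}
```

(abridged; floats shortened). Reading it: the region greens on average at
1.7×10⁻³ NDVI·yr⁻¹, with 75% of pixels trending upward and 72% in the
slight/notable-improvement classes; human activities dominate the change
(HA 76% on average — as built into this scenario's strong human-pressure
bands); the mean Hurst exponent 0.705 with 99% of pixels above 0.5 says
the trends are mostly persistent; 119 pixels combine a significant
degradation trend with persistent dynamics — the degrading band — and are
flagged as priority hotspots.

Check how well attribution recovers the generator's ground truth across
observation-noise levels:

```sh
vegdyn recover --seed 7 --out rec/
```

```
 noise_sd  n_pixels  mae_vs_truth  bias_vs_truth  mae_vs_estimand
     0.00       500      8.464250       8.464250          0.00000
     0.01       500      8.823649       8.737779          2.66172
     0.03       500     13.852129      12.478104         10.23090
```

`mae_vs_truth` is the mean absolute error of the estimated CC share
against the generative truth; its noise-free floor (~8.5 points) is the
method's intrinsic leakage bias, while `mae_vs_estimand` isolates the
error added by observation noise alone.

The same functionality is available as a library
(`vegdyn.trend_map`, `vegdyn.attribute_map`, `vegdyn.hurst_map`, ...)
on `AnnualCube` objects.

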