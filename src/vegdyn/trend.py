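"""Per-pixel linear NDVI trends, significance, and 5-class labelling.

The trend is the ordinary-least-squares slope of growing-season NDVI on the
time index i = 1..n (annual steps, so units are NDVI per year), computed
with the classic closed form

    slope = [n * sum(i * y_i) - sum(i) * sum(y_i)] / [n * sum(i^2) - (sum(i))^2]

Significance is the two-sided t-test on the slope with n - 2 degrees of
freedom (the standard companion of regression trend maps; for simple
regression it is numerically identical to the test on the correlation
coefficient).  Slopes are binned into five classes at +/-0.001 and
+/-0.005 NDVI/yr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cube import AnnualCube

TREND5_CLASSES = (
    "notable_degradation",
    "slight_degradation",
    "stable",
    "slight_improvement",
    "notable_improvement",
)

#: slope bin edges (NDVI/yr) separating the five classes
TREND5_EDGES = (-0.005, -0.001, 0.001, 0.005)


@dataclass
class TrendResult:
    """Per-pixel trend grids over a valid mask."""

    slope: np.ndarray        # NDVI/yr
    intercept: np.ndarray    # NDVI at i = 0
    p_value: np.ndarray      # two-sided, NaN outside mask
    trend_class5: np.ndarray  # object array of class names, '' outside mask
    valid: np.ndarray        # the mask the stats were computed over


def _check_series(y: np.ndarray, min_n: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be 1-D")
    if y.size < min_n:
        raise ValueError(f"series too short: n={y.size} < {min_n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    return y


def _slope_core(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form OLS slope/intercept along axis 0 with i = 1..n."""
    n = values.shape[0]
    i = np.arange(1, n + 1, dtype=float).reshape((n,) + (1,) * (values.ndim - 1))
    si = n * (n + 1) / 2.0
    sii = n * (n + 1) * (2 * n + 1) / 6.0
    siy = np.sum(i * values, axis=0)
    sy = np.sum(values, axis=0)
    denom = n * sii - si * si
    slope = (n * siy - si * sy) / denom
    intercept = sy / n - slope * (si / n)
    return slope, intercept


def ols_slope_intercept(series: np.ndarray) -> tuple[float, float]:
    """Least-squares slope (per year) and intercept of one series, i = 1..n."""
    y = _check_series(series, 3)
    slope, intercept = _slope_core(y)
    return float(slope), float(intercept)


def _pvalue_core(values: np.ndarray) -> np.ndarray:
    """Two-sided p of the OLS slope along axis 0 (df = n - 2), vectorised.

    A perfect linear fit (zero residual variance) gets p = 0: the trend is
    unambiguous even though the t statistic degenerates.
    """
    n = values.shape[0]
    slope, intercept = _slope_core(values)
    i = np.arange(1, n + 1, dtype=float).reshape((n,) + (1,) * (values.ndim - 1))
    resid = values - (intercept + slope * i)
    sse = np.sum(resid**2, axis=0)
    sst = np.sum((values - values.mean(axis=0)) ** 2, axis=0)
    sxx = n * (n * n - 1) / 12.0  # sum((i - mean(i))^2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / (n - 2) / sxx)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    # residual variance indistinguishable from float noise: perfect fit
    degenerate = sse <= 1e-14 * sst
    p = np.where(degenerate & (slope != 0), 0.0, p)
    p = np.where(degenerate & (slope == 0), 1.0, p)
    return p


def slope_pvalue(series: np.ndarray) -> float:
    """Two-sided p-value of the trend slope of one series (df = n - 2 >= 1)."""
    y = _check_series(series, 3)
    return float(_pvalue_core(y))


def classify_trend5(slope: float) -> str:
    """Five-class trend label at the +/-0.001 and +/-0.005 NDVI/yr cuts.

    notable_degradation  slope < -0.005
    slight_degradation   -0.005 <= slope < -0.001
    stable               -0.001 <= slope <= 0.001
    slight_improvement   0.001 < slope <= 0.005
    notable_improvement  slope > 0.005
    """
    if not np.isfinite(slope):
        raise ValueError(f"non-finite slope: {slope}")
    e1, e2, e3, e4 = TREND5_EDGES
    if slope < e1:
        return "notable_degradation"
    if slope < e2:
        return "slight_degradation"
    if slope <= e3:
        return "stable"
    if slope <= e4:
        return "slight_improvement"
    return "notable_improvement"


def _classify5_grid(slope: np.ndarray, valid: np.ndarray) -> np.ndarray:
    e1, e2, e3, e4 = TREND5_EDGES
    out = np.full(slope.shape, "", dtype=object)
    s = slope
    out[valid & (s < e1)] = "notable_degradation"
    out[valid & (s >= e1) & (s < e2)] = "slight_degradation"
    out[valid & (s >= e2) & (s <= e3)] = "stable"
    out[valid & (s > e3) & (s <= e4)] = "slight_improvement"
    out[valid & (s > e4)] = "notable_improvement"
    return out


def trend_map(
    cube: AnnualCube,
    valid: np.ndarray | None = None,
    alpha: float = 0.1,
) -> tuple[TrendResult, pd.DataFrame]:
    """Per-pixel trend grids plus an area-fraction table.

    The table reports, over valid pixels: the share of each of the five
    classes, the share with slope > 0, and the share significant at
    ``p < alpha`` (default 0.1).
    """
    if valid is None:
        valid = ~cube.nodata_mask
    valid = np.asarray(valid, dtype=bool) & ~cube.nodata_mask
    if not valid.any():
        raise ValueError("no valid pixels for trend analysis")
    vals = np.where(np.isfinite(cube.values), cube.values, 0.0)
    slope, intercept = _slope_core(vals)
    p = _pvalue_core(vals)
    slope = np.where(valid, slope, np.nan)
    intercept = np.where(valid, intercept, np.nan)
    p = np.where(valid, p, np.nan)
    classes = _classify5_grid(slope, valid)
    result = TrendResult(slope, intercept, p, classes, valid)

    nv = int(valid.sum())
    rows = [
        {"statistic": f"frac_{cls}", "value": float(np.sum(classes[valid] == cls) / nv)}
        for cls in TREND5_CLASSES
    ]
    rows.append({"statistic": "frac_slope_positive",
                 "value": float(np.sum(slope[valid] > 0) / nv)})
    rows.append({"statistic": f"frac_significant_p{alpha:g}",
                 "value": float(np.sum(p[valid] < alpha) / nv)})
    rows.append({"statistic": "mean_slope", "value": float(np.mean(slope[valid]))})
    return result, pd.DataFrame(rows)
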