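"""Residual analysis: splitting NDVI trends into climate and human drivers.

Per pixel, growing-season NDVI is regressed on annual mean temperature T
and annual precipitation P:

    NDVI_pre = a*T + b*P + c         (climate-explained part)
    NDVI_res = NDVI_obs - NDVI_pre   (everything else: human activities)

The trend slopes of the observed, predicted and residual series are then
converted into percentage contributions of climate change (CC) and human
activities (HA) by the six-condition sign scheme: when all three slopes
share a sign, CC = 100*slope_pre/slope_obs and HA = 100*slope_res/slope_obs
(shares of a same-signed sum, each in [0, 100]); when the components
disagree in sign, 100% goes to the component whose sign matches the
observed trend.  Pixels with an essentially zero observed slope are left
undefined (the scheme covers strict signs only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cube import AnnualCube, ZoneMask, check_aligned
from . import io as _io
from .trend import _slope_core

#: |slope_obs| at or below this (NDVI/yr) counts as "no observed trend"
STABLE_EPS = 1e-8

CONDITIONS = (
    "proportional_greening",   # obs>0, pre>0, res>0
    "climate_only_greening",   # obs>0, pre>0, res<0
    "human_only_greening",     # obs>0, pre<0, res>0
    "proportional_browning",   # obs<0, pre<0, res<0
    "climate_only_browning",   # obs<0, pre<0, res>0
    "human_only_browning",     # obs<0, pre>0, res<0
    "undefined_stable",
)


@dataclass
class ClimateFit:
    """Per-pixel fit of NDVI on temperature and precipitation."""

    a: float               # NDVI per degC
    b: float               # NDVI per mm
    c: float               # intercept NDVI
    predicted: np.ndarray  # NDVI_pre series
    residual: np.ndarray   # NDVI_res = NDVI_obs - NDVI_pre
    collinearity_flag: bool = False


@dataclass
class AttributionResult:
    """Per-pixel attribution grids over a valid mask."""

    slope_obs: np.ndarray
    slope_pre: np.ndarray
    slope_res: np.ndarray
    cc_pct: np.ndarray     # NaN where undefined
    ha_pct: np.ndarray
    condition: np.ndarray  # object array of condition names
    valid: np.ndarray


def fit_climate_model(ndvi: np.ndarray, T: np.ndarray, P: np.ndarray) -> ClimateFit:
    """Least-squares fit of NDVI = a*T + b*P + c for one pixel.

    A rank-deficient design (T and P collinear, or both constant) returns
    the minimum-norm least-squares solution with ``collinearity_flag`` set.
    """
    y = np.asarray(ndvi, dtype=float)
    t = np.asarray(T, dtype=float)
    p = np.asarray(P, dtype=float)
    if not (y.shape == t.shape == p.shape) or y.ndim != 1:
        raise ValueError("ndvi, T, P must be 1-D series of equal length")
    n = y.size
    if n < 4:
        raise ValueError(f"need at least 4 years to fit the climate model, got {n}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
        raise ValueError("non-finite values in input series")
    X = np.column_stack([t, p, np.ones(n)])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    a, b, c = (float(v) for v in coef)
    pred = X @ coef
    return ClimateFit(a, b, c, pred, y - pred, collinearity_flag=rank < 3)


def contribution_rates(
    slope_obs: float, slope_pre: float, slope_res: float,
    eps: float = STABLE_EPS, tol: float = 1e-6,
) -> tuple[float, float, str]:
    """CC/HA percentage contributions from the three trend slopes.

    Returns ``(cc_pct, ha_pct, condition)``; the percentages are NaN when
    the observed slope is within ``eps`` of zero (condition
    ``undefined_stable``).  The slopes must satisfy the decomposition
    ``slope_res = slope_obs - slope_pre`` within ``tol`` (relative to the
    observed slope's magnitude).
    """
    for v in (slope_obs, slope_pre, slope_res):
        if not np.isfinite(v):
            raise ValueError("non-finite slope")
    scale = max(abs(slope_obs), 1.0)
    if abs(slope_res - (slope_obs - slope_pre)) > tol * scale:
        raise ValueError(
            f"inconsistent slopes: res={slope_res} != obs-pre={slope_obs - slope_pre}"
        )
    if abs(slope_obs) <= eps:
        return float("nan"), float("nan"), "undefined_stable"
    if slope_obs > 0:
        if slope_pre > 0 and slope_res > 0:
            cc = 100.0 * slope_pre / slope_obs
            return cc, 100.0 - cc, "proportional_greening"
        if slope_res <= 0:  # pre carries the greening alone
            return 100.0, 0.0, "climate_only_greening"
        return 0.0, 100.0, "human_only_greening"
    if slope_pre < 0 and slope_res < 0:
        cc = 100.0 * slope_pre / slope_obs
        return cc, 100.0 - cc, "proportional_browning"
    if slope_res >= 0:  # pre carries the browning alone
        return 100.0, 0.0, "climate_only_browning"
    return 0.0, 100.0, "human_only_browning"


def _fit_grid(ndvi: AnnualCube, T: AnnualCube, P: AnnualCube,
              valid: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (a, b, c) and predicted-series slope over a mask."""
    n = ndvi.n_years
    rows, cols = ndvi.shape
    slope_pre = np.full((rows, cols), np.nan)
    coefs = np.full((3, rows, cols), np.nan)
    idx = np.argwhere(valid)
    ones = np.ones(n)
    for r, c in idx:
        X = np.column_stack([T.values[:, r, c], P.values[:, r, c], ones])
        y = ndvi.values[:, r, c]
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        coefs[:, r, c] = coef
        pred = X @ coef
        slope_pre[r, c], _ = _slope_core(pred)
    return coefs, slope_pre, idx


def attribute_map(
    ndvi: AnnualCube, T: AnnualCube, P: AnnualCube,
    valid: np.ndarray | None = None,
    zones: ZoneMask | None = None,
    eps: float = STABLE_EPS,
) -> tuple[AttributionResult, dict[str, pd.DataFrame]]:
    """Per-pixel attribution plus summary tables.

    The residual slope is computed as ``slope_obs - slope_pre`` (the OLS
    slope is linear in the series, so the decomposition is exact and the
    three slopes can never be inconsistent).

    Summaries: ``overall`` (area-mean CC/HA over defined pixels),
    ``by_sign`` (mean CC stratified by the sign of the observed slope), and
    when ``zones`` is given, ``by_zone`` (per-zone mean CC/HA) and
    ``ha_bins`` (per-zone histogram of HA% in 20-point bins).
    """
    check_aligned(ndvi, T, P)
    if valid is None:
        valid = ~ndvi.nodata_mask & ~T.nodata_mask & ~P.nodata_mask
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise ValueError("no valid pixels for attribution")

    obs_vals = np.where(np.isfinite(ndvi.values), ndvi.values, 0.0)
    slope_obs, _ = _slope_core(obs_vals)
    slope_obs = np.where(valid, slope_obs, np.nan)
    _, slope_pre, _ = _fit_grid(ndvi, T, P, valid)
    slope_res = slope_obs - slope_pre

    cc = np.full(valid.shape, np.nan)
    ha = np.full(valid.shape, np.nan)
    cond = np.full(valid.shape, "", dtype=object)
    for r, c in np.argwhere(valid):
        cc[r, c], ha[r, c], cond[r, c] = contribution_rates(
            slope_obs[r, c], slope_pre[r, c], slope_res[r, c], eps=eps
        )
    result = AttributionResult(slope_obs, slope_pre, slope_res, cc, ha, cond, valid)

    defined = valid & (cond != "undefined_stable")
    summaries: dict[str, pd.DataFrame] = {}
    summaries["overall"] = pd.DataFrame([
        {"statistic": "mean_cc_pct", "value": float(np.nanmean(cc[defined])) if defined.any() else np.nan},
        {"statistic": "mean_ha_pct", "value": float(np.nanmean(ha[defined])) if defined.any() else np.nan},
        {"statistic": "n_defined", "value": int(defined.sum())},
        {"statistic": "n_undefined", "value": int((valid & ~defined).sum())},
    ])
    rows = []
    for name, sel in (("slope_obs_positive", defined & (slope_obs > 0)),
                      ("slope_obs_negative", defined & (slope_obs < 0))):
        rows.append({
            "stratum": name,
            "n": int(sel.sum()),
            "mean_cc_pct": float(np.nanmean(cc[sel])) if sel.any() else np.nan,
            "mean_ha_pct": float(np.nanmean(ha[sel])) if sel.any() else np.nan,
        })
    summaries["by_sign"] = pd.DataFrame(rows)
    if zones is not None:
        summaries["by_zone_cc"] = _io.zonal_summary(cc, zones, "mean", valid=defined)
        summaries["by_zone_ha"] = _io.zonal_summary(ha, zones, "mean", valid=defined)
        summaries["ha_bins"] = _io.zonal_summary(
            ha, zones, "histogram", valid=defined, bins=[0, 20, 40, 60, 80, 100.0001]
        )
    return result, summaries
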