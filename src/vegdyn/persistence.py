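"""Rescaled-range (R/S) Hurst analysis and persistence classification.

For a series of length n and each window size r, the series is split into
g = floor(n/r) non-overlapping consecutive groups (trailing remainder
discarded).  Per group: the mean, the cumulative deviations from the mean,
their range R = max - min, and the population standard deviation S
(divisor r).  The rescaled range R/S is averaged over groups to RS_bar(r),
and the Hurst exponent H is the least-squares slope of ln RS_bar on ln r.

H > 0.5 indicates a persistent series (future change continues the past
trend), H < 0.5 an anti-persistent one, H = 0.5 no long-range memory.  H
is binned into seven persistence classes; crossing the three past-trend
categories (degradation / stable / improvement at +/-0.001 NDVI/yr) with
the persistence classes gives the combined past-and-future labels, and the
management "hotspots" are pixels whose significant past trend is expected
to persist in the wrong direction (degradation that will continue) or not
persist in the right one (improvement that will reverse).

For 21-year annual series the default window grid is r = 2..10.  R/S at
such lengths carries a known upward bias on short memoryless series; for
long validation series a power-of-two window grid away from tiny r is
available via ``window_sizes``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cube import AnnualCube
from .trend import _slope_core

H7_CLASSES = (
    "strong_anti",
    "medium_anti",
    "weak_anti",
    "random",
    "weak_sust",
    "medium_sust",
    "strong_sust",
)

#: trend-slope cut (NDVI/yr) separating degradation / stable / improvement
TREND3_EDGE = 0.001


@dataclass
class HurstResult:
    """R/S estimate for one series."""

    H: float
    fit_intercept: float                 # ln c of RS_bar = c * r^H
    rs_points: list[tuple[int, float]]   # (r, mean rescaled range)
    h_class7: str
    clamped: bool = False                # True if H fell outside (0,1)


def rs_curve(
    series: np.ndarray, window_sizes: list[int] | None = None
) -> list[tuple[int, float]]:
    """Mean rescaled range RS_bar(r) for each window size r.

    Defaults to r = 2..floor(n/2).  Groups with zero standard deviation are
    dropped; a window size whose groups are all degenerate is omitted.  At
    least two usable window sizes are required (the log-log fit needs two
    points).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n = x.size
    if n < 4:
        raise ValueError(f"series too short for R/S analysis: n={n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if window_sizes is None:
        window_sizes = list(range(2, n // 2 + 1))
    points: list[tuple[int, float]] = []
    for r in window_sizes:
        r = int(r)
        if r < 2 or r > n:
            raise ValueError(f"window size {r} out of range for n={n}")
        g = n // r
        groups = x[: g * r].reshape(g, r)
        means = groups.mean(axis=1, keepdims=True)
        dev = groups - means
        X = np.cumsum(dev, axis=1)
        R = X.max(axis=1) - X.min(axis=1)
        S = np.sqrt(np.mean(dev**2, axis=1))  # population divisor r
        usable = S > 0
        if not usable.any():
            continue
        points.append((r, float(np.mean(R[usable] / S[usable]))))
    if len(points) < 2 and len(points) < len(window_sizes):
        # degenerate groups (zero spread) wiped out the requested windows
        raise ValueError("fewer than 2 usable window sizes; cannot fit log-log line")
    return points


def hurst_exponent(
    series: np.ndarray, window_sizes: list[int] | None = None,
    clamp_eps: float = 1e-6,
) -> HurstResult:
    """Hurst exponent by least squares on ln RS_bar vs ln r.

    The raw estimate is reported as-is; if it falls outside (0, 1) the
    class label uses the value clamped into the open interval and
    ``clamped`` is flagged.
    """
    points = rs_curve(series, window_sizes)
    if len(points) < 2:
        raise ValueError("need at least 2 (r, RS) points to fit the log-log line")
    ln_r = np.log([p[0] for p in points])
    ln_rs = np.log([p[1] for p in points])
    A = np.column_stack([ln_r, np.ones_like(ln_r)])
    (H, intercept), *_ = np.linalg.lstsq(A, ln_rs, rcond=None)
    H = float(H)
    clamped = not (0.0 < H < 1.0)
    h_for_class = min(max(H, clamp_eps), 1.0 - clamp_eps)
    return HurstResult(H, float(intercept), points, classify_h7(h_for_class), clamped)


def classify_h7(H: float) -> str:
    """Seven-class persistence label.

    strong_anti  0 < H <= 0.2    medium_anti 0.2 < H <= 0.35
    weak_anti    0.35 < H < 0.5  random      H = 0.5 (exact)
    weak_sust    0.5 < H <= 0.65 medium_sust 0.65 < H <= 0.8
    strong_sust  0.8 < H < 1
    """
    if not np.isfinite(H):
        raise ValueError(f"non-finite H: {H}")
    if not (0.0 < H < 1.0):
        raise ValueError(f"H must lie in (0, 1), got {H}")
    if H <= 0.2:
        return "strong_anti"
    if H <= 0.35:
        return "medium_anti"
    if H < 0.5:
        return "weak_anti"
    if H == 0.5:
        return "random"
    if H <= 0.65:
        return "weak_sust"
    if H <= 0.8:
        return "medium_sust"
    return "strong_sust"


def classify_trend3(slope: float, edge: float = TREND3_EDGE) -> str:
    """Three-category past-trend label at +/-0.001 NDVI/yr."""
    if not np.isfinite(slope):
        raise ValueError(f"non-finite slope: {slope}")
    if slope < -edge:
        return "degradation"
    if slope > edge:
        return "improvement"
    return "stable"


def combine_trend_persistence(slope: float, h_class7: str) -> str:
    """Combined past-trend x future-persistence label.

    With all H in (0.2, 1) and never exactly 0.5 (as in typical vegetation
    series), five persistence classes remain and the label space has
    3 x 5 = 15 members.
    """
    if h_class7 not in H7_CLASSES:
        raise ValueError(f"unknown persistence class {h_class7!r}")
    return f"{classify_trend3(slope)}_{h_class7}"


def hurst_map(
    cube: AnnualCube, valid: np.ndarray | None = None,
    window_sizes: list[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel H grid and 7-class label grid."""
    if valid is None:
        valid = ~cube.nodata_mask
    valid = np.asarray(valid, dtype=bool) & ~cube.nodata_mask
    H = np.full(cube.shape, np.nan)
    cls = np.full(cube.shape, "", dtype=object)
    for r, c in np.argwhere(valid):
        res = hurst_exponent(cube.values[:, r, c], window_sizes)
        H[r, c] = res.H
        cls[r, c] = res.h_class7
    return H, cls


def combined_map(
    slope: np.ndarray, h_class: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, pd.DataFrame]:
    """Combined-label grid plus the observed-label inventory (shares sum to 1)."""
    out = np.full(slope.shape, "", dtype=object)
    for r, c in np.argwhere(valid):
        out[r, c] = combine_trend_persistence(slope[r, c], h_class[r, c])
    labels, counts = np.unique(out[valid], return_counts=True)
    nv = counts.sum()
    table = pd.DataFrame(
        {"label": labels, "n": counts, "fraction": counts / nv}
    ).sort_values("fraction", ascending=False, ignore_index=True)
    return out, table


def extract_hotspots(
    slope: np.ndarray, p: np.ndarray, H: np.ndarray,
    alpha: float = 0.1, edge: float = TREND3_EDGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Management-priority masks from past trend and future persistence.

    mask A (sustained degradation): significant past degradation expected
    to persist - slope < -0.001, p < alpha, H > 0.5.
    mask B (unsustainable improvement): significant past improvement
    expected to reverse - slope > 0.001, p < alpha, H < 0.5.
    The masks are disjoint by construction.
    """
    slope = np.asarray(slope, dtype=float)
    p = np.asarray(p, dtype=float)
    H = np.asarray(H, dtype=float)
    if not (slope.shape == p.shape == H.shape):
        raise ValueError("slope, p and H grids must share one shape")
    with np.errstate(invalid="ignore"):
        mask_a = (slope < -edge) & (p < alpha) & (H > 0.5)
        mask_b = (slope > edge) & (p < alpha) & (H < 0.5)
    return mask_a, mask_b
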