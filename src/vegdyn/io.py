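"""Raster and table I/O, growing-season compositing, masks, zonal summaries.

Rasters are TIFF files (one band per year as pages of a multi-page file, or
one single-band file per year) written via :mod:`tifffile`; the year axis,
affine transform and nodata value travel in a JSON document stored in the
TIFF ImageDescription tag, so a cube round-trips losslessly.

The growing season is April-October: sub-annual layers are averaged to one
annual value per pixel over that window.  Pixels whose multi-year mean
growing-season NDVI falls below 0.1 (sparse/non-vegetated) are excluded
from all downstream analysis; the 0.1 boundary itself is kept valid.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .cube import AnnualCube, GridTransform, ZoneMask

_DESC_KEY = "vegdyn_cube"

GROWING_SEASON_MONTHS = range(4, 11)  # April..October inclusive


# ---------------------------------------------------------------------------
# raster read/write


def write_annual_cube(path, cube: AnnualCube, nodata: float = -9999.0) -> None:
    """Write a cube as a multi-page TIFF (one page per year)."""
    data = cube.values.astype(np.float64).copy()
    data[:, cube.nodata_mask] = nodata
    meta = {
        _DESC_KEY: {
            "years": cube.years,
            "transform": list(cube.transform),
            "nodata": nodata,
        }
    }
    tifffile.imwrite(str(path), data, photometric="minisblack",
                     description=json.dumps(meta))


def _read_tiff(path) -> tuple[np.ndarray, dict | None]:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = None
    if desc:
        try:
            parsed = json.loads(desc)
            meta = parsed.get(_DESC_KEY)
        except (ValueError, AttributeError):
            meta = None
    return np.asarray(data, dtype=float), meta


def read_cube(path) -> AnnualCube:
    """Read a multi-page cube written by :func:`write_annual_cube`."""
    data, meta = _read_tiff(path)
    if data.ndim == 2:
        data = data[None]
    if meta is None:
        raise ValueError(f"{path}: not a vegdyn cube (missing metadata tag)")
    nodata = meta["nodata"]
    mask = np.any(data == nodata, axis=0)
    data = data.copy()
    data[:, mask] = np.nan
    return AnnualCube(
        values=data,
        years=meta["years"],
        transform=GridTransform(*meta["transform"]),
        nodata_mask=mask,
    )


def read_annual_cube(
    paths: Sequence, years: Sequence[int], nodata: float | None = None
) -> AnnualCube:
    """Assemble a cube from single-band rasters, one file per year.

    All rasters must share shape and geometry.  A pixel that is nodata in
    any year is masked in every year (per-pixel statistics need gap-free
    series).
    """
    paths = list(paths)
    years = [int(y) for y in years]
    if len(paths) != len(years):
        raise ValueError(f"{len(paths)} paths but {len(years)} years")
    layers = []
    transform: GridTransform | None = None
    nodata_val = nodata
    for p in paths:
        data, meta = _read_tiff(p)
        if data.ndim == 3:
            if data.shape[0] != 1:
                raise ValueError(f"{p}: expected a single band, got {data.shape[0]}")
            data = data[0]
        tr = GridTransform(*meta["transform"]) if meta else GridTransform()
        if meta and nodata_val is None:
            nodata_val = meta["nodata"]
        if transform is None:
            transform = tr
            shape = data.shape
        else:
            if data.shape != shape:
                raise ValueError(
                    f"{p}: grid shape {data.shape} differs from first raster {shape}"
                )
            if tr != transform:
                raise ValueError(f"{p}: grid geometry differs from first raster")
        layers.append(data)
    stack = np.stack(layers)
    mask = np.zeros(stack.shape[1:], dtype=bool)
    if nodata_val is not None:
        mask = np.any(stack == nodata_val, axis=0)
    mask |= np.any(~np.isfinite(stack), axis=0)
    stack = stack.copy()
    stack[:, mask] = np.nan
    return AnnualCube(stack, years, transform or GridTransform(), mask)


def write_single_band(path, layer: np.ndarray, transform: GridTransform = GridTransform(),
                      nodata: float = -9999.0) -> None:
    """Write one 2-D layer as a single-band TIFF with cube-style metadata."""
    data = np.asarray(layer, dtype=np.float64).copy()
    data[~np.isfinite(data)] = nodata
    meta = {_DESC_KEY: {"years": [0], "transform": list(transform), "nodata": nodata}}
    tifffile.imwrite(str(path), data, description=json.dumps(meta))


# ---------------------------------------------------------------------------
# growing-season compositing


def composite_growing_season(
    layers: Iterable[tuple[_dt.date, np.ndarray]],
    transform: GridTransform = GridTransform(),
) -> AnnualCube:
    """Average dated sub-annual NDVI layers to annual growing-season means.

    Layers dated April 1 - October 31 (inclusive) contribute to their year's
    unweighted arithmetic mean; layers outside the window are ignored.  Every
    year spanned by the input must have at least one in-window layer: the
    output cube must be gap-free.
    """
    by_year: dict[int, list[tuple[_dt.date, np.ndarray]]] = {}
    all_years: set[int] = set()
    shape = None
    for date, arr in layers:
        arr = np.asarray(arr, dtype=float)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(f"layer dated {date}: shape {arr.shape} != {shape}")
        all_years.add(date.year)
        if date.month in GROWING_SEASON_MONTHS:
            by_year.setdefault(date.year, []).append((date, arr))
    # average in date order so the result is independent of input ordering
    for y in by_year:
        by_year[y] = [a for _, a in sorted(by_year[y], key=lambda da: da[0])]
    if shape is None:
        raise ValueError("no layers supplied")
    years = sorted(all_years)
    missing = [y for y in range(years[0], years[-1] + 1) if y not in by_year]
    if missing:
        raise ValueError(
            f"years with no April-October layer: {missing} (cube must be gap-free)"
        )
    years = list(range(years[0], years[-1] + 1))
    values = np.stack([np.mean(by_year[y], axis=0) for y in years])
    mask = np.any(~np.isfinite(values), axis=0)
    return AnnualCube(values, years, transform, mask)


# ---------------------------------------------------------------------------
# validity mask


def build_valid_mask(ndvi_cube: AnnualCube, threshold: float = 0.1,
                     rule: str = "period_mean") -> np.ndarray:
    """Pixels carrying enough vegetation signal to analyse.

    A pixel is valid iff it is not nodata and its growing-season NDVI
    reaches ``threshold`` (default 0.1, inclusive).  ``rule`` selects
    whether the threshold applies to the multi-year mean (``period_mean``,
    default: a pixel is kept or dropped for the whole period, so series stay
    gap-free) or to every year (``per_year``: all years must reach it).
    """
    if rule == "period_mean":
        metric = np.nanmean(ndvi_cube.values, axis=0)
    elif rule == "per_year":
        metric = np.nanmin(ndvi_cube.values, axis=0)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    with np.errstate(invalid="ignore"):
        valid = (metric >= threshold) & ~ndvi_cube.nodata_mask
    if not valid.any():
        warnings.warn("valid mask is empty (all pixels below NDVI threshold or nodata)")
    return valid


# ---------------------------------------------------------------------------
# zonal summaries


def zonal_summary(
    layer: np.ndarray,
    zones: ZoneMask,
    statistic: str = "mean",
    valid: np.ndarray | None = None,
    bins: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-zone statistic of a 2-D layer.

    statistic:
        ``mean`` - mean of the layer values per zone;
        ``class_fraction`` - fraction of pixels in each distinct layer value
        (categorical layers), fractions summing to 1 per zone;
        ``histogram`` - counts per bin with the stated ``bins`` edges.
    Zones with no valid pixels yield a row of nulls.
    """
    layer = np.asarray(layer)
    if layer.shape != zones.shape:
        raise ValueError("layer and zone grids have different shapes")
    if valid is None:
        valid = np.isfinite(layer.astype(float)) if np.issubdtype(
            layer.dtype, np.floating) else np.ones(layer.shape, bool)
    rows = []
    zone_ids = sorted(zones.legend)
    if statistic == "mean":
        for zid in zone_ids:
            sel = (zones.labels == zid) & valid
            rows.append({
                "zone_id": zid,
                "zone": zones.legend[zid],
                "n": int(sel.sum()),
                "mean": float(np.mean(layer[sel].astype(float))) if sel.any() else np.nan,
            })
        return pd.DataFrame(rows)
    if statistic == "class_fraction":
        classes = np.unique(layer[valid]) if valid.any() else np.array([])
        for zid in zone_ids:
            sel = (zones.labels == zid) & valid
            n = int(sel.sum())
            row = {"zone_id": zid, "zone": zones.legend[zid], "n": n}
            for cls in classes:
                key = f"frac_{cls}"
                row[key] = float(np.mean(layer[sel] == cls)) if n else np.nan
            rows.append(row)
        return pd.DataFrame(rows)
    if statistic == "histogram":
        if bins is None:
            raise ValueError("histogram statistic requires explicit bin edges")
        edges = np.asarray(bins, dtype=float)
        for zid in zone_ids:
            sel = (zones.labels == zid) & valid
            n = int(sel.sum())
            row = {"zone_id": zid, "zone": zones.legend[zid], "n": n}
            counts, _ = np.histogram(layer[sel].astype(float), bins=edges)
            for k in range(len(edges) - 1):
                key = f"bin_{edges[k]:g}_{edges[k + 1]:g}"
                row[key] = int(counts[k]) if n else np.nan
            rows.append(row)
        return pd.DataFrame(rows)
    raise ValueError(f"unknown statistic {statistic!r}")


def write_zone_legend(path, zones: ZoneMask) -> None:
    with open(path, "w") as fh:
        json.dump({str(k): v for k, v in zones.legend.items()}, fh, indent=1)


def read_zone_mask(labels_path, legend_path) -> ZoneMask:
    data, _ = _read_tiff(labels_path)
    if data.ndim == 3:
        data = data[0]
    with open(legend_path) as fh:
        legend = {int(k): v for k, v in json.load(fh).items()}
    return ZoneMask(np.asarray(data, dtype=np.int64), legend)
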