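"""Core grid containers: annual raster cubes, zone masks, grid geometry.

An :class:`AnnualCube` holds one variable (growing-season NDVI, annual mean
air temperature in degC, or annual precipitation in mm) as a ``(year, row,
col)`` array together with the year axis, an affine grid transform and a
2-D nodata mask.  All per-pixel statistics downstream assume gap-free
series, so a pixel that is nodata in *any* year is masked everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np


class GridTransform(NamedTuple):
    """Affine grid geometry in the GeoTIFF convention.

    ``x = c + a*col + b*row``, ``y = f + d*col + e*row`` for the upper-left
    corner of a pixel; rows run top-down (``e`` is normally negative).
    """

    a: float = 1.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    e: float = -1.0
    f: float = 0.0

    def pixel_origin(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.c + self.a * col + self.b * row,
            self.f + self.d * col + self.e * row,
        )


@dataclass
class AnnualCube:
    """One variable on a fixed grid over consecutive years.

    Parameters
    ----------
    values
        ``(n_years, rows, cols)`` float array.
    years
        Strictly increasing, consecutive integers; ``len(years)`` must equal
        ``values.shape[0]``.
    transform
        Affine grid geometry shared by all layers.
    nodata_mask
        2-D boolean, ``True`` where the pixel is excluded (in every year).
    """

    values: np.ndarray
    years: list[int]
    transform: GridTransform = field(default_factory=GridTransform)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D (year, row, col), got {self.values.ndim}-D")
        self.years = [int(y) for y in self.years]
        if len(self.years) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.years)} years but {self.values.shape[0]} layers"
            )
        diffs = np.diff(self.years)
        if len(self.years) > 1 and not np.all(diffs == 1):
            raise ValueError("years must be strictly increasing consecutive integers")
        if not isinstance(self.transform, GridTransform):
            self.transform = GridTransform(*self.transform)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape[1:], dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape[1:]:
                raise ValueError("nodata_mask shape does not match grid shape")

    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def series(self, row: int, col: int) -> np.ndarray:
        """Per-pixel time series (1-D, length n_years)."""
        return self.values[:, row, col]

    def same_grid(self, other: "AnnualCube") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
            and self.years == other.years
        )


@dataclass
class ZoneMask:
    """Categorical zone raster (e.g. ecological-restoration project areas).

    ``labels`` is a 2-D integer grid; ``legend`` maps every id present to a
    zone name such as ``GTGP`` (Grain to Green Project) or ``none``.
    """

    labels: np.ndarray
    legend: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("zone labels must be a 2-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("zone labels must be integers")
        self.legend = dict(self.legend)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"legend missing ids: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def check_aligned(*cubes: AnnualCube) -> None:
    """Raise if the cubes do not share grid shape, geometry and years."""
    ref = cubes[0]
    for c in cubes[1:]:
        if c.shape != ref.shape:
            raise ValueError(f"grid shape mismatch: {c.shape} vs {ref.shape}")
        if c.transform != ref.transform:
            raise ValueError("grid geometry (affine transform) mismatch")
        if c.years != ref.years:
            raise ValueError("year axis mismatch between cubes")


def combined_valid_mask(*cubes: AnnualCube) -> np.ndarray:
    """Pixels valid in every cube (2-D boolean, True = usable)."""
    check_aligned(*cubes)
    valid = ~cubes[0].nodata_mask
    for c in cubes[1:]:
        valid &= ~c.nodata_mask
    return valid
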