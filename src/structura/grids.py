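"""Raster carriers: GeoTIFF I/O, canopy height model derivation, and
block aggregation to coarser grains.

A grid is a rectangular array of elevations or heights in meters with a
square cell size. GeoTIFF files are read and written through tifffile,
honoring the standard georeferencing tags (``ModelPixelScaleTag``,
``ModelTiepointTag``) and the GDAL nodata convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

#: Default sweep of aggregation grains (linear pixel edge, meters).
GRAIN_SWEEP = (1, 5, 10, 15, 20, 25, 30, 40, 50, 60, 70, 100)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


@dataclass
class ElevationGrid:
    """Rectangular grid of elevation or height values (m).

    Parameters
    ----------
    values : ndarray of shape (rows, cols)
        Elevation/height in meters. Values under the nodata mask are
        not interpreted.
    cell_size : float
        Linear edge of a cell in meters; cells are square.
    nodata_mask : ndarray of bool, optional
        True where the cell carries no data. Defaults to all-valid.
    meta : dict
        Opaque pass-through metadata (origin, CRS, source tags).
    """

    values: np.ndarray
    cell_size: float
    nodata_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("non-finite values outside the nodata mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        """1-D array of the unmasked cell values."""
        return self.values[~self.nodata_mask]


@dataclass
class PixelSummary:
    """Per-pixel aggregates of a fine grid at one grain.

    Each retained grain pixel records the maximum and mean of the fine
    cells it covers and how many fine cells contributed. ``s`` is the
    number of retained pixels.
    """

    vmax: np.ndarray  # shape (s,): per-pixel max
    vmean: np.ndarray  # shape (s,): per-pixel mean
    n_cells: np.ndarray  # shape (s,): contributing fine cells
    grain: float  # linear pixel edge (m)
    max2d: np.ndarray  # 2-D per-block max, NaN where dropped
    mean2d: np.ndarray  # 2-D per-block mean, NaN where dropped
    valid2d: np.ndarray  # 2-D bool, retained blocks

    @property
    def s(self) -> int:
        return int(self.vmax.size)

    def to_grid(self, statistic: str = "mean") -> ElevationGrid:
        """Aggregated grid at the grain's cell size.

        Dropped blocks become nodata cells.
        """
        if statistic == "mean":
            arr = self.mean2d
        elif statistic == "max":
            arr = self.max2d
        else:
            raise ValueError("statistic must be 'max' or 'mean'")
        vals = np.where(self.valid2d, arr, 0.0)
        return ElevationGrid(vals, self.grain, nodata_mask=~self.valid2d)


def read_grid(path) -> ElevationGrid:
    """Read a single-band GeoTIFF into an :class:`ElevationGrid`.

    Raises
    ------
    ValueError
        For multi-band input or missing georeferencing (no pixel-scale
        tag, so the cell size is unknown).
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise ValueError(f"expected a single-band raster, got shape {values.shape}")
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags:
            raise ValueError("missing georeferencing: no ModelPixelScaleTag")
        scale = tags[_TAG_PIXEL_SCALE].value
        sx, sy = float(scale[0]), float(scale[1])
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise ValueError(f"non-square cells not supported: {sx} x {sy}")
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        meta = {}
        if _TAG_TIEPOINT in tags:
            meta["tiepoint"] = tuple(float(v) for v in tags[_TAG_TIEPOINT].value)
    values = np.asarray(values, dtype=float)
    mask = ~np.isfinite(values)
    if nodata is not None:
        mask |= values == nodata
        meta["nodata"] = nodata
    values = np.where(mask, 0.0, values)
    return ElevationGrid(values, sx, nodata_mask=mask, meta=meta)


def write_grid(grid: ElevationGrid, path, nodata: float = DEFAULT_NODATA) -> None:
    """Write a grid as a single-band GeoTIFF with georeferencing tags."""
    data = np.where(grid.nodata_mask, nodata, grid.values).astype(np.float64)
    tiepoint = grid.meta.get("tiepoint", (0.0, 0.0, 0.0, 0.0, 0.0, 0.0))
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, tuple(tiepoint)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def compute_chm(dsm: ElevationGrid, dtm: ElevationGrid, min_height: float = 0.5) -> ElevationGrid:
    """Canopy height model: DSM - DTM, clamped at >= 0.

    Heights below ``min_height`` (default 0.5 m) are set to 0 and count
    as ground/gap; negative differences (sensor noise) are clamped to 0.
    """
    if dsm.shape != dtm.shape:
        raise ValueError(f"DSM/DTM shape mismatch: {dsm.shape} vs {dtm.shape}")
    if not math.isclose(dsm.cell_size, dtm.cell_size, rel_tol=1e-9):
        raise ValueError("DSM/DTM cell size mismatch")
    chm = np.clip(dsm.values - dtm.values, 0.0, None)
    chm[chm < min_height] = 0.0
    mask = dsm.nodata_mask | dtm.nodata_mask
    chm[mask] = 0.0
    return ElevationGrid(chm, dsm.cell_size, nodata_mask=mask, meta=dict(dsm.meta))


def aggregate(grid: ElevationGrid, grain: float, min_valid_frac: float = 0.5) -> PixelSummary:
    """Partition ``grid`` into grain x grain blocks and summarize each.

    Every block records both its maximum and its mean over the unmasked
    fine cells it covers; downstream metrics pick the statistic they
    consume. Partial edge blocks are retained when at least
    ``min_valid_frac`` of their cells are unmasked, otherwise dropped.
    """
    if grid.values.size == 0:
        raise ValueError("empty grid")
    if grain < grid.cell_size - 1e-9:
        raise ValueError(f"grain {grain} smaller than cell size {grid.cell_size}")
    b = max(1, int(round(grain / grid.cell_size)))
    nr, nc = grid.shape
    nbr, nbc = math.ceil(nr / b), math.ceil(nc / b)
    # pad to a multiple of the block edge with masked cells
    vals = np.full((nbr * b, nbc * b), np.nan)
    vals[:nr, :nc] = np.where(grid.nodata_mask, np.nan, grid.values)
    blocks = vals.reshape(nbr, b, nbc, b).transpose(0, 2, 1, 3).reshape(nbr, nbc, b * b)
    n_valid = np.sum(np.isfinite(blocks), axis=2)
    # padding cells do not belong to the block; count true block area
    rows_in = np.minimum(nr - np.arange(nbr) * b, b)
    cols_in = np.minimum(nc - np.arange(nbc) * b, b)
    area = rows_in[:, None] * cols_in[None, :]
    valid = n_valid >= min_valid_frac * area
    valid &= n_valid >= 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bmax = np.nanmax(blocks, axis=2)
        bmean = np.nanmean(blocks, axis=2)
    if not valid.any():
        raise ValueError("no blocks retained at this grain")
    return PixelSummary(
        vmax=bmax[valid],
        vmean=bmean[valid],
        n_cells=n_valid[valid],
        grain=float(grain),
        max2d=bmax,
        mean2d=bmean,
        valid2d=valid,
    )
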