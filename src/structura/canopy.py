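"""Canopy structural complexity metrics from a canopy height model.

Nine metrics are computed per site and grain: 95th-percentile height,
mean outer canopy height (MOCH), canopy rugosity (CR), vertical entropy,
vertical complexity index (VCI), vegetation area index (VAI), rumple,
deep-gap fraction (DGF) and cover fraction (CF). Per-pixel statistics
(maxima h_i) come from block aggregation of the fine CHM; see
:func:`structura.grids.aggregate`.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from structura.grids import ElevationGrid, PixelSummary, aggregate

#: Beer-Lambert extinction coefficient used by the VAI estimator.
EXTINCTION_K = 0.5


def _pixel_maxima(pixels) -> np.ndarray:
    if isinstance(pixels, PixelSummary):
        return pixels.vmax
    arr = np.asarray(pixels, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty input")
    return arr


def percentile_height(pixels, q: float = 0.95) -> float:
    """Empirical q-quantile (linear interpolation) of per-pixel max heights."""
    h = _pixel_maxima(pixels)
    if h.size == 0:
        raise ValueError("empty input")
    return float(np.quantile(h, q))


def moch(pixels) -> float:
    """Mean outer canopy height: mean of per-pixel maximum heights."""
    h = _pixel_maxima(pixels)
    if h.size == 0:
        raise ValueError("empty input")
    return float(np.mean(h))


def canopy_rugosity(pixels, variance: bool = False) -> float:
    """Canopy rugosity: population standard deviation of per-pixel max
    heights about their mean (meters).

    ``variance=True`` returns the squared form instead.
    """
    h = _pixel_maxima(pixels)
    if h.size < 2:
        raise ValueError("canopy rugosity needs at least 2 pixels")
    v = float(np.mean((h - h.mean()) ** 2))
    return v if variance else math.sqrt(v)


def height_profile(heights: np.ndarray, dz: float = 1.0, min_height: float = 0.5):
    """Vertical height profile of the vegetated cells.

    Heights are binned at ``dz`` starting at ``min_height``; ground
    cells (height 0, i.e. below ``min_height``) are excluded. Returns
    ``(p, n_bins)`` where ``p`` are per-bin relative abundances over the
    occupied range and ``n_bins`` the count of bins spanning it.
    """
    h = np.asarray(heights, dtype=float).ravel()
    veg = h[h >= min_height]
    if veg.size == 0:
        return np.array([]), 0
    idx = np.floor((veg - min_height) / dz).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return counts / counts.sum(), n_bins


def _heights_of(chm) -> np.ndarray:
    if isinstance(chm, ElevationGrid):
        return chm.valid_values()
    if isinstance(chm, PixelSummary):
        return chm.vmax
    return np.asarray(chm, dtype=float).ravel()


def entropy(chm, dz: float = 1.0, min_height: float = 0.5) -> float:
    """Shannon entropy (nats) of the vertical height distribution.

    E' = -sum p_i ln p_i over ``dz``-wide height bins of the vegetated
    cells. With no vegetated cells the entropy is 0 (a warning is
    emitted).
    """
    p, _ = height_profile(_heights_of(chm), dz=dz, min_height=min_height)
    if p.size == 0:
        warnings.warn("no vegetated cells; entropy defined as 0", stacklevel=2)
        return 0.0
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def vci(chm, dz: float = 1.0, min_height: float = 0.5) -> float:
    """Vertical complexity index: entropy normalized by ln(n_bins), in [0, 1].

    ``n_bins`` is the number of ``dz`` bins spanning the occupied height
    range; fewer than 2 bins gives 0.
    """
    heights = _heights_of(chm)
    p, n_bins = height_profile(heights, dz=dz, min_height=min_height)
    if n_bins < 2:
        return 0.0
    p = p[p > 0]
    e = float(-np.sum(p * np.log(p)))
    return e / math.log(n_bins)


def vai(chm, dz: float = 1.0, k: float = EXTINCTION_K) -> float:
    """Vegetation area index: summed leaf-area density over 1-m slices.

    A CHM carries only the canopy top per column, so slice occupancy
    o_z is the fraction of columns whose top lies above the slice
    bottom. Each occupied slice attenuates a downward beam by the
    Beer-Lambert factor, giving the log-ratio form
    ``LAD_z = -ln(1 - o_z * (1 - exp(-k dz))) / (k dz)`` with extinction
    coefficient ``k``. This is an approximation: true within-canopy
    return profiles are not recoverable from a surface model.
    """
    h = _heights_of(chm)
    if h.size == 0:
        return 0.0
    hmax = float(h.max())
    if hmax <= 0:
        return 0.0
    n_slices = int(math.ceil(hmax / dz - 1e-12))
    z = np.arange(n_slices) * dz
    occ = (h[None, :] > z[:, None]).mean(axis=1)
    absorb = 1.0 - math.exp(-k * dz)
    lad = -np.log(1.0 - occ * absorb) / (k * dz)
    return float(lad.sum())


def rumple(chm: ElevationGrid) -> float:
    """Ratio of triangulated 3-D canopy surface area to ground area.

    Each grid square is split into two triangles along the same
    diagonal; 1 for any flat surface, >= 1 always.
    """
    z = chm.values
    if z.ndim != 2 or z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("rumple needs a grid of at least 2x2")
    c = chm.cell_size
    # corner heights of each square
    z00 = z[:-1, :-1]
    z01 = z[:-1, 1:]
    z10 = z[1:, :-1]
    z11 = z[1:, 1:]

    def tri_area(za, zb, zc, xb_yb, xc_yc):
        # vertices at (0,0,za), (xb,yb,zb), (xc,yc,zc) in cell units of c
        xb, yb = xb_yb
        xc, yc = xc_yc
        ux, uy, uz = xb * c, yb * c, zb - za
        vx, vy, vz = xc * c, yc * c, zc - za
        nx = uy * vz - uz * vy
        ny = uz * vx - ux * vz
        nz = ux * vy - uy * vx
        return 0.5 * np.sqrt(nx**2 + ny**2 + nz**2)

    # split along the (0,0)-(1,1) diagonal of each square
    a1 = tri_area(z00, z10, z11, (0, 1), (1, 1))
    a2 = tri_area(z00, z01, z11, (1, 0), (1, 1))
    surface = float(np.sum(a1 + a2))
    ground = (z.shape[0] - 1) * (z.shape[1] - 1) * c * c
    return surface / ground


def gap_fractions(pixels) -> tuple[float, float]:
    """Deep-gap fraction and cover fraction.

    DGF is the share of cells/pixels with zero canopy height; CF is its
    complement.
    """
    h = _heights_of(pixels)
    if h.size == 0:
        raise ValueError("empty input")
    dgf = float(np.mean(h == 0))
    return dgf, 1.0 - dgf


CANOPY_METRIC_NAMES = ("q95", "moch", "cr", "entropy", "vci", "vai", "rumple", "dgf", "cf")


def canopy_metrics(chm: ElevationGrid, grain: float, dz: float = 1.0, min_height: float = 0.5) -> dict:
    """All nine canopy metrics of a CHM at one grain.

    The CHM is block-aggregated to ``grain``; the per-pixel maximum
    (the canopy top within the pixel) feeds every metric. Rumple is
    NaN when fewer than 2x2 aggregated pixels remain.
    """
    pixels = aggregate(chm, grain)
    agg = pixels.to_grid("max")
    heights = agg.valid_values()
    out = {
        "grain": float(grain),
        "q95": percentile_height(pixels),
        "moch": moch(pixels),
        "cr": canopy_rugosity(pixels) if pixels.s >= 2 else float("nan"),
        "entropy": entropy(heights, dz=dz, min_height=min_height) if (heights >= min_height).any() else 0.0,
        "vci": vci(heights, dz=dz, min_height=min_height),
        "vai": vai(heights, dz=dz),
    }
    if agg.shape[0] >= 2 and agg.shape[1] >= 2 and not agg.nodata_mask.any():
        out["rumple"] = rumple(agg)
    else:
        out["rumple"] = float("nan")
    dgf, cf = gap_fractions(heights)
    out["dgf"] = dgf
    out["cf"] = cf
    return out
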