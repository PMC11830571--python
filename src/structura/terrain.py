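"""Terrain complexity metrics from a digital terrain model.

Six metrics per site and grain: mean elevation, max elevation, slope,
terrain ruggedness index (TRI), roughness (3x3 range) and terrain
rugosity (TR). Window metrics (slope, TRI, roughness) use the eight
neighbors of each interior cell; edge cells are excluded rather than
padded. The secant form 1/cos(slope) is exposed as a derived column
``roughness_secant``.
"""

from __future__ import annotations

import math

import numpy as np

from structura.grids import ElevationGrid, PixelSummary, aggregate


def _as_array(dtm) -> np.ndarray:
    if isinstance(dtm, ElevationGrid):
        if dtm.nodata_mask.any():
            raise ValueError("window metrics require a gap-free grid")
        return dtm.values
    return np.asarray(dtm, dtype=float)


def _windows(z: np.ndarray):
    """Center and the 8 neighbor planes for every interior cell."""
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("window metrics need a grid of at least 3x3")
    c = z[1:-1, 1:-1]
    neigh = np.stack(
        [
            z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:],
            z[1:-1, :-2], z[1:-1, 2:],
            z[2:, :-2], z[2:, 1:-1], z[2:, 2:],
        ]
    )
    return c, neigh


def elevation_summaries(pixels: PixelSummary) -> tuple[float, float]:
    """(mean elevation, max elevation).

    Mean elevation averages the per-pixel mean elevations; max
    elevation averages the per-pixel maxima.
    """
    if pixels.s < 1:
        raise ValueError("empty input")
    return float(np.mean(pixels.vmean)), float(np.mean(pixels.vmax))


def slope(dtm, cell_size: float | None = None) -> float:
    """Mean slope (degrees) by the Horn 8-neighbor gradient.

    Each interior cell's gradient is the Horn finite difference over
    its 3x3 window; the slope is arctan of the gradient magnitude,
    averaged over interior cells.
    """
    z = _as_array(dtm)
    if cell_size is None:
        cell_size = dtm.cell_size if isinstance(dtm, ElevationGrid) else 1.0
    _, n = _windows(z)
    # Horn weights: neighbors indexed nw,nn,ne,ww,ee,sw,ss,se
    nw, nn, ne, ww, ee, sw, ss, se = n
    dzdx = ((ne + 2 * ee + se) - (nw + 2 * ww + sw)) / (8.0 * cell_size)
    dzdy = ((sw + 2 * ss + se) - (nw + 2 * nn + ne)) / (8.0 * cell_size)
    s = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return float(np.mean(s))


def tri(dtm, method: str = "mean_abs") -> float:
    """Terrain ruggedness index (m): local elevation difference to the
    8 neighbors, averaged over interior cells.

    ``method='mean_abs'`` (default) is the mean absolute difference;
    ``method='rss'`` the Riley root-sum-of-squares form.
    """
    z = _as_array(dtm)
    c, n = _windows(z)
    diff = n - c[None, :, :]
    if method == "mean_abs":
        per_cell = np.mean(np.abs(diff), axis=0)
    elif method == "rss":
        per_cell = np.sqrt(np.sum(diff**2, axis=0))
    else:
        raise ValueError("method must be 'mean_abs' or 'rss'")
    return float(np.mean(per_cell))


def terrain_roughness(dtm) -> float:
    """Roughness (m): 3x3 window max minus min (center included),
    averaged over interior cells."""
    z = _as_array(dtm)
    c, n = _windows(z)
    full = np.concatenate([c[None, :, :], n], axis=0)
    return float(np.mean(full.max(axis=0) - full.min(axis=0)))


def roughness_secant(slope_deg: float) -> float:
    """Derived secant form 1/cos(slope)."""
    return 1.0 / math.cos(math.radians(slope_deg))


def terrain_rugosity(dtm, variance: bool = False) -> float:
    """Terrain rugosity (m): population standard deviation of the
    elevation values (same estimator convention as canopy rugosity)."""
    if isinstance(dtm, ElevationGrid):
        e = dtm.valid_values()
    elif isinstance(dtm, PixelSummary):
        e = dtm.vmax
    else:
        e = np.asarray(dtm, dtype=float).ravel()
    if e.size < 2:
        raise ValueError("terrain rugosity needs at least 2 values")
    v = float(np.mean((e - e.mean()) ** 2))
    return v if variance else math.sqrt(v)


TERRAIN_METRIC_NAMES = ("me", "max_elev", "slope", "tri", "roughness", "roughness_secant", "tr")


def terrain_metrics(dtm: ElevationGrid, grain: float) -> dict:
    """All terrain metrics of a DTM at one grain.

    Elevation summaries and TR consume the per-pixel aggregates
    (maxima for TR/max elevation, means for mean elevation); window
    metrics are computed on the mean-aggregated grid at the grain's
    spacing and are NaN when fewer than 3x3 pixels remain.
    """
    pixels = aggregate(dtm, grain)
    me, max_elev = elevation_summaries(pixels)
    out = {
        "grain": float(grain),
        "me": me,
        "max_elev": max_elev,
        "tr": terrain_rugosity(pixels) if pixels.s >= 2 else float("nan"),
    }
    agg = pixels.to_grid("mean")
    ok = agg.shape[0] >= 3 and agg.shape[1] >= 3 and not agg.nodata_mask.any()
    if ok:
        s = slope(agg)
        out["slope"] = s
        out["tri"] = tri(agg)
        out["roughness"] = terrain_roughness(agg)
        out["roughness_secant"] = roughness_secant(s)
    else:
        out["slope"] = out["tri"] = out["roughness"] = out["roughness_secant"] = float("nan")
    return out
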