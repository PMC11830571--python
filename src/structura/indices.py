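"""Cross-site scaling and the two combined complexity indices.

Raw site-level metrics are min-max scaled across the site collection to
[0.1, 1]; the 0.1 floor keeps reciprocals finite. Combined rugosity
(RuC) multiplies scaled canopy rugosity by the reciprocal of scaled
terrain rugosity — increased terrain complexity is expected to depress
biological complexity, hence the reciprocal. Combined roughness (RoC)
additionally multiplies in the scaled 95th-percentile canopy height.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def scale_minmax(values, lo: float = 0.1, hi: float = 1.0) -> np.ndarray:
    """Linear map of site values onto [lo, hi]; min -> lo, max -> hi.

    Raises for fewer than 2 values or an all-equal collection (the
    scaling is undefined there — pick the grain/metric differently or
    drop the metric).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("scaling needs at least 2 sites")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        raise ValueError("all values equal; min-max scaling undefined")
    return lo + (hi - lo) * (v - vmin) / (vmax - vmin)


def combined_rugosity(cr_scaled, tr_scaled):
    """RuC = scaled CR x 1 / scaled TR."""
    tr = np.asarray(tr_scaled, dtype=float)
    if np.any(tr <= 0):
        raise ValueError("scaled terrain rugosity must be positive")
    return np.asarray(cr_scaled, dtype=float) / tr


def combined_roughness(cr_scaled, tr_scaled, h_scaled):
    """RoC = scaled CR x scaled q95 height x 1 / scaled TR."""
    return combined_rugosity(cr_scaled, tr_scaled) * np.asarray(h_scaled, dtype=float)


def combine_site_metrics(table: pd.DataFrame, cr_col: str = "cr", tr_col: str = "tr", h_col: str = "q95") -> pd.DataFrame:
    """Add scaled components and the combined indices to a site table.

    ``table`` has one row per site with raw CR, TR and q95 height at
    their chosen grains; returns a copy with ``cr_scaled``,
    ``tr_scaled``, ``h_scaled``, ``ruc`` and ``roc`` columns.
    """
    out = table.copy()
    out["cr_scaled"] = scale_minmax(out[cr_col].to_numpy())
    out["tr_scaled"] = scale_minmax(out[tr_col].to_numpy())
    out["h_scaled"] = scale_minmax(out[h_col].to_numpy())
    out["ruc"] = combined_rugosity(out["cr_scaled"], out["tr_scaled"])
    out["roc"] = combined_roughness(out["cr_scaled"], out["tr_scaled"], out["h_scaled"])
    return out
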