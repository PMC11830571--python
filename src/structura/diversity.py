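"""Taxon-table cleaning, per-trophic-level diversity, the multi-trophic
diversity index (MDI), and species accumulation curves.

Input is a long-format count table with columns
``site, trophic_level, unit, date, taxon, count`` (the NEON-style bird
point-count, beetle pitfall and plant presence tables map onto this via
:func:`from_neon_columns`). Shannon diversity per trophic level is
min-max scaled to [0.1, 1] across sites and the MDI is the mean of the
scaled components over the trophic levels considered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from structura.indices import scale_minmax

REQUIRED_COLUMNS = ("site", "trophic_level", "taxon", "count")

#: Column aliases for common NEON observational tables.
NEON_COLUMN_MAP = {
    "siteID": "site",
    "plotID": "unit",
    "pointID": "unit",
    "trapID": "unit",
    "subplotID": "unit",
    "observation_datetime": "date",
    "startDate": "date",
    "collectDate": "date",
    "endDate": "date",
    "scientificName": "taxon",
    "taxonID": "taxon",
    "clusterSize": "count",
    "individualCount": "count",
}


def from_neon_columns(table: pd.DataFrame, trophic_level: str) -> pd.DataFrame:
    """Rename NEON-style observational columns to the long format used
    here and attach the trophic level."""
    out = table.rename(columns=NEON_COLUMN_MAP).copy()
    out["trophic_level"] = trophic_level
    if "count" not in out.columns:
        out["count"] = 1  # presence table
    return out


@dataclass
class CleaningReport:
    n_input: int
    n_retained: int
    dropped: dict  # reason -> rows dropped


def clean_taxa(table: pd.DataFrame) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove rows with unknown/empty taxon identifiers; coerce counts.

    Rows whose taxon is missing, blank, or an explicit unknown marker
    are dropped, as are rows with missing or non-positive counts.
    Idempotent. Raises if nothing survives.
    """
    df = table.copy()
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    n_input = len(df)
    dropped: dict[str, int] = {}

    taxon = df["taxon"].astype("string")
    blank = taxon.isna() | (taxon.str.strip() == "")
    unknown = taxon.str.strip().str.lower().isin({"unknown", "unknown species", "sp.", "unidentified"}).fillna(False)
    dropped["empty_taxon"] = int(blank.sum())
    dropped["unknown_taxon"] = int((unknown & ~blank).sum())
    df = df[~(blank | unknown)]

    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts <= 0)
    dropped["invalid_count"] = int(bad.sum())
    df = df[~bad].copy()
    df["count"] = counts[~bad].round().astype(int)

    if len(df) == 0:
        raise ValueError("no rows survive taxon cleaning")
    return df.reset_index(drop=True), CleaningReport(n_input, len(df), dropped)


def _shannon(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _simpson(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    return float(1.0 - np.sum(p**2))


def diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per (site, trophic level): richness, abundance, Shannon H (nats)
    and Simpson (1 - sum p^2), from taxon counts pooled over sampling
    units and dates."""
    pooled = table.groupby(["site", "trophic_level", "taxon"], sort=True)["count"].sum().reset_index()
    rows = []
    for (site, level), grp in pooled.groupby(["site", "trophic_level"], sort=True):
        counts = grp["count"].to_numpy(dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"zero total count for site {site!r}, level {level!r}")
        rows.append(
            {
                "site": site,
                "trophic_level": level,
                "richness": int((counts > 0).sum()),
                "abundance": int(total),
                "shannon": _shannon(counts),
                "simpson": _simpson(counts),
            }
        )
    return pd.DataFrame(rows)


def mdi(diversity_table: pd.DataFrame, trophic_levels, form: str = "table") -> pd.DataFrame:
    """Multi-trophic diversity index per site.

    Shannon H of each requested trophic level is min-max scaled to
    [0.1, 1] across sites (column ``I_<level>``); the MDI is the mean of
    a site's scaled components. ``form='text'`` divides that mean by the
    number of levels once more (a literal alternative reading of the
    definition, kept for comparison).

    Raises if any (site, level) pair is missing.
    """
    levels = list(trophic_levels)
    sub = diversity_table[diversity_table["trophic_level"].isin(levels)]
    wide = sub.pivot(index="site", columns="trophic_level", values="shannon")
    missing = [lvl for lvl in levels if lvl not in wide.columns]
    gaps = [(site, lvl) for lvl in wide.columns for site in wide.index[wide[lvl].isna()]]
    if missing or gaps:
        raise ValueError(f"missing (site, level) data: levels {missing}, gaps {gaps}")
    if len(wide) < 2:
        raise ValueError("MDI needs at least 2 sites")
    out = pd.DataFrame(index=wide.index)
    for lvl in levels:
        out[f"I_{lvl}"] = scale_minmax(wide[lvl].to_numpy())
    scaled = out[[f"I_{lvl}" for lvl in levels]].to_numpy()
    out["n_levels"] = len(levels)
    out["mdi"] = scaled.mean(axis=1)
    if form == "text":
        out["mdi"] = out["mdi"] / len(levels)
    elif form != "table":
        raise ValueError("form must be 'table' or 'text'")
    return out.reset_index()


def accumulation_curve(table: pd.DataFrame, by: str = "unit", pooled: bool = True) -> pd.DataFrame:
    """Species accumulation curves per site.

    Sampling units (or dates, ``by='date'``) are taken in sorted order;
    each step records the cumulative count of distinct taxa per
    (site, trophic level), plus a pooled multi-trophic curve combining
    all levels when ``pooled`` is True. Non-decreasing by construction.
    """
    if by not in table.columns:
        raise ValueError(f"no ordering column {by!r} in table")
    frames = []

    def one_curve(site, level, grp):
        seen: set = set()
        rows = []
        for step, (unit, ugrp) in enumerate(sorted(grp.groupby(by)), start=1):
            seen.update(ugrp["taxon"])
            rows.append({"site": site, "trophic_level": level, "step": step, "unit": unit, "cum_richness": len(seen)})
        return pd.DataFrame(rows)

    for (site, level), grp in table.groupby(["site", "trophic_level"], sort=True):
        frames.append(one_curve(site, level, grp))
    if pooled:
        for site, grp in table.groupby("site", sort=True):
            frames.append(one_curve(site, "all", grp))
    return pd.concat(frames, ignore_index=True)
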