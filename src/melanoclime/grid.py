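"""Assemblages on an equal-area grid.

Species occupancy on a planar grid of unit-area square cells, the two
exclusion filters applied in the analysis (water-dominated cells,
assemblages with poor colour-data coverage), per-cell trait summaries
and per-species range-mean environments.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENV_VARS = ["MAT", "elevation", "EVI", "UVB"]
CELL_COLUMNS = ["cell_id", "x", "y", "water_fraction", "realm"] + ENV_VARS

WATER_THRESHOLD = 0.5  # cells with MORE than this water fraction are excluded
COVERAGE_THRESHOLD = 0.33  # assemblages with colour data for LESS than this are excluded


def filter_cells(cells: pd.DataFrame, water_threshold: float = WATER_THRESHOLD) -> pd.DataFrame:
    """Flag water-dominated cells (water_fraction strictly above threshold)."""
    out = cells.copy()
    excluded = out["water_fraction"] > water_threshold
    out["included"] = ~excluded
    out["exclusion_reason"] = np.where(excluded, "water", "")
    return out


def rasterize_rect_ranges(ranges: dict, cells: pd.DataFrame) -> pd.DataFrame:
    """Occupancy from per-species rectangles (x0, x1, y0, y1) in grid units.

    A species occupies every included cell whose centre lies inside its
    rectangle (inclusive bounds).  Species with an empty intersection
    are dropped with a log entry.
    """
    cells = cells if "included" in cells.columns else filter_cells(cells)
    inc = cells[cells["included"]]
    x = inc["x"].to_numpy()
    y = inc["y"].to_numpy()
    ids = inc["cell_id"].to_numpy()
    rows = []
    for sp in sorted(ranges):
        x0, x1, y0, y1 = ranges[sp]
        mask = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
        if not mask.any():
            logger.info("species %s has an empty rasterized range; dropped", sp)
            continue
        rows.append(pd.DataFrame({"cell_id": ids[mask], "species_id": sp}))
    if not rows:
        return pd.DataFrame(columns=["cell_id", "species_id"])
    return pd.concat(rows, ignore_index=True)


def assemblage_trait_means(occupancy: pd.DataFrame, traits: pd.DataFrame,
                           grand_mean: float | None = None) -> pd.DataFrame:
    """Per-cell unweighted means of raw/P/S across co-occurring species.

    `traits` has species_id plus any of raw, P, S (species without
    colour data simply absent).  Species lacking colour data count
    toward n_species_total but not toward the means; coverage is the
    fraction of species with colour data.
    """
    occ = occupancy.drop_duplicates(["cell_id", "species_id"])
    trait_cols = [c for c in ("raw", "P", "S") if c in traits.columns]
    merged = occ.merge(traits[["species_id"] + trait_cols], on="species_id", how="left")
    has_col = merged[trait_cols[0]].notna() if trait_cols else pd.Series(False, index=merged.index)

    g = merged.groupby("cell_id", sort=True)
    out = pd.DataFrame({
        "cell_id": list(g.groups),
        "n_species_total": g.size().to_numpy(),
        "n_species_with_colour": g.apply(lambda d: int(d[trait_cols[0]].notna().sum()) if trait_cols else 0,
                                         include_groups=False).to_numpy(),
    })
    for c in trait_cols:
        out[f"mean_{c}"] = g[c].mean().to_numpy()
    out["coverage"] = out["n_species_with_colour"] / out["n_species_total"]
    if grand_mean is not None:
        out.attrs["grand_mean"] = grand_mean
    return out


def filter_assemblages(summaries: pd.DataFrame,
                       coverage_threshold: float = COVERAGE_THRESHOLD) -> pd.DataFrame:
    """Flag assemblages with colour data for less than the threshold fraction
    of their species, or with no species at all."""
    out = summaries.copy()
    empty = out["n_species_with_colour"] < 1
    poor = (~empty) & (out["coverage"] < coverage_threshold)
    out["included"] = ~(empty | poor)
    out["exclusion_reason"] = np.where(empty, "empty", np.where(poor, "coverage", ""))
    return out


def species_range_environment(occupancy: pd.DataFrame, cells: pd.DataFrame,
                              equator_y: float | None = None) -> pd.DataFrame:
    """Per-species unweighted means of each environment variable across the
    included cells of its range, plus range size and a mean absolute
    latitude proxy (|y - equator|)."""
    cells = cells if "included" in cells.columns else filter_cells(cells)
    inc = cells[cells["included"]]
    if equator_y is None:
        equator_y = float(cells["y"].mean())
    occ = occupancy.drop_duplicates(["cell_id", "species_id"])
    merged = occ.merge(inc[["cell_id", "x", "y"] + ENV_VARS], on="cell_id", how="inner")
    dropped = set(occ["species_id"]) - set(merged["species_id"])
    for sp in sorted(dropped):
        logger.info("species %s occupies no included cell; dropped from range means", sp)
    merged["abs_lat"] = (merged["y"] - equator_y).abs()
    g = merged.groupby("species_id", sort=True)
    out = g[ENV_VARS + ["abs_lat"]].mean()
    out["range_size"] = g.size()
    return out.reset_index()


def attach_cell_environment(summaries: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Join per-cell environment and coordinates onto assemblage summaries."""
    keep = ["cell_id", "x", "y", "realm"] + ENV_VARS
    return summaries.merge(cells[keep], on="cell_id", how="left")
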