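"""Basin-level aggregation of rasters into the regression design.

Basins are the analysis units coupling natural and socio-economic structure:
per basin we aggregate mean habitat quality Q (the response), mean
nighttime-light intensity NTL, mean population density POP, and the land
urbanization rate LUR (construction-land share of basin area).  Means are
used for NTL/POP so the indicators are invariant to basin size.

Indicator columns can be standardized (min–max to [0, 1] by default, z-score
optionally); the SUM column — the sum of the four standardized indicators —
is the joint development level used to order zoning classes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .landuse import CONSTRUCTION_CODES
from .raster import Raster

__all__ = [
    "zonal_mean",
    "land_urbanization_rate",
    "basin_table",
    "standardize",
    "INDICATOR_COLS",
]

INDICATOR_COLS = ("q_mean", "ntl_mean", "pop_mean", "lur")


def _check_labels(labels: Raster, grid: Raster) -> None:
    labels.require_same_geometry(grid)


def zonal_mean(grid: Raster, basin_labels: Raster) -> pd.Series:
    """Mean of ``grid`` over valid cells, per basin label.

    Basins whose cells are all invalid get NaN.  Labels must be positive
    integers on the same geometry.
    """
    _check_labels(basin_labels, grid)
    labels = basin_labels.data.astype(int)
    valid = grid.valid_mask & (labels > 0)
    if not valid.any():
        raise ValueError("no overlap between basin labels and valid data")
    lab = labels[valid]
    val = grid.data[valid].astype(float)
    nmax = labels.max()
    sums = np.bincount(lab, weights=val, minlength=nmax + 1)
    cnts = np.bincount(lab, minlength=nmax + 1)
    present = np.unique(labels[labels > 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / cnts
    return pd.Series(means[present], index=pd.Index(present, name="basin_id"))


def land_urbanization_rate(
    lulc: Raster,
    basin_labels: Raster,
    construction_codes: Sequence[int] = CONSTRUCTION_CODES,
) -> pd.Series:
    """Construction-land share of each basin's area, in [0, 1]."""
    _check_labels(basin_labels, lulc)
    labels = basin_labels.data.astype(int)
    valid = lulc.valid_mask & (labels > 0)
    if not valid.any():
        raise ValueError("no overlap between basin labels and valid data")
    built = np.isin(lulc.data, construction_codes).astype(float)
    lab = labels[valid]
    nmax = labels.max()
    urb = np.bincount(lab, weights=built[valid], minlength=nmax + 1)
    cnt = np.bincount(lab, minlength=nmax + 1)
    present = np.unique(labels[labels > 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = urb / cnt
    return pd.Series(frac[present], index=pd.Index(present, name="basin_id"))


def basin_table(
    quality: Raster,
    ntl: Raster,
    pop: Raster,
    lulc: Raster,
    basin_labels: Raster,
    construction_codes: Sequence[int] = CONSTRUCTION_CODES,
) -> pd.DataFrame:
    """Assemble the per-basin indicator table.

    Columns: ``area_km2``, ``q_mean``, ``ntl_mean``, ``pop_mean``, ``lur``,
    ``centroid_x``, ``centroid_y`` (metres), indexed by basin id.
    """
    labels = basin_labels.data.astype(int)
    present = np.unique(labels[labels > 0])
    cnt = np.bincount(labels.ravel(), minlength=labels.max() + 1)
    xs, ys = basin_labels.cell_centers()
    sx = np.bincount(labels.ravel(), weights=xs.ravel(), minlength=labels.max() + 1)
    sy = np.bincount(labels.ravel(), weights=ys.ravel(), minlength=labels.max() + 1)
    table = pd.DataFrame(
        {
            "area_km2": cnt[present] * basin_labels.cell_area_km2,
            "q_mean": zonal_mean(quality, basin_labels),
            "ntl_mean": zonal_mean(ntl, basin_labels),
            "pop_mean": zonal_mean(pop, basin_labels),
            "lur": land_urbanization_rate(lulc, basin_labels, construction_codes),
            "centroid_x": sx[present] / cnt[present],
            "centroid_y": sy[present] / cnt[present],
        },
        index=pd.Index(present, name="basin_id"),
    )
    return table


def standardize(
    table: pd.DataFrame,
    columns: Sequence[str] = INDICATOR_COLS,
    method: str = "minmax",
    sum_column: str = "SUM",
) -> pd.DataFrame:
    """Standardize indicator columns and append their SUM.

    ``minmax`` maps each column to [0, 1]; ``zscore`` to mean 0, sd 1
    (constant columns are rejected under z-score; under min–max they map
    to 0).  Standardized columns are added as ``<col>_std`` and summed into
    ``sum_column``.
    """
    if len(table) < 2:
        raise ValueError("standardization needs at least two basins")
    out = table.copy()
    std_cols = []
    for col in columns:
        x = out[col].astype(float)
        if not np.isfinite(x).all():
            raise ValueError(f"non-finite values in column {col!r}")
        if method == "minmax":
            rng = x.max() - x.min()
            z = (x - x.min()) / rng if rng > 0 else x * 0.0
        elif method == "zscore":
            sd = x.std(ddof=0)
            if sd == 0:
                raise ValueError(f"column {col!r} is constant; z-score undefined")
            z = (x - x.mean()) / sd
        else:
            raise ValueError(f"unknown standardization method {method!r}")
        out[f"{col}_std"] = z
        std_cols.append(f"{col}_std")
    out[sum_column] = out[std_cols].sum(axis=1)
    return out
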