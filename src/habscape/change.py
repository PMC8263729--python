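"""Land-use transition mapping and habitat-quality change accounting.

Given co-registered categorical grids at two epochs, this module builds the
full from-class x to-class transition matrix (cell counts and km²), maps the
source classes of new construction land, and computes the two change
statistics used to attribute quality loss to land conversion:

* **HQCI** — the mean per-cell quality change over the cells undergoing a
  given transition, ``sum(Q_t2 - Q_t1) / n`` (negative = loss);
* **CI** — the transition's total contribution, ``HQCI x S`` with S the
  converted area in km² (equivalently ``sum(dQ) x cell_area``).

Grade bookkeeping reports the share of each quality grade per epoch and the
per-grade area change per period; sub-period changes telescope exactly to the
full-period change before rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .habitat import GRADE_LABELS, QualitySurface, grade_quality
from .landuse import CODE_NAMES, CONSTRUCTION_CODES, resolve_code
from .raster import Raster

__all__ = [
    "TransitionMatrix",
    "TransitionImpact",
    "transition_matrix",
    "expansion_sources",
    "hqci_ci",
    "transition_report",
    "grade_change_table",
    "mean_quality",
]


@dataclass
class TransitionMatrix:
    """Counts and areas per (from-class, to-class) pair between two epochs."""

    counts: pd.DataFrame  # index = from-class code, columns = to-class code
    cell_area_km2: float

    @property
    def areas(self) -> pd.DataFrame:
        return self.counts * self.cell_area_km2

    @property
    def total_area_km2(self) -> float:
        return float(self.counts.to_numpy().sum() * self.cell_area_km2)


@dataclass
class TransitionImpact:
    """HQCI / CI statistics of one land-class transition."""

    hqci: float  # mean per-cell quality change; NaN when no cell transitions
    ci: float  # total contribution = hqci * s_km2; NaN when empty
    s_km2: float
    n: int


def _valid_pair_mask(a: Raster, b: Raster) -> np.ndarray:
    """Cells valid at both epochs; others are excluded from all statistics."""
    return a.valid_mask & b.valid_mask


def transition_matrix(lulc_t1: Raster, lulc_t2: Raster) -> TransitionMatrix:
    """Complete cross-tabulation of land classes between two epochs."""
    lulc_t1.require_same_geometry(lulc_t2)
    mask = _valid_pair_mask(lulc_t1, lulc_t2)
    f = lulc_t1.data[mask].astype(int).ravel()
    t = lulc_t2.data[mask].astype(int).ravel()
    counts = pd.crosstab(pd.Series(f, name="from"), pd.Series(t, name="to"))
    return TransitionMatrix(counts=counts, cell_area_km2=lulc_t1.cell_area_km2)


def expansion_sources(
    lulc_t1: Raster,
    lulc_t2: Raster,
    construction_codes: Sequence[int] = CONSTRUCTION_CODES,
) -> Raster:
    """Label each newly-construction cell with its prior land class.

    Cells that were already construction, or did not convert, are nodata (0).
    The per-label counts equal the construction column of the transition
    matrix minus its construction rows.
    """
    lulc_t1.require_same_geometry(lulc_t2)
    mask = _valid_pair_mask(lulc_t1, lulc_t2)
    was = np.isin(lulc_t1.data, construction_codes)
    now = np.isin(lulc_t2.data, construction_codes)
    new = now & ~was & mask
    out = np.where(new, lulc_t1.data, 0).astype(np.int16)
    return lulc_t1.with_data(out, nodata=0)


def hqci_ci(
    q_t1: Raster,
    q_t2: Raster,
    lulc_t1: Raster,
    lulc_t2: Raster,
    from_class: int | str | Sequence,
    to_class: int | str | Sequence,
) -> TransitionImpact:
    """HQCI and CI for the cells converting from ``from_class`` to ``to_class``.

    ``from_class`` / ``to_class`` may be a single class or a collection
    (e.g. the union of construction codes).  With no transitioning cells the
    mean is undefined: HQCI and CI are NaN, not 0.
    """
    for other in (q_t2, lulc_t1, lulc_t2):
        q_t1.require_same_geometry(other)

    def codes_of(ref) -> tuple[int, ...]:
        if isinstance(ref, (str, int, np.integer)):
            return (resolve_code(ref),)
        return tuple(resolve_code(r) for r in ref)

    mask = _valid_pair_mask(lulc_t1, lulc_t2) & _valid_pair_mask(q_t1, q_t2)
    sel = (
        np.isin(lulc_t1.data, codes_of(from_class))
        & np.isin(lulc_t2.data, codes_of(to_class))
        & mask
    )
    n = int(sel.sum())
    cell_area = q_t1.cell_area_km2
    if n == 0:
        return TransitionImpact(hqci=math.nan, ci=math.nan, s_km2=0.0, n=0)
    dq = q_t2.data[sel] - q_t1.data[sel]
    hqci = float(dq.mean())
    s = n * cell_area
    return TransitionImpact(hqci=hqci, ci=hqci * s, s_km2=s, n=n)


def transition_report(
    q_t1: Raster,
    q_t2: Raster,
    lulc_t1: Raster,
    lulc_t2: Raster,
    to_codes: Sequence[int] = CONSTRUCTION_CODES,
    round_decimals: int | None = 2,
) -> pd.DataFrame:
    """Per source-class HQCI / S / CI table for conversion into ``to_codes``.

    One row per from-class with at least one transitioning cell.  With
    ``round_decimals`` set, HQCI, S and CI are rounded for reporting (the
    identity CI = HQCI x S holds exactly only before rounding).
    """
    rows = []
    from_codes = [c for c in CODE_NAMES if c not in to_codes]
    for code in from_codes:
        imp = hqci_ci(q_t1, q_t2, lulc_t1, lulc_t2, code, tuple(to_codes))
        if imp.n == 0:
            continue
        rows.append(
            {
                "from_class": CODE_NAMES[code],
                "n": imp.n,
                "HQCI": imp.hqci,
                "S_km2": imp.s_km2,
                "CI": imp.ci,
            }
        )
    df = pd.DataFrame(rows, columns=["from_class", "n", "HQCI", "S_km2", "CI"])
    if round_decimals is not None and not df.empty:
        for col in ("HQCI", "S_km2", "CI"):
            df[col] = df[col].round(round_decimals)
    return df


def mean_quality(q: QualitySurface | Raster) -> float:
    """Arithmetic mean of Q over valid cells."""
    qr = q.raster if isinstance(q, QualitySurface) else q
    mask = qr.valid_mask
    if not mask.any():
        raise ValueError("quality surface has no valid cells")
    return float(qr.data[mask].mean())


def grade_change_table(
    surfaces: Mapping[object, QualitySurface | Raster],
    epochs: Sequence | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grade shares per epoch (%) and per-grade area change per period (km²).

    ``surfaces`` maps epoch labels to quality surfaces (or pre-graded
    rasters).  Returns ``(shares, deltas)``: shares has one row per epoch and
    one column per grade I–V summing to 100; deltas has one row per
    consecutive period plus a full-period row, and telescopes exactly.
    """
    keys = list(epochs) if epochs is not None else list(surfaces.keys())
    if len(keys) < 2:
        raise ValueError("need at least two epochs")
    areas = {}
    for key in keys:
        surf = surfaces[key]
        if isinstance(surf, QualitySurface):
            grade = surf.grade if surf.grade is not None else grade_quality(surf)
        elif np.issubdtype(np.asarray(surf.data).dtype, np.integer):
            grade = surf
        else:
            grade = grade_quality(surf)
        cell_area = grade.cell_area_km2
        counts = np.bincount(grade.data[grade.valid_mask].ravel(), minlength=6)[1:6]
        areas[key] = counts * cell_area
    area_df = pd.DataFrame(areas, index=list(GRADE_LABELS)).T
    shares = area_df.div(area_df.sum(axis=1), axis=0) * 100.0

    delta_rows = {}
    for a, b in zip(keys[:-1], keys[1:]):
        delta_rows[f"{a}-{b}"] = area_df.loc[b] - area_df.loc[a]
    delta_rows[f"{keys[0]}-{keys[-1]}"] = area_df.loc[keys[-1]] - area_df.loc[keys[0]]
    deltas = pd.DataFrame(delta_rows).T
    return shares, deltas
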