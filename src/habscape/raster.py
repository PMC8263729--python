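"""Minimal single-band raster container with plain-text (ESRI ASCII grid) I/O.

All grids in the pipeline — categorical land use, continuous covariates,
degradation/quality surfaces, basin labels — share one container.  Geometry is
a square-cell grid in a projected metric plane; the affine transform reduces to
a cell size in metres plus the lower-left corner, which is exactly what the
``.asc`` format stores.  Row 0 of ``data`` is the northernmost row, matching
the on-disk order of the format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii", "write_ascii"]


@dataclass
class Raster:
    """A single-band raster on a square-cell grid.

    Parameters
    ----------
    data:
        2-D array, row 0 = northernmost row.
    cell_size:
        Cell edge length in metres (cells are square).
    xll, yll:
        Projected coordinates of the lower-left corner of the grid, metres.
    nodata:
        Value marking invalid cells, or ``None`` if every cell is valid.
    """

    data: np.ndarray
    cell_size: float
    xll: float = 0.0
    yll: float = 0.0
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got shape {self.data.shape}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata, finite) cells."""
        mask = np.ones(self.data.shape, dtype=bool)
        if self.nodata is not None:
            mask &= self.data != self.nodata
        if np.issubdtype(self.data.dtype, np.floating):
            mask &= np.isfinite(self.data)
        return mask

    def same_geometry(self, other: "Raster", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= atol
            and abs(self.xll - other.xll) <= atol
            and abs(self.yll - other.yll) <= atol
        )

    def require_same_geometry(self, other: "Raster") -> None:
        if not self.same_geometry(other):
            raise ValueError(
                f"raster geometry mismatch: {self.shape}/{self.cell_size} vs "
                f"{other.shape}/{other.cell_size}"
            )

    def with_data(self, data: np.ndarray, nodata=None) -> "Raster":
        """New raster sharing this one's geometry."""
        return replace(self, data=np.asarray(data), nodata=nodata)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinates in metres, each shaped like ``data``."""
        nrows, ncols = self.shape
        x = self.xll + (np.arange(ncols) + 0.5) * self.cell_size
        y = self.yll + (nrows - 1 - np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(x, y)


def write_ascii(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (plain text)."""
    nrows, ncols = raster.shape
    nodata = raster.nodata if raster.nodata is not None else -9999
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.xll}\n"
        f"yllcorner {raster.yll}\n"
        f"cellsize {raster.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    data = raster.data
    if raster.nodata is None and np.issubdtype(data.dtype, np.floating):
        data = np.where(np.isfinite(data), data, nodata)
    fmt = "%d" if np.issubdtype(data.dtype, np.integer) else "%.8g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)


def read_ascii(path: str | Path, dtype=None) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii` (or any tool)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=dtype if dtype is not None else float)
    data = data.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value")
    if nodata is not None and np.issubdtype(data.dtype, np.integer):
        nodata = int(nodata)
    return Raster(
        data=data,
        cell_size=header["cellsize"],
        xll=header.get("xllcorner", 0.0),
        yll=header.get("yllcorner", 0.0),
        nodata=nodata,
    )
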