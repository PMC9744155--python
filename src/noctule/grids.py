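"""Lightweight georeferenced raster container with plain-text (ESRI ASCII) I/O.

All layers in the pipeline live on regular WGS84 lon/lat grids with square
cells registered by center. A :class:`RasterGrid` wraps a 2-D float array
(row 0 = northernmost row) plus the grid origin and cell size; nodata is
carried as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "aggregate"]


@dataclass
class RasterGrid:
    """A 2-D raster on a regular lon/lat grid.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values, NaN where nodata. Row 0 is the northernmost row.
    xmin, ymin : float
        Coordinates of the lower-left corner of the grid (degrees).
    res : float
        Cell size in decimal degrees (square cells).
    """

    values: np.ndarray
    xmin: float
    ymin: float
    res: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster must be a non-empty 2-D array")

    # ------------------------------------------------------------------ shape
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrows * self.res

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.res

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True on valid (non-nodata) cells."""
        return np.isfinite(self.values)

    # ------------------------------------------------------------ coordinates
    def cell_centers(self):
        """(lons, lats) 1-D arrays of column / row cell-center coordinates."""
        lons = self.xmin + (np.arange(self.ncols) + 0.5) * self.res
        lats = self.ymax - (np.arange(self.nrows) + 0.5) * self.res
        return lons, lats

    def center_grids(self):
        """2-D lon and lat arrays of every cell center."""
        lons, lats = self.cell_centers()
        return np.meshgrid(lons, lats)

    def index_of(self, lon, lat):
        """(row, col) of the cell containing the point(s); may be out of range."""
        col = np.floor((np.asarray(lon) - self.xmin) / self.res).astype(int)
        row = np.floor((self.ymax - np.asarray(lat)) / self.res).astype(int)
        return row, col

    def contains(self, lon, lat):
        row, col = self.index_of(lon, lat)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def value_at(self, lon, lat):
        row, col = self.index_of(lon, lat)
        return self.values[row, col]

    # --------------------------------------------------------------- checking
    def same_grid(self, other: "RasterGrid", check_mask: bool = True) -> bool:
        """True when the two rasters share shape, registration and nodata mask."""
        if self.values.shape != other.values.shape:
            return False
        if not (
            np.isclose(self.xmin, other.xmin)
            and np.isclose(self.ymin, other.ymin)
            and np.isclose(self.res, other.res)
        ):
            return False
        if check_mask and not np.array_equal(self.mask, other.mask):
            return False
        return True

    def like(self, values: np.ndarray) -> "RasterGrid":
        """New raster with the same grid and the given values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch")
        return RasterGrid(values, self.xmin, self.ymin, self.res)

    # -------------------------------------------------------------------- I/O
    def write_ascii(self, path, nodata: float = -9999.0) -> None:
        """Write as ESRI ASCII grid (plain text)."""
        out = np.where(self.mask, self.values, nodata)
        header = (
            f"ncols {self.ncols}\nnrows {self.nrows}\n"
            f"xllcorner {self.xmin!r}\nyllcorner {self.ymin!r}\n"
            f"cellsize {self.res!r}\nNODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :meth:`RasterGrid.write_ascii`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    values = np.loadtxt(lines[6:])
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return RasterGrid(values, header["xllcorner"], header["yllcorner"], header["cellsize"])


def aggregate(grid: RasterGrid, factor: int, how: str = "mean") -> RasterGrid:
    """Upscale a raster by an integer factor (block aggregation).

    ``how='mean'`` averages valid cells per block (used for elevation
    classes); ``how='max'`` takes the block maximum (used for river
    classes, so a corridor is never averaged away). Blocks with no valid
    cell become nodata.
    """
    if factor < 1 or grid.nrows % factor or grid.ncols % factor:
        raise ValueError("factor must divide both raster dimensions")
    blocks = grid.values.reshape(grid.nrows // factor, factor, grid.ncols // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(grid.nrows // factor, grid.ncols // factor, -1)
    with np.errstate(all="ignore"):
        if how == "mean":
            out = np.nanmean(blocks, axis=-1)
        elif how == "max":
            out = np.nanmax(np.where(np.isfinite(blocks), blocks, -np.inf), axis=-1)
            out = np.where(np.isfinite(out), out, np.nan)
        else:
            raise ValueError(f"unknown aggregation {how!r}")
    return RasterGrid(out, grid.xmin, grid.ymin, grid.res * factor)
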