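"""Minimal planar raster grid with ESRI ASCII (.asc) text I/O.

A :class:`Grid` stores cell values in a 2-D array whose first row is the
*northernmost* row, matching the on-disk layout of the ESRI ASCII format.
No-data cells are represented as NaN in memory.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Grid", "read_ascii_grid", "write_ascii_grid"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass
class Grid:
    """A regular planar grid of float values.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values, row 0 at the top (maximum y). NaN marks no-data.
    xll, yll : float
        Coordinates of the lower-left corner of the lower-left cell (m).
    cellsize : float
        Cell edge length (m); cells are square.
    """

    values: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_area_km2(self) -> float:
        return (self.cellsize / 1000.0) ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) arrays of cell-center coordinates, shaped like values."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xll + (cols + 0.5) * self.cellsize
        # row 0 is the top row
        y = self.yll + (self.nrows - 1 - rows + 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def copy_with(self, values: np.ndarray) -> "Grid":
        return Grid(np.asarray(values, dtype=float), self.xll, self.yll, self.cellsize)


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII grid file into a :class:`Grid`."""
    text = Path(path).read_text()
    lines = text.splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"ESRI ASCII header missing keys: {missing}")
    nodata = header.get("nodata_value", -9999.0)
    values = np.loadtxt(io.StringIO("\n".join(lines[body_start:])), ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid body shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    values = np.where(values == nodata, np.nan, values)
    return Grid(values, header["xllcorner"], header["yllcorner"], header["cellsize"])


def write_ascii_grid(grid: Grid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a :class:`Grid` as an ESRI ASCII grid file (NaN -> nodata)."""
    out = np.where(np.isnan(grid.values), nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll:.6f}\n")
        fh.write(f"yllcorner {grid.yll:.6f}\n")
        fh.write(f"cellsize {grid.cellsize:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, out, fmt="%.8g")
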