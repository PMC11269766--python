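"""Minimal single-band raster container on a regular metric grid.

Rasters here are categorical land-use grids or per-cell dominance values on a
projected metric CRS.  Row 0 is the north edge; cell (row, col) has its centre
at ``(x0 + (col + 0.5) * cell, y0 + (nrows - row - 0.5) * cell)`` where
``(x0, y0)`` is the lower-left corner of the grid.  I/O uses the plain-text
ESRI ASCII grid format so fixtures stay human-readable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster"]


@dataclass
class Raster:
    data: np.ndarray        # (nrows, ncols), row 0 = north
    x0: float               # lower-left corner x (m)
    y0: float               # lower-left corner y (m)
    cell: float             # cell size (m)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell,
            self.y0 + self.nrows * self.cell,
        )

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(xs, ys)`` of cell-centre coordinates, shape (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        xs = self.x0 + (cols + 0.5) * self.cell
        ys = self.y0 + (self.nrows - rows - 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Grid indices of the cell containing point (x, y)."""
        col = int((x - self.x0) // self.cell)
        row = int(self.nrows - 1 - (y - self.y0) // self.cell)
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise IndexError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def value_at(self, x: float, y: float):
        r, c = self.rowcol(x, y)
        return self.data[r, c]

    # ---- text I/O ------------------------------------------------------

    def write_ascii(self, path: str | Path, fmt: str = "%g") -> None:
        path = Path(path)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x0}\n"
            f"yllcorner {self.y0}\n"
            f"cellsize {self.cell}\n"
            f"NODATA_value {self.nodata}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data, fmt=fmt)

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        path = Path(path)
        meta: dict[str, float] = {}
        with path.open() as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        r = cls(
            data=data,
            x0=meta["xllcorner"],
            y0=meta["yllcorner"],
            cell=meta["cellsize"],
            nodata=meta.get("nodata_value", -9999.0),
        )
        if r.nrows != int(meta["nrows"]) or r.ncols != int(meta["ncols"]):
            raise ValueError(f"{path}: header/body shape mismatch")
        return r
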