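"""Elevation rasters on a regular grid, with ESRI ASCII grid I/O.

Row 0 is the northernmost row (the layout of the ASCII format itself).  A
raster is either *geographic* (coordinates in decimal degrees; metric step
lengths are computed with a per-row cosine correction, adequate at the
sub-degree extents this package targets) or *projected* (coordinates already
in meters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ElevationRaster", "read_esri_ascii", "write_esri_ascii"]

#: meters per degree of latitude (spherical earth, R = 6371.0088 km)
M_PER_DEG = 6371.0088e3 * np.pi / 180.0


@dataclass
class ElevationRaster:
    """Regular elevation grid.

    ``values`` holds elevations in meters with ``numpy.nan`` for NODATA;
    ``xll``/``yll`` locate the lower-left corner; ``cell_size`` is in the
    coordinate units (degrees if ``geographic`` else meters).
    """

    values: np.ndarray
    xll: float
    yll: float
    cell_size: float
    nodata: float = -9999.0
    geographic: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def y_top(self) -> float:
        return self.yll + self.n_rows * self.cell_size

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing point (x, y); raises if outside."""
        col = int(np.floor((x - self.xll) / self.cell_size))
        row = int(np.floor((self.y_top - y) / self.cell_size))
        # points exactly on the top/right edge belong to the edge cell
        if col == self.n_cols and np.isclose(x, self.xll + self.n_cols * self.cell_size):
            col -= 1
        if row == self.n_rows and np.isclose(y, self.yll):
            row -= 1
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) falls outside the raster")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) of a cell center."""
        x = self.xll + (col + 0.5) * self.cell_size
        y = self.y_top - (row + 0.5) * self.cell_size
        return x, y

    def row_latitudes(self) -> np.ndarray:
        """Latitude (or projected y) of each row center, row 0 first."""
        return self.y_top - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def step_lengths_m(self) -> tuple[np.ndarray, float]:
        """Per-row east-west step length and the north-south step, in meters."""
        if self.geographic:
            dy = self.cell_size * M_PER_DEG
            dx = self.cell_size * M_PER_DEG * np.cos(np.radians(self.row_latitudes()))
        else:
            dy = self.cell_size
            dx = np.full(self.n_rows, self.cell_size)
        return dx, dy


def read_esri_ascii(path: str | Path, geographic: bool | None = None) -> ElevationRaster:
    """Read an ESRI ASCII grid (.asc).

    ``geographic`` defaults to a guess: cell sizes below 1 are taken as
    degrees, larger ones as meters.
    """
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: ESRI ASCII header misses {req}")
    values = np.concatenate(rows).reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    if geographic is None:
        geographic = header["cellsize"] < 1.0
    return ElevationRaster(
        values=values,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=nodata,
        geographic=geographic,
    )


def write_esri_ascii(raster: ElevationRaster, path: str | Path) -> None:
    vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.xll!r}\n")
        fh.write(f"yllcorner {raster.yll!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(f"{v:g}" for v in row) + "\n")
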