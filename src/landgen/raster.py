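"""Minimal geo-referenced grid container with ESRI ASCII grid (.asc) I/O.

Values are stored row-major from the top row (the ASCII grid convention);
``nodata`` cells are represented as NaN in memory and written back as the
header's NODATA_value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass
class Raster:
    values: np.ndarray          # (nrows, ncols), float, NaN = nodata
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D grid")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def data_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def like(self, values: np.ndarray) -> "Raster":
        """New raster with the same georeferencing and different values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch with template raster")
        return Raster(values, self.xllcorner, self.yllcorner, self.cellsize, self.nodata)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the pixel containing the point; raises off-grid."""
        col = int(np.floor((x - self.xllcorner) / self.cellsize))
        row_from_bottom = int(np.floor((y - self.yllcorner) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) falls outside the raster extent")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.xllcorner + (col + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - row - 0.5) * self.cellsize
        return x, y


def read_ascii_grid(path) -> Raster:
    """Parse an ESRI ASCII grid; header keys are case-insensitive."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in _HEADER_KEYS or key == "nodata_value":
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for key in _HEADER_KEYS:
        if key not in header:
            raise ValueError(f"missing ASCII grid header field: {key}")
    values = np.concatenate(rows).reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return Raster(values, header["xllcorner"], header["yllcorner"], header["cellsize"], nodata)


def write_ascii_grid(raster: Raster, path) -> None:
    vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner:.10g}\n")
        fh.write(f"yllcorner {raster.yllcorner:.10g}\n")
        fh.write(f"cellsize {raster.cellsize:.10g}\n")
        fh.write(f"NODATA_value {raster.nodata:.10g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
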