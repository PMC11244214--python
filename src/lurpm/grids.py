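"""Planar raster grids for predictor layers.

All spatial data in this package live on a common projected grid in meters.
A :class:`Grid` is a plain 2-D array with an origin and a square cell size;
row 0 is the southernmost row, column 0 the westernmost column, and cell
``(i, j)`` has its center at ``(x0 + (j + 0.5) * resolution,
y0 + (i + 0.5) * resolution)``.  Grids round-trip through a self-describing
gridded-CSV format (header comments carry the georeferencing).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    """A single-band raster on a projected planar grid (meters)."""

    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    resolution: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if self.resolution <= 0:
            raise ValueError("grid resolution must be positive")
        object.__setattr__(self, "values", values)

    # -- geometry -----------------------------------------------------------

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the covered area."""
        return (
            self.x0,
            self.x0 + self.nx * self.resolution,
            self.y0,
            self.y0 + self.ny * self.resolution,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return 1-D arrays of cell-center x (len nx) and y (len ny)."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.resolution
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.resolution
        return xs, ys

    def contains(self, x, y) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell containing each point (must be inside)."""
        inside = self.contains(x, y)
        if not np.all(inside):
            raise ValueError("point(s) outside grid extent")
        j = ((np.asarray(x, dtype=float) - self.x0) / self.resolution).astype(int)
        i = ((np.asarray(y, dtype=float) - self.y0) / self.resolution).astype(int)
        return i, j

    def value_at(self, x, y) -> np.ndarray:
        """Nearest-cell lookup of grid values at points (vectorized)."""
        i, j = self.cell_index(x, y)
        return self.values[i, j]

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        header = (
            f"# x0={self.x0!r} y0={self.y0!r} resolution={self.resolution!r} "
            f"ny={self.ny} nx={self.nx}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, delimiter=",", fmt="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Grid":
        path = Path(path)
        with path.open() as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError(f"{path}: missing gridded-CSV header line")
            meta = dict(tok.split("=") for tok in first[1:].split())
            values = np.loadtxt(fh, delimiter=",", ndmin=2)
        return cls(
            values=values,
            x0=float(meta["x0"]),
            y0=float(meta["y0"]),
            resolution=float(meta["resolution"]),
        )
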