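"""Minimal planar georeferencing for north-up rasters.

A :class:`GridTransform` maps pixel indices to map coordinates using the
six-coefficient affine convention shared by GDAL and rasterio::

    x = a * col + b * row + c
    y = d * col + e * row + f

where ``(col, row)`` are measured in pixel units from the upper-left corner
of the grid. The map coordinate of a pixel is the coordinate of its
*center*, i.e. the transform is evaluated at ``(col + 0.5, row + 0.5)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridTransform"]


@dataclass(frozen=True)
class GridTransform:
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def north_up(cls, west: float, north: float, xres: float, yres: float) -> "GridTransform":
        """Transform for a north-up grid with upper-left corner (west, north).

        ``xres`` and ``yres`` are positive pixel sizes; row index increases
        southward.
        """
        if xres <= 0 or yres <= 0:
            raise ValueError("pixel sizes must be positive")
        return cls(xres, 0.0, west, 0.0, -yres, north)

    @classmethod
    def identity(cls) -> "GridTransform":
        return cls(1.0, 0.0, 0.0, 0.0, -1.0, 0.0)

    def xy(self, row, col, offset: str = "center"):
        """Map coordinates of pixel (row, col); arrays broadcast."""
        shift = 0.5 if offset == "center" else 0.0
        col = np.asarray(col, dtype=float) + shift
        row = np.asarray(row, dtype=float) + shift
        x = self.a * col + self.b * row + self.c
        y = self.d * col + self.e * row + self.f
        return x, y

    def rowcol(self, x, y):
        """Fractional (row, col) pixel indices of map coordinates.

        The returned indices are continuous: the center of pixel (i, j)
        maps back to (i + 0.5, j + 0.5) before the caller floors them.
        """
        x = np.asarray(x, dtype=float) - self.c
        y = np.asarray(y, dtype=float) - self.f
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("singular transform")
        col = (self.e * x - self.b * y) / det
        row = (self.a * y - self.d * x) / det
        return row, col

    @property
    def coefficients(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)

    @property
    def is_north_up(self) -> bool:
        return self.b == 0 and self.d == 0 and self.a > 0 and self.e < 0

    def pixel_area(self) -> float:
        return abs(self.a * self.e - self.b * self.d)
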