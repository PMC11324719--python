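"""Shared 2D rasterization utilities.

All 2D mask operations in the package run on a common square-pixel grid
(default 0.2 mm), fine enough that discretization error is negligible
relative to the millimetre-scale registration errors being measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path

DEFAULT_PIXEL_MM = 0.2


@dataclass(frozen=True)
class Grid2D:
    """Axis-aligned pixel grid in mm; pixel (i, j) center is origin + (i, j)*pixel_mm."""

    origin: tuple[float, float]
    pixel_mm: float
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")
        if min(self.shape) < 1:
            raise ValueError("grid shape must be at least 1x1")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_mm**2

    def pixel_centers(self) -> np.ndarray:
        """Return (N, 2) array of pixel center coordinates in mm (row-major)."""
        ii, jj = np.meshgrid(
            np.arange(self.shape[0]), np.arange(self.shape[1]), indexing="ij"
        )
        x = self.origin[0] + ii * self.pixel_mm
        y = self.origin[1] + jj * self.pixel_mm
        return np.column_stack([x.ravel(), y.ravel()])


def grid_for_polygons(
    polygons: list[np.ndarray],
    pixel_mm: float = DEFAULT_PIXEL_MM,
    margin_mm: float = 2.0,
) -> Grid2D:
    """Build the smallest grid covering all polygons plus a margin."""
    if not polygons:
        raise ValueError("need at least one polygon to build a grid")
    pts = np.vstack([np.asarray(p, dtype=float) for p in polygons])
    lo = pts.min(axis=0) - margin_mm
    hi = pts.max(axis=0) + margin_mm
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / pixel_mm)) + 1 for k in range(2))
    return Grid2D(origin=(float(lo[0]), float(lo[1])), pixel_mm=pixel_mm, shape=shape)


def polygon_mask(vertices: np.ndarray, grid: Grid2D) -> np.ndarray:
    """Rasterize a closed polygon (first vertex not repeated) onto the grid.

    A pixel belongs to the mask when its center lies inside the polygon.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs >= 3 two-dimensional vertices")
    path = Path(verts, closed=False)
    inside = path.contains_points(grid.pixel_centers())
    return inside.reshape(grid.shape)
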