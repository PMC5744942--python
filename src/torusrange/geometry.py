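"""Plot geometry and run configuration.

Coordinates are planar metres in an arbitrary local frame (field GPS fixes
are treated as already projected); all computations are Euclidean, so no
geodetic handling exists anywhere in the package.

Rasters are cell-centred and row-major with the origin at the lower-left
plot corner: flat index ``iy * nx + ix``, cell ``(iy, ix)`` covering the
half-open box ``[x0 + ix*c, x0 + (ix+1)*c) x [y0 + iy*c, y0 + (iy+1)*c)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely

from .errors import ConfigurationError, GeometryError

_EPS = 1e-9


def _as_polygon_tuple(poly) -> tuple:
    """Normalize a polygon given as vertex sequence or shapely Polygon."""
    if isinstance(poly, shapely.Polygon):
        coords = list(poly.exterior.coords)
    else:
        coords = [(float(x), float(y)) for x, y in poly]
    return tuple((float(x), float(y)) for x, y in coords)


@dataclass(frozen=True)
class PlotGeometry:
    """A rectangular study plot with a square-cell raster laid over it.

    Parameters
    ----------
    length_x, length_y : float
        Plot side lengths in metres; must be positive integer multiples of
        ``cell_size``.
    origin_x, origin_y : float
        Lower-left corner of the plot in metres.
    cell_size : float
        Raster resolution in metres (default 5).
    exclusion_polygons : sequence of polygons
        Planar polygons (vertex lists or shapely Polygons) marking areas with
        no field data, e.g. a dirt road; cells whose centre falls inside any
        polygon are masked out of every analysis.
    """

    length_x: float
    length_y: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 5.0
    exclusion_polygons: tuple = ()

    def __post_init__(self):
        if not (self.length_x > 0 and self.length_y > 0):
            raise GeometryError("plot side lengths must be positive")
        if not self.cell_size > 0:
            raise GeometryError("cell_size must be positive")
        for name in ("length_x", "length_y"):
            ratio = getattr(self, name) / self.cell_size
            if abs(ratio - round(ratio)) > _EPS * max(1.0, ratio):
                raise GeometryError(
                    f"{name}={getattr(self, name)} is not an integer multiple "
                    f"of cell_size={self.cell_size}"
                )
        object.__setattr__(
            self,
            "exclusion_polygons",
            tuple(_as_polygon_tuple(p) for p in self.exclusion_polygons),
        )

    # --- raster layout -------------------------------------------------
    @property
    def nx(self) -> int:
        return int(round(self.length_x / self.cell_size))

    @property
    def ny(self) -> int:
        return int(round(self.length_y / self.cell_size))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    @property
    def x_centres(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.nx) + 0.5) * self.cell_size

    @property
    def y_centres(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.ny) + 0.5) * self.cell_size

    def centre_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(ny, nx) arrays of cell-centre x and y coordinates."""
        return np.meshgrid(self.x_centres, self.y_centres)

    def centres_flat(self) -> np.ndarray:
        """(n_cells, 2) cell-centre coordinates in row-major order."""
        cx, cy = self.centre_grids()
        return np.column_stack([cx.ravel(), cy.ravel()])

    # --- point <-> cell -----------------------------------------------
    def contains(self, x, y, strict: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if strict:
            return (
                (x > self.origin_x)
                & (x < self.origin_x + self.length_x)
                & (y > self.origin_y)
                & (y < self.origin_y + self.length_y)
            )
        return (
            (x >= self.origin_x)
            & (x < self.origin_x + self.length_x)
            & (y >= self.origin_y)
            & (y < self.origin_y + self.length_y)
        )

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the half-open cell containing each point."""
        inside = self.contains(x, y)
        if not np.all(inside):
            raise GeometryError("point outside plot rectangle")
        ix = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size)
        iy = np.floor((np.asarray(y, float) - self.origin_y) / self.cell_size)
        return iy.astype(int), ix.astype(int)

    # --- exclusion mask -------------------------------------------------
    def exclusion_mask(self) -> np.ndarray:
        """(ny, nx) boolean array, True where the cell centre is excluded."""
        mask = np.zeros((self.ny, self.nx), dtype=bool)
        if not self.exclusion_polygons:
            return mask
        cx, cy = self.centre_grids()
        for verts in self.exclusion_polygons:
            poly = shapely.Polygon(verts)
            hit = shapely.contains_xy(poly, cx.ravel(), cy.ravel())
            mask |= hit.reshape(mask.shape)
        return mask

    # --- derived geometries ---------------------------------------------
    def expanded_to_cover(self, points: np.ndarray, margin: float) -> "PlotGeometry":
        """Smallest grid-aligned expansion covering ``points`` plus a margin.

        The returned geometry shares this geometry's cell size and its cell
        lattice (origins differ by whole cells), so rasters on the two
        geometries can be overlaid by integer index offsets.
        """
        pts = np.asarray(points, dtype=float)
        lo = pts.min(axis=0) - margin
        hi = pts.max(axis=0) + margin
        c = self.cell_size
        kx_lo = min(0, math.floor((lo[0] - self.origin_x) / c))
        ky_lo = min(0, math.floor((lo[1] - self.origin_y) / c))
        kx_hi = max(self.nx, math.ceil((hi[0] - self.origin_x) / c))
        ky_hi = max(self.ny, math.ceil((hi[1] - self.origin_y) / c))
        return PlotGeometry(
            length_x=(kx_hi - kx_lo) * c,
            length_y=(ky_hi - ky_lo) * c,
            origin_x=self.origin_x + kx_lo * c,
            origin_y=self.origin_y + ky_lo * c,
            cell_size=c,
        )

    def aligned_offset(self, other: "PlotGeometry") -> tuple[int, int]:
        """Integer (row, col) offset of ``other``'s cell (0,0) in this grid.

        Raises GeometryError when the cell sizes differ or the lattices are
        not aligned.
        """
        if abs(self.cell_size - other.cell_size) > _EPS:
            raise GeometryError("cell sizes differ between grids")
        fx = (other.origin_x - self.origin_x) / self.cell_size
        fy = (other.origin_y - self.origin_y) / self.cell_size
        if abs(fx - round(fx)) > 1e-6 or abs(fy - round(fy)) > 1e-6:
            raise GeometryError("grids are not lattice-aligned")
        return int(round(fy)), int(round(fx))


@dataclass
class RunConfig:
    """Pipeline configuration with the study's default rules.

    ``min_locations``/``max_locations`` implement the relocation-count
    inclusion rules (drop birds under 25 sightings, subsample over 32);
    ``torus_step`` is the torus translation step in metres and must equal
    the raster cell size.
    """

    min_locations: int = 25
    max_locations: int = 32
    kernel_level: float = 0.95
    torus_step: float = 5.0
    variogram_lags: int = 5
    significance_level: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.kernel_level < 1:
            raise ConfigurationError("kernel_level must be in (0, 1)")
        if self.min_locations > self.max_locations:
            raise ConfigurationError("min_locations must not exceed max_locations")
        if self.torus_step <= 0:
            raise ConfigurationError("torus_step must be positive")
        if self.variogram_lags < 1:
            raise ConfigurationError("variogram_lags must be >= 1")
        if not 0 < self.significance_level < 1:
            raise ConfigurationError("significance_level must be in (0, 1)")
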