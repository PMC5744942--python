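"""Gridded surfaces: habitat rasters, utilization densities, pooled overlays.

All rasters share the :class:`~torusrange.geometry.PlotGeometry` layout:
row-major ``(ny, nx)`` arrays, row 0 at the *bottom* of the plot. The ESRI
ASCII grid text format (which stores the top row first) is the on-disk
representation; rows are flipped on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import FormatError, GeometryError
from .geometry import PlotGeometry

NODATA = -9999.0


@dataclass
class HabitatRaster:
    """A continuous habitat variable on the plot grid.

    ``mask`` is True on excluded cells (e.g. the dirt-road strip); those
    cells carry no usable value.
    """

    geometry: PlotGeometry
    values: np.ndarray
    variable_name: str = ""
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        shape = (self.geometry.ny, self.geometry.nx)
        if self.values.shape != shape:
            raise GeometryError(
                f"raster values shape {self.values.shape} != geometry {shape}"
            )
        if self.mask is None:
            self.mask = np.zeros(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise GeometryError("mask shape does not match geometry")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise GeometryError("non-finite values on unmasked cells")

    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def value_at(self, x, y) -> np.ndarray:
        iy, ix = self.geometry.cell_of(x, y)
        return self.values[iy, ix]

    def with_values(self, values: np.ndarray) -> "HabitatRaster":
        return HabitatRaster(self.geometry, values, self.variable_name, self.mask)


@dataclass
class UDSurface:
    """A kernel utilization distribution on a grid.

    Density integrates to 1 over the grid: sum(density) * cell_area == 1.
    """

    geometry: PlotGeometry
    density: np.ndarray
    bandwidth_m: float

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        shape = (self.geometry.ny, self.geometry.nx)
        if self.density.shape != shape:
            raise GeometryError(
                f"density shape {self.density.shape} != geometry {shape}"
            )
        if np.any(self.density < 0):
            raise GeometryError("utilization density must be nonnegative")

    def mass(self) -> float:
        return float(self.density.sum() * self.geometry.cell_area)


@dataclass
class DensityOverlay:
    """Pooled utilization density of all retained individuals on the plot.

    Mass 1 over unmasked cells; masked cells carry density 0.
    """

    geometry: PlotGeometry
    density: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        shape = (self.geometry.ny, self.geometry.nx)
        if self.density.shape != shape:
            raise GeometryError("overlay density shape != geometry")
        if self.mask is None:
            self.mask = np.zeros(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.density < 0):
            raise GeometryError("overlay density must be nonnegative")

    def mass(self) -> float:
        return float(self.density[~self.mask].sum() * self.geometry.cell_area)

    def cell_weights(self) -> np.ndarray:
        """(ny, nx) probability mass per cell (zero on masked cells)."""
        w = self.density * self.geometry.cell_area
        w[self.mask] = 0.0
        return w


# ---------------------------------------------------------------------------
# ESRI ASCII grid text I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: HabitatRaster, path, nodata: float = NODATA) -> None:
    """Write a raster as an ESRI ASCII grid (plain text, top row first)."""
    g = raster.geometry
    vals = np.where(raster.mask, nodata, raster.values)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {g.nx}\n")
        fh.write(f"nrows {g.ny}\n")
        fh.write(f"xllcorner {g.origin_x:.12g}\n")
        fh.write(f"yllcorner {g.origin_y:.12g}\n")
        fh.write(f"cellsize {g.cell_size:.12g}\n")
        fh.write(f"NODATA_value {nodata:.12g}\n")
        for row in vals[::-1]:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def read_ascii_grid(path, variable_name: str = "") -> HabitatRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip() and not _is_data_line(lines[i]):
        key, _, val = lines[i].partition(" ")
        header[key.strip().lower()] = float(val)
        i += 1
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing ASCII-grid header line {key!r}")
    nx, ny = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", NODATA)
    rows = [np.array(ln.split(), dtype=float) for ln in lines[i:] if ln.strip()]
    if len(rows) != ny or any(r.size != nx for r in rows):
        raise FormatError(f"{path}: grid body does not match ncols/nrows")
    vals = np.array(rows)[::-1]
    mask = np.isclose(vals, nodata)
    vals = np.where(mask, 0.0, vals)
    geom = PlotGeometry(
        length_x=nx * header["cellsize"],
        length_y=ny * header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
    )
    return HabitatRaster(geom, vals, variable_name=variable_name, mask=mask)


def _is_data_line(line: str) -> bool:
    first = line.split()[0]
    try:
        float(first)
        return True
    except ValueError:
        return False
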