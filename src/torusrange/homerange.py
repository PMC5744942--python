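"""Per-individual home-range estimation.

Two estimators are provided, matching standard practice for territorial
passerines monitored by repeated sightings:

* the fixed-kernel utilization distribution (UD) with a single isotropic
  Gaussian bandwidth chosen by least-squares cross-validation (LSCV), home
  range = smallest raster region holding 95% of UD mass;
* the 95% minimum convex polygon (MCP), the convex hull after peeling the
  5% of points farthest from the arithmetic mean centre.

Inclusion rules for field data: individuals with fewer than
``min_locations`` sightings are dropped (home-range accumulation curves do
not stabilise below ~25 points); individuals with more than
``max_locations`` are subsampled to exactly that many (dense clusters of
repeated sightings make LSCV degenerate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

from .errors import ConvergenceError, DegenerateGeometryError, GeometryError
from .geometry import PlotGeometry, RunConfig
from .io import RelocationSet
from .rasters import UDSurface

log = logging.getLogger(__name__)

M2_PER_HA = 10_000.0
#: 95% quantile of the chi-square(2) distribution; the 95% highest-density
#: region of an isotropic bivariate normal(sigma) is a disk of area
#: pi * CHI2_95 * sigma^2.
CHI2_95 = 5.991464547107979


@dataclass
class HomeRangeRegion:
    """A home-range estimate: either a raster cell set (kernel) or a polygon (MCP)."""

    level: float
    area_ha: float
    cells: Optional[frozenset] = None      # flat row-major cell indices
    geometry: Optional[PlotGeometry] = None
    vertices: Optional[np.ndarray] = None  # hull vertices, CCW

    def __post_init__(self):
        if self.area_ha < 0:
            raise ValueError("area_ha must be nonnegative")


@dataclass
class SummaryStats:
    mean: float
    sd: float
    q1: float
    q3: float
    n: int


# ---------------------------------------------------------------------------
# inclusion rules
# ---------------------------------------------------------------------------

def filter_individuals(relocations: RelocationSet, config: RunConfig) -> RelocationSet:
    """Apply the location-count inclusion rules.

    Individuals with fewer than ``config.min_locations`` points are dropped;
    individuals with more than ``config.max_locations`` are subsampled to
    exactly that many by seeded uniform sampling without replacement, keeping
    the surviving points in their original order.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for ind in relocations.individuals:
        sub = relocations.df[relocations.df["id"] == ind]
        n = len(sub)
        if n < config.min_locations:
            log.info("filter_individuals: dropping %s (%d < %d locations)",
                     ind, n, config.min_locations)
            continue
        if n > config.max_locations:
            keep = np.sort(rng.choice(n, size=config.max_locations, replace=False))
            sub = sub.iloc[keep]
            log.info("filter_individuals: subsampled %s from %d to %d locations",
                     ind, n, config.max_locations)
        frames.append(sub)
    if not frames:
        log.warning("filter_individuals: no individuals retained")
        return RelocationSet(relocations.df.iloc[0:0].copy())
    import pandas as pd
    return RelocationSet(pd.concat(frames).reset_index(drop=True))


# ---------------------------------------------------------------------------
# minimum convex polygon
# ---------------------------------------------------------------------------

def mcp(points, percent: float = 0.95) -> HomeRangeRegion:
    """Minimum convex polygon home range at the given inclusion percentage.

    Peels the ``floor((1 - percent) * n)`` points farthest (Euclidean) from
    the arithmetic mean centre, then returns the convex hull of the rest.
    Distance ties are broken by peeling the later-listed point first.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not 0 < percent <= 1:
        raise ValueError("percent must be in (0, 1]")
    n = len(pts)
    # epsilon guards float artifacts like (1 - 0.8) * 5 = 0.9999...
    n_peel = int(math.floor((1.0 - percent) * n + 1e-9))
    if n_peel > 0:
        centre = pts.mean(axis=0)
        dist = np.hypot(*(pts - centre).T)
        # sort by distance descending, later index first among ties
        order = sorted(range(n), key=lambda i: (-dist[i], -i))
        drop = set(order[:n_peel])
        pts = pts[[i for i in range(n) if i not in drop]]
    if len(pts) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 points after peeling, have {len(pts)}"
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(
            "points are collinear; convex polygon undefined"
        ) from exc
    # for 2-D input ConvexHull.volume is the polygon area
    return HomeRangeRegion(
        level=percent,
        area_ha=float(hull.volume) / M2_PER_HA,
        vertices=pts[hull.vertices],
    )


def accumulation_curve(points) -> list[tuple[int, float]]:
    """Area-accumulation curve: 100% MCP area of the first k points, k=3..n.

    While the first k points are still collinear the area is recorded as 0.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 points")
    curve = []
    for k in range(3, len(pts) + 1):
        try:
            area = mcp(pts[:k], percent=1.0).area_ha
        except DegenerateGeometryError:
            area = 0.0
        curve.append((k, area))
    return curve


def asymptote_reached(curve, tolerance: float = 0.01) -> tuple[bool, Optional[int]]:
    """First k* on the accumulation curve where five more points add <= 1% area.

    Returns ``(True, k*)`` for the first k* with
    ``area(k* + 5) <= (1 + tolerance) * area(k*)`` and positive area,
    otherwise ``(False, None)``.
    """
    if len(curve) < 8:
        raise ValueError("curve must cover at least 8 point counts (k..k+5)")
    areas = dict(curve)
    for k, area in curve:
        if area <= 0 or (k + 5) not in areas:
            continue
        if areas[k + 5] <= (1.0 + tolerance) * area:
            return True, k
    return False, None


# ---------------------------------------------------------------------------
# kernel UD with LSCV bandwidth
# ---------------------------------------------------------------------------

def reference_bandwidth(points) -> float:
    """Bivariate-normal reference bandwidth h_ref = sigma * n^(-1/6)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("need >= 2 points")
    sigma = math.sqrt(0.5 * (pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1)))
    if sigma == 0:
        raise ConvergenceError("all points identical; no reference bandwidth")
    return sigma * n ** (-1.0 / 6.0)


def _lscv_score(h: float, d2: np.ndarray, n: int) -> float:
    """Exact LSCV score for the isotropic bivariate Gaussian kernel.

    d2 is the condensed vector of squared pairwise distances. The score is
    integral(fhat^2) - 2/n * sum_i fhat_{-i}(x_i), both terms in closed form
    for Gaussian kernels.
    """
    h2 = h * h
    term1 = (n + 2.0 * np.exp(-d2 / (4.0 * h2)).sum()) / (n * n * 4.0 * np.pi * h2)
    term2 = 2.0 * np.exp(-d2 / (2.0 * h2)).sum() / (n * (n - 1) * np.pi * h2)
    return term1 - term2


def lscv_bandwidth(points, individual: str = "") -> float:
    """LSCV-optimal isotropic bandwidth for a bivariate Gaussian kernel.

    The score is scanned over [0.05 h_ref, 2 h_ref] and the interior minimum
    refined by bounded golden-section search. When the minimum sits on the
    interval boundary the score is monotone there (the classic failure mode
    with many tightly clustered points) and a ConvergenceError is raised.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 5:
        raise ValueError("need >= 5 points for LSCV")
    h_ref = reference_bandwidth(pts)
    d2 = pdist(pts, metric="sqeuclidean")
    lo, hi = 0.05 * h_ref, 2.0 * h_ref
    grid = np.geomspace(lo, hi, 64)
    scores = np.array([_lscv_score(h, d2, n) for h in grid])
    k = int(np.argmin(scores))
    if k == 0 or k == len(grid) - 1:
        who = f" for individual {individual!r}" if individual else ""
        raise ConvergenceError(
            f"LSCV score has no interior minimum on [0.05, 2] x h_ref{who}; "
            "points are likely too tightly clustered"
        )
    res = minimize_scalar(
        _lscv_score, args=(d2, n), bounds=(grid[k - 1], grid[k + 1]),
        method="bounded", options={"xatol": 1e-6 * h_ref},
    )
    return float(res.x)


def kernel_ud(points, bandwidth_m: float, geometry: PlotGeometry) -> UDSurface:
    """Fixed-kernel utilization distribution on the given grid.

    Density at each cell centre is the average of isotropic bivariate
    Gaussian kernels centred at the points, then renormalized so the raster
    integrates to exactly 1. The grid must cover every point with a
    3-bandwidth margin so that negligible mass is lost off-grid.
    """
    pts = np.asarray(points, dtype=float)
    if bandwidth_m <= 0:
        raise ValueError("bandwidth must be positive")
    margin = 3.0 * bandwidth_m
    tol = 1e-9
    if (
        pts[:, 0].min() - margin < geometry.origin_x - tol
        or pts[:, 0].max() + margin > geometry.origin_x + geometry.length_x + tol
        or pts[:, 1].min() - margin < geometry.origin_y - tol
        or pts[:, 1].max() + margin > geometry.origin_y + geometry.length_y + tol
    ):
        raise GeometryError(
            "grid does not cover the points plus a 3-bandwidth margin; "
            "use PlotGeometry.expanded_to_cover first"
        )
    cx, cy = geometry.centre_grids()
    h2 = bandwidth_m ** 2
    dens = np.zeros((geometry.ny, geometry.nx))
    # accumulate per point; n is small (<= a few dozen relocations)
    for px, py in pts:
        dens += np.exp(-0.5 * ((cx - px) ** 2 + (cy - py) ** 2) / h2)
    dens /= len(pts) * 2.0 * np.pi * h2
    dens /= dens.sum() * geometry.cell_area
    return UDSurface(geometry=geometry, density=dens, bandwidth_m=float(bandwidth_m))


def isopleth_region(ud: UDSurface, level: float = 0.95) -> HomeRangeRegion:
    """Smallest raster region holding ``level`` of the UD mass.

    Cells are accumulated in decreasing density order (row-major order
    breaks ties) until the cumulative mass reaches the level.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    flat = ud.density.ravel()
    order = np.argsort(-flat, kind="stable")
    mass = np.cumsum(flat[order]) * ud.geometry.cell_area
    total = mass[-1]
    # relative tolerance guards against float shortfalls like 0.95*k/k
    k = int(np.searchsorted(mass, level * total * (1.0 - 1e-12)) + 1)
    cells = frozenset(int(i) for i in order[:k])
    return HomeRangeRegion(
        level=level,
        area_ha=k * ud.geometry.cell_area / M2_PER_HA,
        cells=cells,
        geometry=ud.geometry,
    )


def overlap_percent(a: HomeRangeRegion, b: HomeRangeRegion) -> float:
    """Fraction of the focal region ``a`` overlapped by region ``b``.

    Directional: overlap_percent(a, b) need not equal overlap_percent(b, a).
    """
    if a.cells is None or b.cells is None:
        raise GeometryError("overlap requires raster (kernel) regions")
    if a.geometry != b.geometry:
        raise GeometryError("regions live on different grids")
    inter = len(a.cells & b.cells) * a.geometry.cell_area
    return inter / (a.area_ha * M2_PER_HA)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_table(values) -> SummaryStats:
    """Mean, SD (n-1), and type-7 quartiles of a list of areas (hectares)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to summarize")
    return SummaryStats(
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        q1=float(np.quantile(v, 0.25)),  # numpy 'linear' = type-7
        q3=float(np.quantile(v, 0.75)),
        n=int(v.size),
    )


# ---------------------------------------------------------------------------
# estimator class
# ---------------------------------------------------------------------------

class KernelUD(BaseEstimator):
    """Fixed-kernel UD home-range estimator with LSCV bandwidth.

    Parameters
    ----------
    bandwidth : float or None
        Kernel bandwidth in metres; None (default) selects it by LSCV.
    level : float
        Isopleth level for the home-range region (default 0.95).
    cell_size : float
        Raster resolution in metres (default 5, the shared plot grid).
    geometry : PlotGeometry or None
        Base grid to align to; the fitted grid is its lattice-aligned
        expansion covering the points plus a 3-bandwidth margin. When None a
        free-standing grid anchored at the data is built.

    Attributes
    ----------
    bandwidth_ : float
        Bandwidth actually used (LSCV minimizer unless supplied).
    ud_ : UDSurface
        The fitted utilization distribution.
    region_ : HomeRangeRegion
        The ``level`` isopleth region.
    area_ha_ : float
        Home-range area in hectares.
    """

    def __init__(self, bandwidth=None, level=0.95, cell_size=5.0, geometry=None):
        self.bandwidth = bandwidth
        self.level = level
        self.cell_size = cell_size
        self.geometry = geometry

    def fit(self, X, y=None):
        pts = np.asarray(X, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of planar coordinates")
        if not np.all(np.isfinite(pts)):
            raise ValueError("coordinates must be finite")
        self.bandwidth_ = (
            float(self.bandwidth) if self.bandwidth is not None
            else lscv_bandwidth(pts)
        )
        base = self.geometry
        if base is None:
            c = self.cell_size
            base = PlotGeometry(
                length_x=c, length_y=c,
                origin_x=math.floor(pts[:, 0].min() / c) * c,
                origin_y=math.floor(pts[:, 1].min() / c) * c,
                cell_size=c,
            )
        grid = base.expanded_to_cover(pts, margin=3.0 * self.bandwidth_)
        self.ud_ = kernel_ud(pts, self.bandwidth_, grid)
        self.region_ = isopleth_region(self.ud_, self.level)
        self.area_ha_ = self.region_.area_ha
        return self

    def score_samples(self, X):
        """UD density at the cells containing the query points."""
        pts = np.asarray(X, dtype=float)
        return self.ud_.density[self.ud_.geometry.cell_of(pts[:, 0], pts[:, 1])]
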