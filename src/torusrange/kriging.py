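"""Ordinary kriging of habitat variables with a spherical variogram.

The workflow mirrors standard geostatistical practice on quadrat samples:
empirical semivariogram with a small number of equal-width lags (default 5,
cutoff at half the maximum pair distance), weighted least-squares fit of the
spherical model, then ordinary-kriging prediction at every raster cell with
a global neighbourhood (all samples; plots hold at most a few hundred
quadrats, so exactness beats speed here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import SingularSystemError, VariogramFitError
from .geometry import PlotGeometry
from .io import QuadratTable
from .rasters import HabitatRaster

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SphericalModel:
    """Spherical semivariogram: nugget + psill*(1.5 h/a - 0.5 (h/a)^3), sill at h >= a."""

    nugget: float
    partial_sill: float
    range_m: float

    def __post_init__(self):
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be nonnegative")
        if self.range_m <= 0:
            raise ValueError("range_m must be positive")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def gamma(self, h) -> np.ndarray:
        """Semivariance at lag distance h (gamma(0) = 0 by convention)."""
        h = np.asarray(h, dtype=float)
        r = np.clip(h / self.range_m, 0.0, 1.0)
        g = self.nugget + self.partial_sill * (1.5 * r - 0.5 * r ** 3)
        return np.where(h > 0, g, 0.0)

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance implied by the model.

        C(0) = partial_sill + nugget; for h > 0,
        C(h) = partial_sill - (gamma(h) - nugget).
        """
        h = np.asarray(h, dtype=float)
        r = np.clip(h / self.range_m, 0.0, 1.0)
        c = self.partial_sill * (1.0 - (1.5 * r - 0.5 * r ** 3))
        return np.where(h > 0, c, self.partial_sill + self.nugget)


@dataclass
class Variogram:
    """Empirical semivariogram: binned lag centres, semivariances, pair counts."""

    lag_centres: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray
    cutoff: float

    def __post_init__(self):
        self.lag_centres = np.asarray(self.lag_centres, dtype=float)
        self.semivariance = np.asarray(self.semivariance, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if np.any(np.diff(self.lag_centres) <= 0):
            raise ValueError("lag centres must be strictly increasing")
        if np.any(self.pair_counts < 1):
            raise ValueError("used lags must contain at least one pair")

    @property
    def n_lags(self) -> int:
        return len(self.lag_centres)


def empirical_variogram(samples, variable: str = None, n_lags: int = 5) -> Variogram:
    """Empirical semivariogram of one variable over the quadrat sample.

    Pair distances are binned into ``n_lags`` equal-width bins over
    ``(0, max_pair_distance / 2]``; per-bin semivariance is the mean of
    ``0.5 * (z_i - z_j)^2``. Empty bins are dropped with a warning. Accepts
    either a QuadratTable plus variable name or ``(coords, values)`` arrays.
    """
    if isinstance(samples, QuadratTable):
        xy = samples.coords()
        z = samples.values(variable)
    else:
        xy, z = samples
        xy = np.asarray(xy, dtype=float)
        z = np.asarray(z, dtype=float)
    ok = np.isfinite(z)
    if ok.sum() < 2:
        raise ValueError("need >= 2 quadrats with the variable present")
    xy, z = xy[ok], z[ok]
    d = pdist(xy)
    if not np.any(d > 0):
        raise ValueError("all pairwise distances are zero")
    cutoff = d.max() / 2.0
    if not np.any((d > 0) & (d <= cutoff)):
        # degenerate layouts (e.g. two points) where the half-max cutoff
        # excludes every pair: fall back to the full distance range
        cutoff = d.max()
    dz2 = 0.5 * pdist(z[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, cutoff, n_lags + 1)
    use = (d > 0) & (d <= cutoff)
    # bin index via right-closed intervals (0, e1], (e1, e2], ...
    idx = np.clip(np.searchsorted(edges, d[use], side="left") - 1, 0, n_lags - 1)
    centres, semis, counts = [], [], []
    for b in range(n_lags):
        sel = idx == b
        m = int(sel.sum())
        if m == 0:
            warnings.warn(f"empirical_variogram: lag bin {b + 1} is empty; dropped")
            continue
        centres.append(0.5 * (edges[b] + edges[b + 1]))
        semis.append(float(dz2[use][sel].mean()))
        counts.append(m)
    return Variogram(np.array(centres), np.array(semis), np.array(counts), cutoff)


def fit_spherical(emp: Variogram, n_starts: int = 5) -> SphericalModel:
    """Weighted least-squares fit of the spherical model to an empirical variogram.

    Minimizes the pair-count-weighted squared error over nugget >= 0,
    partial_sill >= 0 and range in (0, 2*max_lag], with ``n_starts``
    multi-start L-BFGS-B runs; among (near-)tied optima the smallest range
    wins.
    """
    if emp.n_lags < 3:
        raise VariogramFitError("need >= 3 non-empty lags to fit", empirical=emp)
    h = emp.lag_centres
    g = emp.semivariance
    w = emp.pair_counts.astype(float)
    a_max = 2.0 * h[-1]
    scale = max(g.max(), 1e-12)

    def sse(theta):
        nug, ps, a = theta
        r = np.clip(h / a, 0.0, 1.0)
        model = nug + ps * (1.5 * r - 0.5 * r ** 3)
        return float(np.sum(w * (model - g) ** 2))

    bounds = [(0.0, None), (0.0, None), (1e-6 * a_max, a_max)]
    starts = []
    for frac_a in np.linspace(0.2, 1.0, n_starts):
        starts.append([0.1 * scale, 0.9 * scale, frac_a * a_max])
    best = None
    for x0 in starts:
        try:
            res = minimize(sse, x0, method="L-BFGS-B", bounds=bounds)
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        cand = (res.fun, res.x)
        if best is None:
            best = cand
        else:
            # near-tied objective: prefer the smaller range
            if cand[0] < best[0] - 1e-12 * (1 + abs(best[0])):
                best = cand
            elif abs(cand[0] - best[0]) <= 1e-9 * (1 + abs(best[0])) and cand[1][2] < best[1][2]:
                best = cand
    if best is None:
        raise VariogramFitError("all optimizer starts failed", empirical=emp)
    nug, ps, a = best[1]
    return SphericalModel(nugget=max(nug, 0.0), partial_sill=max(ps, 0.0), range_m=a)


class OrdinaryKriging(BaseEstimator, RegressorMixin):
    """Ordinary-kriging interpolator with a spherical variogram.

    Parameters
    ----------
    model : SphericalModel or None
        Variogram model; None (default) fits one to the training sample via
        :func:`empirical_variogram` + :func:`fit_spherical`.
    n_lags : int
        Number of variogram lags when the model is fitted (default 5).

    Attributes
    ----------
    model_ : SphericalModel
        The variogram model used for prediction.
    variogram_ : Variogram or None
        Empirical variogram (None when the model was supplied).
    X_, y_ : ndarray
        Training coordinates and values.

    Notes
    -----
    Prediction solves, for each target location, the (n+1) ordinary-kriging
    system with the semivariance matrix and a Lagrange multiplier forcing
    the weights to sum to one; gamma(0) = 0, so prediction is exact at
    sample locations.
    """

    def __init__(self, model=None, n_lags: int = 5):
        self.model = model
        self.n_lags = n_lags

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2) planar coordinates")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        ok = np.isfinite(y)
        X, y = X[ok], y[ok]
        if len(X) < 3:
            raise ValueError("need >= 3 samples with values")
        d0 = squareform(pdist(X))
        if np.any(d0[np.triu_indices_from(d0, k=1)] == 0):
            raise SingularSystemError(
                "coincident sample coordinates make the kriging matrix singular"
            )
        if self.model is not None:
            self.model_ = self.model
            self.variogram_ = None
        else:
            self.variogram_ = empirical_variogram((X, y), n_lags=self.n_lags)
            self.model_ = fit_spherical(self.variogram_)
        n = len(X)
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = self.model_.gamma(d0)
        A[n, :n] = 1.0
        A[:n, n] = 1.0
        A[n, n] = 0.0
        try:
            self._lu = lu_factor(A)
        except Exception as exc:
            raise SingularSystemError(f"kriging matrix is singular: {exc}") from exc
        self.X_, self.y_ = X, y
        return self

    def predict(self, X):
        """Ordinary-kriging predictions at the query coordinates."""
        Xq = np.atleast_2d(np.asarray(X, dtype=float))
        n = len(self.X_)
        rhs = np.empty((n + 1, len(Xq)))
        rhs[:n] = self.model_.gamma(cdist(self.X_, Xq))
        rhs[n] = 1.0
        lam = lu_solve(self._lu, rhs)
        n_neg = int((lam[:n].min(axis=0) < -1e-10).sum())
        if n_neg:
            log.info("OrdinaryKriging.predict: negative weights at %d of %d targets",
                     n_neg, len(Xq))
        return lam[:n].T @ self.y_


def krige_grid(
    samples: QuadratTable,
    variable: str,
    model: SphericalModel,
    geometry: PlotGeometry,
    clip_negative: bool = False,
) -> HabitatRaster:
    """Ordinary-kriging prediction of one variable at every unmasked cell centre.

    Cells inside the geometry's exclusion polygons are masked and carry no
    value. ``clip_negative`` clips negative predictions to zero (physical
    lower bound for heights, densities, covers), logging how many cells were
    affected.
    """
    ok = OrdinaryKriging(model=model).fit(samples.coords(), samples.values(variable))
    mask = geometry.exclusion_mask()
    vals = np.zeros((geometry.ny, geometry.nx))
    targets = geometry.centres_flat()[~mask.ravel()]
    pred = ok.predict(targets)
    if clip_negative:
        n_clip = int((pred < 0).sum())
        if n_clip:
            log.info("krige_grid[%s]: clipped %d negative predictions to 0",
                     variable, n_clip)
        pred = np.clip(pred, 0.0, None)
    vals[~mask] = pred
    return HabitatRaster(geometry, vals, variable_name=variable, mask=mask)
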