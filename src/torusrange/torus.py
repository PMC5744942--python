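"""The Adjusted-SD / torus-shift habitat-association test.

The question: is the pooled utilization density of the monitored birds
aligned with a continuous habitat variable, beyond what their territorial
clumping and the habitat's own spatial autocorrelation would produce by
chance?

The statistic: along the habitat gradient x, estimate p(x) (how abundant
habitat value x is on the plot) and p(E|x) (the conditional probability of
bird presence given habitat value x) by Gaussian-kernel smoothing over the
raster cells, then take the standard deviation of x weighted by p(E|x) —
the "adjusted" SD: the spread of use along the gradient after adjusting
for habitat abundance (the division by p(x) inside p(E|x)). A habitat
specialist concentrates its conditional use on a narrow band of x — a
single peak in p(E|x) — giving a *small* SD; the observed SD is therefore
compared against the lower tail of the torus null. The sign (preference vs
avoidance) comes from comparing the density-weighted mean habitat value
with the plot mean.

The null: every cyclic translation of the habitat map on the
two-dimensional torus, in cell-size steps, times the 4 base maps (original,
180-degree rotation, mirror, mirror+rotation). This preserves both the
habitat map's internal autocorrelation and the bird pattern while breaking
their alignment; the variant set is exhaustive, so the test is fully
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
from sklearn.base import BaseEstimator

from .errors import (
    ConfigurationError,
    DegenerateGradientError,
    GeometryError,
    IndeterminateSignError,
)
from .geometry import PlotGeometry, RunConfig
from .rasters import DensityOverlay, HabitatRaster, UDSurface

log = logging.getLogger(__name__)

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class ConditionalCurve:
    """p(x) and p(E|x) along one habitat gradient.

    ``supported`` flags grid points where p(x) is at least 1% of its maximum;
    only supported points enter the adjusted-SD statistic.
    """

    x_grid: np.ndarray
    p_x: np.ndarray
    p_e_given_x: np.ndarray
    supported: np.ndarray
    bandwidth: float


@dataclass
class NullDistribution:
    observed_sd: float
    null_sds: np.ndarray  # NaN where a variant's profile was undefined
    n_variants: int

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.null_sds).sum())


@dataclass
class AssociationResult:
    variable_name: str
    observed_sd: float
    quantile: float
    significant: bool
    sign: str  # "positive" | "negative" | "none"
    n_variants: int
    n_valid: int
    null: Optional[NullDistribution] = None


# ---------------------------------------------------------------------------
# pooled density
# ---------------------------------------------------------------------------

def pooled_density(
    uds: list[UDSurface],
    geometry: PlotGeometry,
    mask: Optional[np.ndarray] = None,
) -> DensityOverlay:
    """Sum individual UDs onto the plot grid and renormalize to mass 1.

    Each UD may live on its own (lattice-aligned) expansion of the plot
    grid; densities are added cell-by-cell where the grids overlap, masked
    cells are zeroed, and the result is rescaled so the unmasked cells hold
    total probability mass 1.
    """
    if not uds:
        raise ValueError("need at least one UD")
    if mask is None:
        mask = geometry.exclusion_mask()
    total = np.zeros((geometry.ny, geometry.nx))
    for ud in uds:
        oy, ox = geometry.aligned_offset(ud.geometry)
        # ud cell (iy, ix) sits at plot cell (iy + oy, ix + ox)
        y0, x0 = max(0, oy), max(0, ox)
        y1 = min(geometry.ny, oy + ud.geometry.ny)
        x1 = min(geometry.nx, ox + ud.geometry.nx)
        if y1 <= y0 or x1 <= x0:
            continue
        total[y0:y1, x0:x1] += ud.density[y0 - oy:y1 - oy, x0 - ox:x1 - ox]
    total[mask] = 0.0
    s = total.sum() * geometry.cell_area
    if s <= 0:
        raise GeometryError("pooled density has zero mass on the plot")
    return DensityOverlay(geometry, total / s, mask=mask)


# ---------------------------------------------------------------------------
# conditional profile and statistic
# ---------------------------------------------------------------------------

def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a 1-D Gaussian KDE."""
    x = np.asarray(x, dtype=float)
    n = x.size
    s = x.std(ddof=1)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    sigma = min(s, iqr / 1.349) if iqr > 0 else s
    if sigma == 0:
        raise DegenerateGradientError("habitat values are (nearly) constant")
    return 0.9 * sigma * n ** (-0.2)


def _profile_arrays(
    x_vals: np.ndarray,
    w_vals: np.ndarray,
    n_cells: int,
    bandwidth: float,
    x_grid: np.ndarray,
    support_frac: float,
):
    """Core Nadaraya-Watson profile on explicit arrays; returns (p_x, p_e, sup)."""
    K = np.exp(-0.5 * ((x_grid[:, None] - x_vals[None, :]) / bandwidth) ** 2)
    K /= bandwidth * _SQRT2PI
    p_x = K.sum(axis=1) / n_cells
    num = K @ w_vals
    supported = p_x >= support_frac * p_x.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        p_e = np.where(supported, num / p_x, 0.0)
    return p_x, np.clip(p_e, 0.0, None), supported


def conditional_profile(
    overlay: DensityOverlay,
    habitat: HabitatRaster,
    n_x: int = 100,
    bandwidth: Optional[float] = None,
    support_frac: float = 0.01,
) -> ConditionalCurve:
    """Estimate p(x) and p(E|x) along the habitat gradient.

    Over the N unmasked cells with habitat values x_i and bird probability
    mass w_i (sum w_i = 1):

        p(x)   = (1/N) sum_i K_b(x - x_i)
        p(E|x) = sum_i w_i K_b(x - x_i) / p(x)        (Nadaraya-Watson)

    with a Gaussian kernel and, by default, Silverman's bandwidth on the
    x_i. The curve is evaluated at ``n_x`` evenly spaced points spanning the
    observed habitat range; points with p(x) below ``support_frac`` of its
    maximum are flagged unsupported.
    """
    if overlay.geometry != habitat.geometry:
        raise GeometryError("overlay and habitat grids differ")
    free = ~(habitat.mask | overlay.mask)
    x_vals = habitat.values[free]
    if np.unique(x_vals).size < 2:
        raise DegenerateGradientError("habitat has < 2 distinct values")
    w_vals = (overlay.density * overlay.geometry.cell_area)[free]
    b = float(bandwidth) if bandwidth is not None else silverman_bandwidth(x_vals)
    x_grid = np.linspace(x_vals.min(), x_vals.max(), n_x)
    p_x, p_e, sup = _profile_arrays(
        x_vals, w_vals, x_vals.size, b, x_grid, support_frac
    )
    return ConditionalCurve(x_grid, p_x, p_e, sup, b)


def adjusted_sd(curve: ConditionalCurve) -> float:
    """Adjusted SD: spread of the habitat gradient under conditional use.

    The p(E|x)-weighted standard deviation of x over the supported gradient
    points. p(E|x) is use per unit of availability, so the weighting is
    already adjusted for how abundant each habitat value is; a specialist
    whose conditional use peaks on a narrow band of x yields a small value.
    """
    sup = curve.supported
    if sup.sum() < 3:
        raise DegenerateGradientError(
            "fewer than 3 supported gradient points; statistic undefined"
        )
    w = curve.p_e_given_x[sup]
    x = curve.x_grid[sup]
    if w.sum() <= 0:
        raise DegenerateGradientError("p(E|x) is zero on all supported points")
    m = float(np.average(x, weights=w))
    return float(np.sqrt(np.average((x - m) ** 2, weights=w)))


# ---------------------------------------------------------------------------
# torus variants
# ---------------------------------------------------------------------------

def _base_maps(values: np.ndarray) -> list[np.ndarray]:
    """Original, 180-degree rotation, mirror (horizontal axis), mirror+rotation."""
    return [values, values[::-1, ::-1], values[::-1, :], values[:, ::-1]]


def n_torus_variants(geometry: PlotGeometry, step: float) -> int:
    nx = int(round(geometry.length_x / step))
    ny = int(round(geometry.length_y / step))
    return 4 * nx * ny


def torus_variants(habitat: HabitatRaster, step: float) -> Iterator[HabitatRaster]:
    """Yield every torus variant of the habitat map.

    For each of the 4 base maps and every cyclic translation in ``step``
    increments (which must equal the cell size), yields the wrapped raster;
    the identity variant (original base, zero shift) comes first and appears
    exactly once. Total: ``4 * nx * ny`` variants.
    """
    g = habitat.geometry
    if abs(step - g.cell_size) > 1e-9:
        raise ConfigurationError(
            f"torus step {step} must equal the raster cell size {g.cell_size}; "
            "resample the raster first"
        )
    for base in _base_maps(habitat.values):
        for dy in range(g.ny):
            for dx in range(g.nx):
                yield HabitatRaster(
                    g,
                    np.roll(base, shift=(dy, dx), axis=(0, 1)),
                    variable_name=habitat.variable_name,
                    mask=habitat.mask,
                )


# ---------------------------------------------------------------------------
# null distributions
# ---------------------------------------------------------------------------

def _null_sds_direct(
    overlay: DensityOverlay,
    habitat: HabitatRaster,
    bandwidth: float,
    x_grid: np.ndarray,
    support_frac: float,
    step: float,
) -> np.ndarray:
    """Reference implementation: loop over materialized variants."""
    free = ~(habitat.mask | overlay.mask)
    w_vals = (overlay.density * overlay.geometry.cell_area)[free]
    n_cells = int(free.sum())
    out = []
    for var in torus_variants(habitat, step):
        x_vals = var.values[free]
        p_x, p_e, sup = _profile_arrays(
            x_vals, w_vals, n_cells, bandwidth, x_grid, support_frac
        )
        if sup.sum() < 3 or p_e[sup].sum() <= 0:
            out.append(np.nan)
            continue
        w = p_e[sup]
        x = x_grid[sup]
        m = np.average(x, weights=w)
        out.append(float(np.sqrt(np.average((x - m) ** 2, weights=w))))
    return np.array(out)


def _null_sds_fft(
    overlay: DensityOverlay,
    habitat: HabitatRaster,
    bandwidth: float,
    x_grid: np.ndarray,
    support_frac: float,
) -> np.ndarray:
    """All-variant statistics via circular cross-correlation.

    For a variant shifted by d, the Nadaraya-Watson numerator at gradient
    point x_k is sum_c w(c) * G_k(c - d) with G_k(c) = K_b(x_k - base(c)),
    a circular cross-correlation over the grid — one FFT product per
    (base map, gradient point) instead of one profile per variant. The
    denominator p(x) is the same correlation with the unmasked-cell
    indicator, so exclusion masks are handled identically for the observed
    and every null variant.
    """
    g = habitat.geometry
    free = ~(habitat.mask | overlay.mask)
    n_cells = int(free.sum())
    w2d = overlay.density * g.cell_area
    w2d = np.where(free, w2d, 0.0)
    m2d = free.astype(float) / n_cells
    Fw = np.fft.rfft2(w2d)
    Fm = np.fft.rfft2(m2d)
    shape = w2d.shape
    inv_b = 1.0 / bandwidth
    null_sds = np.empty(4 * g.ny * g.nx)
    for bi, base in enumerate(_base_maps(habitat.values)):
        # kernel evaluations per gradient point: (n_x, ny, nx)
        G = np.exp(-0.5 * ((x_grid[:, None, None] - base[None]) * inv_b) ** 2)
        G *= inv_b / _SQRT2PI
        FG = np.fft.rfft2(G, axes=(-2, -1))
        num = np.fft.irfft2(np.conj(FG) * Fw[None], s=shape, axes=(-2, -1))
        den = np.fft.irfft2(np.conj(FG) * Fm[None], s=shape, axes=(-2, -1))
        num = np.clip(num, 0.0, None)
        den = np.clip(den, 0.0, None)
        sup = den >= support_frac * den.max(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(sup, num / np.maximum(den, 1e-300), 0.0)
            sw = ratio.sum(axis=0)
            xg = x_grid[:, None, None]
            m1 = (ratio * xg).sum(axis=0) / sw
            var = (ratio * (xg - m1[None]) ** 2).sum(axis=0) / sw
        sd = np.sqrt(np.clip(var, 0.0, None))
        bad = (sup.sum(axis=0) < 3) | (sw <= 0) | ~np.isfinite(sd)
        sd[bad] = np.nan
        null_sds[bi * g.ny * g.nx:(bi + 1) * g.ny * g.nx] = sd.ravel()
    return null_sds


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------

def association_sign(
    curve: ConditionalCurve, habitat: HabitatRaster, overlay: DensityOverlay
) -> str:
    """'positive' when birds sit on above-average habitat values, else 'negative'.

    Compares the overlay-weighted mean habitat value with the unweighted
    mean over unmasked cells; an exact tie raises IndeterminateSignError.
    """
    free = ~(habitat.mask | overlay.mask)
    x = habitat.values[free]
    w = (overlay.density * overlay.geometry.cell_area)[free]
    weighted = float(np.sum(w * x) / np.sum(w))
    area_mean = float(x.mean())
    if weighted == area_mean:
        raise IndeterminateSignError(
            "overlay-weighted mean habitat value exactly equals the plot mean"
        )
    return "positive" if weighted > area_mean else "negative"


def torus_test(
    overlay: DensityOverlay,
    habitat: HabitatRaster,
    config: Optional[RunConfig] = None,
    n_x: int = 100,
    support_frac: float = 0.01,
    method: str = "fft",
    keep_null: bool = False,
) -> AssociationResult:
    """Run the Adjusted-SD / torus-shift test for one habitat variable.

    The observed adjusted SD is compared against the statistic recomputed on
    every torus variant (overlay held fixed; smoothing bandwidth and gradient
    grid fixed at their observed-map values for comparability). The quantile
    is the fraction of valid null statistics <= the observed one; the result
    is significant when the quantile falls in the lower
    ``config.significance_level`` tail, and only then is a sign assigned.
    ``method`` selects the FFT fast path (default) or the direct per-variant
    loop (reference implementation; identical results).
    """
    config = config if config is not None else RunConfig()
    g = habitat.geometry
    if abs(config.torus_step - g.cell_size) > 1e-9:
        raise ConfigurationError(
            f"torus_step {config.torus_step} must equal cell_size {g.cell_size}"
        )
    curve = conditional_profile(overlay, habitat, n_x=n_x, support_frac=support_frac)
    observed = adjusted_sd(curve)
    if method == "fft":
        null_sds = _null_sds_fft(
            overlay, habitat, curve.bandwidth, curve.x_grid, support_frac
        )
    elif method == "direct":
        null_sds = _null_sds_direct(
            overlay, habitat, curve.bandwidth, curve.x_grid, support_frac,
            config.torus_step,
        )
    else:
        raise ValueError("method must be 'fft' or 'direct'")
    # the identity variant is the observed statistic by construction; pin it
    # to cancel FFT round-off
    null_sds[0] = observed
    n_variants = null_sds.size
    valid = np.isfinite(null_sds)
    n_valid = int(valid.sum())
    if n_valid < n_variants:
        log.info("torus_test[%s]: %d of %d variants had undefined profiles",
                 habitat.variable_name, n_variants - n_valid, n_variants)
    tol = 1e-12 * max(1.0, abs(observed))
    quantile = float((null_sds[valid] <= observed + tol).sum() / n_valid)
    significant = quantile <= config.significance_level
    sign = association_sign(curve, habitat, overlay) if significant else "none"
    null = NullDistribution(observed, null_sds, n_variants) if keep_null else None
    return AssociationResult(
        variable_name=habitat.variable_name,
        observed_sd=observed,
        quantile=quantile,
        significant=bool(significant),
        sign=sign,
        n_variants=n_variants,
        n_valid=n_valid,
        null=null,
    )


class TorusShiftTest(BaseEstimator):
    """Estimator-style wrapper around :func:`torus_test`.

    Parameters mirror the function; after :meth:`fit` the result lives in
    ``result_`` with convenience attributes ``observed_sd_``, ``quantile_``,
    ``significant_`` and ``sign_``.
    """

    def __init__(self, significance_level=0.05, n_x=100, support_frac=0.01,
                 method="fft"):
        self.significance_level = significance_level
        self.n_x = n_x
        self.support_frac = support_frac
        self.method = method

    def fit(self, habitat: HabitatRaster, overlay: DensityOverlay):
        config = RunConfig(
            significance_level=self.significance_level,
            torus_step=habitat.geometry.cell_size,
        )
        self.result_ = torus_test(
            overlay, habitat, config, n_x=self.n_x,
            support_frac=self.support_frac, method=self.method,
        )
        self.observed_sd_ = self.result_.observed_sd
        self.quantile_ = self.result_.quantile
        self.significant_ = self.result_.significant
        self.sign_ = self.result_.sign
        return self
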