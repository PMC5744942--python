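"""Synthetic marsh plots: autocorrelated habitat surfaces and territorial birds.

The generator states a small, explicit world standing in for field data:

* habitat variables are stationary Gaussian random fields on the plot's cell
  centres, with the covariance implied by a spherical variogram, simulated
  exactly by Cholesky factorization (plots are desk-scale, <= ~10,000 cells);
* quadrat sampling copies the field design — 1 m2 measurements at the
  intersections of a coarse square grid (35 m in the study this emulates);
* birds are socially monogamous territorial pairs: territory centres placed
  by sequential inhibition, both pair members sharing a centre, relocations
  scattered bivariate-normally around it;
* habitat preference/avoidance is planted by *thinning*: candidate points
  are accepted with probability proportional to exp(beta * z) where z is the
  standardized habitat value, so beta = 0 is an exact null and territoriality
  (the spatial autocorrelation the torus null must respect) stays separate
  from the association signal under test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import yaml

from .errors import SimulationError
from .geometry import PlotGeometry
from .io import QuadratTable, RelocationSet, write_quadrats, write_relocations
from .kriging import SphericalModel
from .rasters import HabitatRaster

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HabitatFieldSpec:
    """One simulated habitat variable: a variogram, a mean, and a transform.

    ``transform="clip"`` clips the Gaussian field at zero, for variables
    that are physically nonnegative (heights, densities, covers).
    """

    variable_name: str = "habitat"
    variogram: SphericalModel = field(
        default_factory=lambda: SphericalModel(nugget=0.05, partial_sill=1.0,
                                               range_m=60.0)
    )
    mean: float = 0.0
    transform: str = "none"

    def __post_init__(self):
        if self.transform not in ("none", "clip"):
            raise ValueError("transform must be 'none' or 'clip'")


@dataclass(frozen=True)
class TerritorySpec:
    """Territorial-pair layout and the planted association strength."""

    n_pairs: int = 4
    dispersion_m: float = 15.0
    n_relocations_per_bird: int = 30
    preference_beta: float = 0.0

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.dispersion_m <= 0:
            raise ValueError("dispersion_m must be positive")
        if self.n_relocations_per_bird < 1:
            raise ValueError("n_relocations_per_bird must be >= 1")


# ---------------------------------------------------------------------------
# Gaussian random field
# ---------------------------------------------------------------------------

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


@lru_cache(maxsize=4)
def _grf_cholesky(geom_key: tuple, model_key: tuple) -> tuple:
    """Lower Cholesky factor of the spherical-model covariance on cell centres.

    Cached because repeated simulation on one geometry/model (calibration
    studies) re-uses the factor; only the Gaussian draw changes per seed.
    """
    length_x, length_y, origin_x, origin_y, cell = geom_key
    geometry = PlotGeometry(length_x, length_y, origin_x, origin_y, cell)
    model = SphericalModel(*model_key)
    xy = geometry.centres_flat()
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    cov = model.covariance(dist)
    for jitter in _JITTERS:
        try:
            L = np.linalg.cholesky(cov + jitter * np.eye(len(cov)))
            if jitter:
                log.info("GRF covariance needed diagonal jitter %g", jitter)
            return L, jitter
        except np.linalg.LinAlgError:
            continue
    raise SimulationError(
        f"covariance matrix not positive semi-definite even with jitter "
        f"{_JITTERS[-1]:g}"
    )


def simulate_habitat(
    geometry: PlotGeometry, spec: HabitatFieldSpec, seed: int
) -> HabitatRaster:
    """Simulate one habitat raster as a Gaussian random field.

    Deterministic given ``seed``. A zero-variance model (nugget and partial
    sill both 0) yields the constant raster equal to the mean.
    """
    if geometry.nx < 2 or geometry.ny < 2:
        raise SimulationError("grid must be at least 2x2 cells")
    m = spec.variogram
    shape = (geometry.ny, geometry.nx)
    if m.partial_sill == 0 and m.nugget == 0:
        values = np.full(shape, float(spec.mean))
    else:
        geom_key = (geometry.length_x, geometry.length_y,
                    geometry.origin_x, geometry.origin_y, geometry.cell_size)
        model_key = (m.nugget, m.partial_sill, m.range_m)
        L, _ = _grf_cholesky(geom_key, model_key)
        rng = np.random.default_rng(seed)
        z = L @ rng.standard_normal(geometry.n_cells)
        values = (spec.mean + z).reshape(shape)
    if spec.transform == "clip":
        values = np.clip(values, 0.0, None)
    return HabitatRaster(
        geometry, values, variable_name=spec.variable_name,
        mask=geometry.exclusion_mask(),
    )


# ---------------------------------------------------------------------------
# quadrat sampling
# ---------------------------------------------------------------------------

def sample_quadrats(
    raster: HabitatRaster, spacing: float, noise_sd: float, seed: int
) -> QuadratTable:
    """Sample the raster at square-grid intersections, plus measurement noise.

    One quadrat sits at every grid intersection spaced ``spacing`` metres
    apart, the first row/column on the plot origin; the measured value is the
    raster value at that point plus Gaussian noise.
    """
    g = raster.geometry
    if spacing < g.cell_size:
        raise ValueError("spacing must be >= cell_size")
    if spacing > max(g.length_x, g.length_y):
        raise ValueError("spacing larger than the plot; no quadrat grid fits")
    rng = np.random.default_rng(seed)
    xs = g.origin_x + spacing * np.arange(int(np.floor(g.length_x / spacing)) + 1)
    ys = g.origin_y + spacing * np.arange(int(np.floor(g.length_y / spacing)) + 1)
    xs = xs[xs < g.origin_x + g.length_x]
    ys = ys[ys < g.origin_y + g.length_y]
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    vals = raster.value_at(gx, gy)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    import pandas as pd
    df = pd.DataFrame({"x": gx, "y": gy, raster.variable_name or "habitat": vals})
    return QuadratTable(df)


# ---------------------------------------------------------------------------
# relocations
# ---------------------------------------------------------------------------

_MAX_CENTRE_ATTEMPTS = 10_000
_MAX_POINT_BATCHES = 10_000


def simulate_relocations(
    geometry: PlotGeometry,
    territories: TerritorySpec,
    habitat: HabitatRaster = None,
    seed: int = 0,
) -> RelocationSet:
    """Simulate relocation points for territorial pairs.

    Territory centres are placed by sequential inhibition with minimum
    spacing ``2 * dispersion_m``; each bird's points are bivariate-normal
    draws around the shared centre, truncated to the open plot rectangle.
    With ``preference_beta != 0`` both territory-centre candidates and
    relocation candidates are thinned with acceptance probability
    proportional to exp(beta * z), z the habitat value standardized over the
    raster: habitat selection acts where real selection does — first at
    territory establishment, then in within-territory use.
    """
    beta = territories.preference_beta
    if beta != 0 and habitat is None:
        raise ValueError("preference_beta != 0 requires a habitat raster")
    rng = np.random.default_rng(seed)
    disp = territories.dispersion_m
    min_gap = 2.0 * disp

    if beta != 0:
        vals = habitat.values[~habitat.mask]
        mu, sd = float(vals.mean()), float(vals.std())
        if sd == 0:
            raise SimulationError("habitat raster is constant; cannot standardize")
        z_grid = (habitat.values - mu) / sd
        # normalize acceptance so its maximum over unmasked cells is 1
        log_pmax = float((beta * z_grid[~habitat.mask]).max())

    centres = []
    for _ in range(_MAX_CENTRE_ATTEMPTS):
        if len(centres) == territories.n_pairs:
            break
        cand = np.array([
            rng.uniform(geometry.origin_x, geometry.origin_x + geometry.length_x),
            rng.uniform(geometry.origin_y, geometry.origin_y + geometry.length_y),
        ])
        if any(np.hypot(*(cand - c)) < min_gap for c in centres):
            continue
        if beta != 0:
            iy, ix = geometry.cell_of(cand[0], cand[1])
            if habitat.mask[iy, ix]:
                continue
            if rng.random() >= np.exp(beta * z_grid[iy, ix] - log_pmax):
                continue
        centres.append(cand)
    if len(centres) < territories.n_pairs:
        raise SimulationError(
            f"could not place {territories.n_pairs} territory centres with "
            f"spacing {min_gap:g} m in {_MAX_CENTRE_ATTEMPTS} attempts; "
            "reduce n_pairs or dispersion_m"
        )

    rows = []
    k = territories.n_relocations_per_bird
    for p, centre in enumerate(centres, start=1):
        for sex in ("F", "M"):
            bird = f"pair{p:02d}{sex}"
            pts: list = []
            batches = 0
            while len(pts) < k:
                batches += 1
                if batches > _MAX_POINT_BATCHES:
                    raise SimulationError(
                        f"could not draw {k} accepted points for {bird}; "
                        "preference thinning too severe"
                    )
                cand = rng.normal(loc=centre, scale=disp, size=(4 * k, 2))
                inside = geometry.contains(cand[:, 0], cand[:, 1], strict=True)
                cand = cand[inside]
                if beta != 0 and len(cand):
                    iy, ix = geometry.cell_of(cand[:, 0], cand[:, 1])
                    ok = ~habitat.mask[iy, ix]
                    cand = cand[ok]
                    iy, ix = iy[ok], ix[ok]
                    accept = rng.random(len(cand)) < np.exp(
                        beta * z_grid[iy, ix] - log_pmax
                    )
                    cand = cand[accept]
                pts.extend(map(tuple, cand[: k - len(pts)]))
            for x, y in pts:
                rows.append((bird, x, y, sex))
    import pandas as pd
    df = pd.DataFrame(rows, columns=["id", "x", "y", "sex"])
    return RelocationSet(df)


# ---------------------------------------------------------------------------
# whole-plot simulation
# ---------------------------------------------------------------------------

def simulate_plot(
    geometry: PlotGeometry,
    habitat_spec: HabitatFieldSpec,
    territory_spec: TerritorySpec,
    seed: int,
    quadrat_spacing: float = 35.0,
    quadrat_noise_sd: float = 0.1,
    outdir=None,
):
    """Simulate one plot end to end; optionally write the io_cli file set.

    Returns ``(habitat, relocations, quadrats, truth)`` where ``truth`` is
    the dict written to truth.yaml (all generative parameters and derived
    seeds, for parameter-recovery tests).
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)
    habitat = simulate_habitat(geometry, habitat_spec, int(sub[0]))
    quadrats = sample_quadrats(habitat, quadrat_spacing, quadrat_noise_sd, int(sub[1]))
    relocations = simulate_relocations(geometry, territory_spec, habitat, int(sub[2]))
    truth = {
        "seed": int(seed),
        "sub_seeds": {"habitat": int(sub[0]), "quadrats": int(sub[1]),
                      "relocations": int(sub[2])},
        "geometry": {
            "length_x": geometry.length_x, "length_y": geometry.length_y,
            "origin_x": geometry.origin_x, "origin_y": geometry.origin_y,
            "cell_size": geometry.cell_size,
        },
        "habitat": {
            "variable_name": habitat_spec.variable_name,
            "mean": habitat_spec.mean,
            "transform": habitat_spec.transform,
            "nugget": habitat_spec.variogram.nugget,
            "partial_sill": habitat_spec.variogram.partial_sill,
            "range_m": habitat_spec.variogram.range_m,
        },
        "territories": {
            "n_pairs": territory_spec.n_pairs,
            "dispersion_m": territory_spec.dispersion_m,
            "n_relocations_per_bird": territory_spec.n_relocations_per_bird,
            "preference_beta": territory_spec.preference_beta,
        },
        "quadrats": {"spacing": quadrat_spacing, "noise_sd": quadrat_noise_sd},
    }
    if outdir is not None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_relocations(relocations, outdir / "relocations.csv")
        write_quadrats(quadrats, outdir / "quadrats.csv")
        with open(outdir / "truth.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(truth, fh, sort_keys=True)
    return habitat, relocations, quadrats, truth
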