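"""End-to-end glue: relocations -> UDs -> overlay -> torus test.

These helpers chain the module-level operations exactly the way the CLI
does, and are what the calibration/power studies drive.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Optional

import numpy as np

from .errors import ConvergenceError
from .geometry import PlotGeometry, RunConfig
from .homerange import (
    filter_individuals,
    isopleth_region,
    kernel_ud,
    lscv_bandwidth,
    mcp,
    reference_bandwidth,
)
from .io import RelocationSet
from .rasters import DensityOverlay, HabitatRaster, UDSurface
from .synthetic import (
    HabitatFieldSpec,
    TerritorySpec,
    simulate_habitat,
    simulate_relocations,
)
from .torus import AssociationResult, pooled_density, torus_test

log = logging.getLogger(__name__)


def ud_for_individual(
    points: np.ndarray,
    geometry: PlotGeometry,
    bandwidth: Optional[float] = None,
) -> UDSurface:
    """Kernel UD on a lattice-aligned expansion of the plot grid.

    Bandwidth defaults to LSCV, falling back to the bivariate-normal
    reference bandwidth when LSCV has no interior minimum (logged) — the
    pipeline must produce a UD for every retained bird.
    """
    pts = np.asarray(points, dtype=float)
    if bandwidth is None:
        try:
            bandwidth = lscv_bandwidth(pts)
        except ConvergenceError:
            bandwidth = reference_bandwidth(pts)
            log.warning(
                "LSCV failed to converge; using reference bandwidth %.3g m",
                bandwidth,
            )
    grid = geometry.expanded_to_cover(pts, margin=3.0 * bandwidth)
    return kernel_ud(pts, bandwidth, grid)


def homerange_table(relocations: RelocationSet, config: RunConfig,
                    geometry: Optional[PlotGeometry] = None):
    """Per-individual home-range table plus the fitted regions.

    Returns ``(rows, regions)``: rows are dicts with id, n_relocations,
    kernel_ud_ha and mcp_ha; regions maps id -> kernel isopleth region (for
    overlap computations downstream).
    """
    retained = filter_individuals(relocations, config)
    if not retained.individuals:
        return [], {}, {}
    cell = geometry.cell_size if geometry is not None else config.torus_step
    base = geometry if geometry is not None else PlotGeometry(
        length_x=cell, length_y=cell,
        origin_x=np.floor(retained.df["x"].min() / cell) * cell,
        origin_y=np.floor(retained.df["y"].min() / cell) * cell,
        cell_size=cell,
    )
    # pick bandwidths first, then lay every UD on one shared grid so the
    # isopleth regions are overlap-comparable cell sets
    bands = {}
    for ind in retained.individuals:
        pts = retained.points(ind)
        try:
            bands[ind] = lscv_bandwidth(pts, individual=str(ind))
        except ConvergenceError:
            bands[ind] = reference_bandwidth(pts)
            log.warning("LSCV failed for %s; using reference bandwidth", ind)
    common = base.expanded_to_cover(
        retained.all_points(), margin=3.0 * max(bands.values())
    )
    rows, regions, uds = [], {}, {}
    for ind in retained.individuals:
        pts = retained.points(ind)
        ud = kernel_ud(pts, bands[ind], common)
        region = isopleth_region(ud, config.kernel_level)
        poly = mcp(pts, config.kernel_level)
        rows.append({
            "id": ind,
            "n_relocations": len(pts),
            "kernel_ud_ha": region.area_ha,
            "mcp_ha": poly.area_ha,
        })
        regions[ind] = region
        uds[ind] = ud
    return rows, regions, uds


def overlay_from_relocations(
    relocations: RelocationSet,
    geometry: PlotGeometry,
    config: RunConfig,
) -> DensityOverlay:
    """Pooled utilization overlay of all retained individuals on the plot."""
    retained = filter_individuals(relocations, config)
    uds = [
        ud_for_individual(retained.points(ind), geometry)
        for ind in retained.individuals
    ]
    return pooled_density(uds, geometry, mask=geometry.exclusion_mask())


def simulate_and_test(
    seed: int,
    beta: float = 0.0,
    plot_side: float = 250.0,
    habitat_spec: Optional[HabitatFieldSpec] = None,
    territory_spec: Optional[TerritorySpec] = None,
    config: Optional[RunConfig] = None,
    n_x: int = 100,
) -> AssociationResult:
    """One full synthetic experiment: plot, birds, UDs, torus test.

    With ``beta = 0`` habitat and bird density are independent by
    construction (the null); nonzero beta plants a monotone preference
    (beta > 0) or avoidance (beta < 0) of the habitat variable.
    """
    habitat_spec = habitat_spec if habitat_spec is not None else HabitatFieldSpec()
    territory_spec = (
        territory_spec if territory_spec is not None else TerritorySpec()
    )
    territory_spec = replace(territory_spec, preference_beta=beta)
    config = config if config is not None else RunConfig(seed=seed)
    geometry = PlotGeometry(length_x=plot_side, length_y=plot_side,
                            cell_size=config.torus_step)
    rng = np.random.default_rng(seed)
    s_hab, s_rel = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    habitat = simulate_habitat(geometry, habitat_spec, s_hab)
    relocations = simulate_relocations(geometry, territory_spec, habitat, s_rel)
    overlay = overlay_from_relocations(relocations, geometry, config)
    return torus_test(overlay, habitat, config, n_x=n_x)
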