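"""The Adjusted-SD / torus-shift association test."""

import numpy as np
import pytest
from scipy.stats import kstest

import torusrange as tr
from torusrange import DegenerateGradientError, GeometryError, IndeterminateSignError
from torusrange.torus import (
    ConditionalCurve,
    _null_sds_direct,
    _null_sds_fft,
)


def _uniform_overlay(geom, mask=None):
    mask = np.zeros((geom.ny, geom.nx), bool) if mask is None else mask
    dens = np.where(~mask, 1.0, 0.0)
    dens /= dens.sum() * geom.cell_area
    return tr.DensityOverlay(geom, dens, mask=mask)


class TestPooledDensity:
    def test_single_ud_identity(self, small_geometry):
        ud = tr.kernel_ud([[30, 25]], 4.0, small_geometry)
        ov = tr.pooled_density([ud], small_geometry)
        np.testing.assert_allclose(ov.density, ud.density, rtol=1e-12)
        assert ov.mass() == pytest.approx(1.0, abs=1e-9)

    def test_two_disjoint_uds_contribute_half_each(self):
        geom = tr.PlotGeometry(200, 50, cell_size=5)
        a = tr.kernel_ud([[40, 25]], 4.0, geom)
        b = tr.kernel_ud([[160, 25]], 4.0, geom)
        ov = tr.pooled_density([a, b], geom)
        left = ov.density[:, :20].sum() * geom.cell_area
        assert left == pytest.approx(0.5, abs=1e-6)

    def test_masking_half_doubles_remaining_density(self, small_geometry):
        g = small_geometry
        dens = np.full((g.ny, g.nx), 1.0 / (g.n_cells * g.cell_area))
        ud = tr.UDSurface(g, dens, bandwidth_m=1.0)
        mask = np.zeros((g.ny, g.nx), bool)
        mask[:, : g.nx // 2] = True
        ov = tr.pooled_density([ud], g, mask=mask)
        np.testing.assert_allclose(ov.density[~mask], 2.0 * dens[~mask])

    def test_grid_mismatch_raises(self, small_geometry):
        other = tr.PlotGeometry(60, 50, cell_size=2.5)
        ud = tr.kernel_ud([[30, 25]], 4.0, other)
        with pytest.raises(GeometryError):
            tr.pooled_density([ud], small_geometry)


class TestConditionalProfile:
    def test_uniform_overlay_gives_flat_unit_profile(self, small_geometry):
        hab = tr.simulate_habitat(small_geometry, tr.HabitatFieldSpec(), seed=1)
        ov = _uniform_overlay(small_geometry)
        curve = tr.conditional_profile(ov, hab)
        np.testing.assert_allclose(curve.p_e_given_x[curve.supported], 1.0,
                                   rtol=1e-9)
        # p(x) integrates to ~1 over the gradient (trapezoid)
        assert np.trapezoid(curve.p_x, curve.x_grid) == pytest.approx(1.0, abs=0.05)

    def test_mass_on_high_half_matches_binned_oracle(self, small_geometry):
        hab = tr.simulate_habitat(small_geometry, tr.HabitatFieldSpec(), seed=2)
        med = np.median(hab.values)
        dens = np.where(hab.values > med, 1.0, 0.0)
        dens /= dens.sum() * small_geometry.cell_area
        ov = tr.DensityOverlay(small_geometry, dens)
        curve = tr.conditional_profile(ov, hab, n_x=200)
        lo = curve.supported & (curve.x_grid < med - 2 * curve.bandwidth)
        hi = curve.supported & (curve.x_grid > med + 2 * curve.bandwidth)
        assert curve.p_e_given_x[lo].max() < 0.2
        # discrete oracle on the high side: sum w / ((1/N) * count) per bin
        x = hab.values.ravel()
        w = (ov.density * small_geometry.cell_area).ravel()
        sel = x > med
        oracle_hi = w[sel].sum() / (sel.mean())
        assert curve.p_e_given_x[hi].mean() == pytest.approx(oracle_hi, rel=0.3)

    def test_constant_habitat_is_degenerate(self, small_geometry):
        hab = tr.HabitatRaster(small_geometry,
                               np.full((small_geometry.ny, small_geometry.nx), 3.0))
        with pytest.raises(DegenerateGradientError):
            tr.conditional_profile(_uniform_overlay(small_geometry), hab)


class TestAdjustedSD:
    def _curve(self, x, p_x, p_e, sup=None):
        x = np.asarray(x, float)
        sup = np.ones(len(x), bool) if sup is None else np.asarray(sup, bool)
        return ConditionalCurve(x, np.asarray(p_x, float), np.asarray(p_e, float),
                                sup, bandwidth=1.0)

    def test_hand_computed_spread(self):
        # equal use at x=0 and x=2, none at x=1: mean 1, SD 1
        c = self._curve([0, 1, 2], [1, 1, 1], [1, 0, 1])
        assert tr.adjusted_sd(c) == pytest.approx(1.0)

    def test_point_concentration_gives_zero(self):
        c = self._curve([0, 1, 2], [1, 1, 1], [0, 5, 0])
        assert tr.adjusted_sd(c) == pytest.approx(0.0)

    def test_unsupported_points_never_contribute(self):
        base = self._curve([0, 1, 2], [1, 1, 1], [1, 0, 1])
        padded = self._curve([0, 1, 2, 9, 10], [1, 1, 1, 0, 0],
                             [1, 0, 1, 7, 7], sup=[1, 1, 1, 0, 0])
        assert tr.adjusted_sd(padded) == tr.adjusted_sd(base)

    def test_too_few_supported_points(self):
        c = self._curve([0, 1, 2], [1, 1, 1], [1, 1, 1], sup=[1, 1, 0])
        with pytest.raises(DegenerateGradientError):
            tr.adjusted_sd(c)


class TestTorusVariants:
    def test_enumeration_count_small_grid(self):
        geom = tr.PlotGeometry(15, 10, cell_size=5)  # 3 x 2 cells
        hab = tr.HabitatRaster(geom, np.arange(6, dtype=float).reshape(2, 3))
        variants = list(tr.torus_variants(hab, 5.0))
        assert len(variants) == 24

    def test_value_multiset_conserved_and_identity_unique(self):
        geom = tr.PlotGeometry(20, 15, cell_size=5)
        vals = np.random.default_rng(0).normal(size=(3, 4))
        hab = tr.HabitatRaster(geom, vals)
        variants = list(tr.torus_variants(hab, 5.0))
        ref = np.sort(vals.ravel())
        identical = 0
        for v in variants:
            np.testing.assert_allclose(np.sort(v.values.ravel()), ref)
            identical += int(np.array_equal(v.values, vals))
        assert identical == 1
        np.testing.assert_array_equal(variants[0].values, vals)

    def test_step_must_match_cell_size(self, small_geometry):
        hab = tr.simulate_habitat(small_geometry, tr.HabitatFieldSpec(), seed=0)
        with pytest.raises(tr.ConfigurationError):
            next(tr.torus_variants(hab, 10.0))


class TestNullDistributionPaths:
    def test_fft_equals_direct_with_mask(self):
        rng = np.random.default_rng(1)
        geom = tr.PlotGeometry(60, 50, cell_size=5,
                               exclusion_polygons=[[(0, 0), (12, 0), (12, 11), (0, 11)]])
        hab = tr.simulate_habitat(
            geom, tr.HabitatFieldSpec(variogram=tr.SphericalModel(0.1, 1.0, 20.0)),
            seed=7,
        )
        w = rng.random((geom.ny, geom.nx))
        w[hab.mask] = 0
        ov = tr.DensityOverlay(geom, w / (w.sum() * geom.cell_area), mask=hab.mask)
        curve = tr.conditional_profile(ov, hab)
        direct = _null_sds_direct(ov, hab, curve.bandwidth, curve.x_grid, 0.01, 5.0)
        fft = _null_sds_fft(ov, hab, curve.bandwidth, curve.x_grid, 0.01)
        np.testing.assert_allclose(fft, direct, rtol=1e-8, atol=1e-12)


class TestTorusTest:
    def _setup(self, seed=3, beta=0.0, side=150.0):
        geom = tr.PlotGeometry(side, side, cell_size=5)
        hab = tr.simulate_habitat(geom, tr.HabitatFieldSpec(), seed)
        spec = tr.TerritorySpec(n_pairs=2, preference_beta=beta)
        rel = tr.simulate_relocations(geom, spec, hab if beta else None, seed + 1)
        cfg = tr.RunConfig(seed=seed)
        ov = tr.overlay_from_relocations(rel, geom, cfg)
        return ov, hab, cfg

    def test_deterministic_and_self_inclusive(self):
        ov, hab, cfg = self._setup()
        r1 = tr.torus_test(ov, hab, cfg)
        r2 = tr.torus_test(ov, hab, cfg)
        assert r1.observed_sd == r2.observed_sd
        assert r1.quantile == r2.quantile
        assert r1.quantile >= 1.0 / r1.n_variants
        assert r1.n_variants == tr.n_torus_variants(hab.geometry, cfg.torus_step)

    def test_habitat_rescaling_leaves_quantile_unchanged(self):
        ov, hab, cfg = self._setup(seed=9)
        r1 = tr.torus_test(ov, hab, cfg)
        hab2 = hab.with_values(2.0 * hab.values + 10.0)
        r2 = tr.torus_test(ov, hab2, cfg)
        assert r2.observed_sd == pytest.approx(2.0 * r1.observed_sd, rel=1e-9)
        assert r2.quantile == pytest.approx(r1.quantile, abs=1e-12)

    def test_estimator_wrapper_matches_function(self):
        ov, hab, cfg = self._setup(seed=5)
        est = tr.TorusShiftTest().fit(hab, ov)
        res = tr.torus_test(ov, hab, cfg)
        assert est.observed_sd_ == res.observed_sd
        assert est.quantile_ == res.quantile
        assert est.get_params()["significance_level"] == 0.05

    def test_monotone_response_to_planted_association(self):
        # stronger planted avoidance never weakens the median quantile shift
        med = []
        for beta in (0.0, -1.0, -2.0):
            qs = [tr.simulate_and_test(seed=s, beta=beta, plot_side=250.0).quantile
                  for s in range(25)]
            med.append(np.median(np.abs(np.array(qs) - 0.5)))
        assert med[0] <= med[1] + 0.05
        assert med[1] <= med[2] + 0.05

    def test_exact_calibration_under_torus_stationary_field(self):
        # machinery validity isolated from the planar-field approximation:
        # a field stationary ON THE TORUS makes the shift group exact, so
        # quantiles must be uniform (KS 95% bound at n=100 is ~0.136)
        geom = tr.PlotGeometry(150, 150, cell_size=5)
        model = tr.SphericalModel(0.05, 1.0, 60.0)
        xy = geom.centres_flat()
        dx = np.abs(xy[:, 0][:, None] - xy[:, 0][None])
        dy = np.abs(xy[:, 1][:, None] - xy[:, 1][None])
        d = np.hypot(np.minimum(dx, 150 - dx), np.minimum(dy, 150 - dy))
        L = np.linalg.cholesky(model.covariance(d) + 1e-8 * np.eye(len(d)))
        cfg = tr.RunConfig()
        qs = []
        for s in range(100):
            vals = (L @ np.random.default_rng(s).standard_normal(len(d)))
            hab = tr.HabitatRaster(geom, vals.reshape(geom.ny, geom.nx), "z")
            rel = tr.simulate_relocations(
                geom, tr.TerritorySpec(n_pairs=2), None, 10_000 + s
            )
            ov = tr.overlay_from_relocations(rel, geom, cfg)
            qs.append(tr.torus_test(ov, hab, cfg).quantile)
        qs = np.array(qs)
        assert kstest(qs, "uniform").statistic < 0.15
        assert (qs <= 0.05).mean() <= 0.11


class TestAssociationSign:
    def test_extremes_and_tie(self, small_geometry):
        hab = tr.simulate_habitat(small_geometry, tr.HabitatFieldSpec(), seed=4)
        top = np.where(hab.values >= np.quantile(hab.values, 0.9), 1.0, 0.0)
        bot = np.where(hab.values <= np.quantile(hab.values, 0.1), 1.0, 0.0)
        g = small_geometry
        ov_top = tr.DensityOverlay(g, top / (top.sum() * g.cell_area))
        ov_bot = tr.DensityOverlay(g, bot / (bot.sum() * g.cell_area))
        curve = tr.conditional_profile(ov_top, hab)
        assert tr.association_sign(curve, hab, ov_top) == "positive"
        assert tr.association_sign(curve, hab, ov_bot) == "negative"
        # exact tie on a hand-built symmetric raster
        tiny = tr.PlotGeometry(10, 10, cell_size=5)
        sym = tr.HabitatRaster(tiny, np.array([[0.0, 2.0], [2.0, 0.0]]))
        ov_uni = _uniform_overlay(tiny)
        with pytest.raises(IndeterminateSignError):
            tr.association_sign(curve, sym, ov_uni)
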