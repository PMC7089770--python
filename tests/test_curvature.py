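"""Contour/centerline curvature, masks, bending corrections, peaks."""

import numpy as np
import pytest

from rodspt import (CellSimConfig, boundary_peaks, build_boundary_profile,
                    centerline_curvature, contour_curvature,
                    correct_for_bending, enrichment_curve,
                    gaussian_curvature_proxy, generate_synthetic_cell,
                    noise_floor, pearson_colocalization, region_masks)
from rodspt.curvature import CellGeometry, pooled_enrichment_curve


def circle_geometry(radius, n=200):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    contour = radius * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    return CellGeometry(contour=contour,
                        centerline=np.zeros((5, 2)) + np.arange(5)[:, None],
                        widths=np.full(n, 1.0), side=np.ones(n, dtype=int),
                        arclength=np.zeros(n), pole_mask=np.zeros(n, bool))


class TestContourCurvature:
    @pytest.mark.parametrize("radius", [0.5, 2.0, 5.0])
    def test_circle_oracle(self, radius):
        """N-point circle returns +1/R everywhere within 1%."""
        c = contour_curvature(circle_geometry(radius, n=200))
        assert np.allclose(c, 1 / radius, rtol=0.01)

    def test_straight_cell_sidewall_zero(self, straight_cell):
        geometry, _ = straight_cell
        c = contour_curvature(geometry)
        profile = build_boundary_profile(geometry, np.ones(geometry.n_points))
        assert np.abs(c[profile.sidewall_mask]).max() < 1e-6

    def test_bent_cell_sidewall_matches_offset_formula(self, bent_cell):
        """Side walls carry -k/(1 - k w/2) inner and +k/(1 + k w/2) outer."""
        geometry, _ = bent_cell
        c = contour_curvature(geometry)
        profile = build_boundary_profile(geometry, np.ones(geometry.n_points))
        inner = profile.sidewall_mask & (geometry.side * geometry.kappa_true > 0)
        outer = profile.sidewall_mask & (geometry.side * geometry.kappa_true < 0)
        assert c[inner].mean() == pytest.approx(-0.2 / (1 - 0.1), rel=0.02)
        assert c[outer].mean() == pytest.approx(0.2 / (1 + 0.1), rel=0.02)


class TestCenterlineCurvature:
    def test_arc_of_known_radius(self):
        s = np.arange(0, 8, 0.032)
        r = 5.0
        pts = np.stack([r * np.sin(s / r), r * (1 - np.cos(s / r))], axis=1)
        kappa = centerline_curvature(pts)
        interior = slice(20, -20)
        assert np.allclose(np.abs(kappa[interior]), 0.2, rtol=0.02)

    def test_straight_zero(self):
        pts = np.stack([np.arange(0, 5, 0.032), np.zeros(157)], axis=1)
        assert np.abs(centerline_curvature(pts)).max() < 1e-9

    def test_generator_profile_recovered(self, bent_cell):
        geometry, _ = bent_cell
        kappa = centerline_curvature(geometry)
        interior = slice(30, -30)
        assert np.allclose(kappa[interior], 0.2, rtol=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            centerline_curvature(np.zeros((3, 2)))


class TestMasks:
    def test_stated_cuts_arithmetic(self, straight_cell):
        """10 um cell: side wall covers [2, 4.675] u [5.325, 8] um."""
        geometry, _ = straight_cell
        sidewall, _ = region_masks(geometry)
        arc = geometry.arclength[sidewall]
        assert arc.min() == pytest.approx(2.0, abs=0.05)
        assert arc.max() == pytest.approx(8.0, abs=0.05)
        gap = (arc > 4.7) & (arc < 5.3)
        assert not gap.any()
        covered = (arc > 4.6) & (arc < 4.68)
        assert covered.any()

    def test_straight_cell_straight_mask_equals_sidewall(self, straight_cell):
        geometry, _ = straight_cell
        sidewall, straight = region_masks(geometry)
        assert np.array_equal(sidewall, straight)

    def test_bent_cell_straight_mask_empty(self, bent_cell):
        geometry, _ = bent_cell
        sidewall, straight = region_masks(geometry)
        assert sidewall.any() and not straight.any()

    def test_mask_subset_invariant(self):
        cfg = CellSimConfig(length=12, width=1,
                            kappa=lambda s: 0.15 * np.sin(2 * np.pi * s / 12),
                            alpha=0.2, seed=3)
        geometry, _ = generate_synthetic_cell(cfg)
        sidewall, straight = region_masks(geometry)
        assert np.all(~straight | sidewall)          # straight subset of sidewall
        assert np.all(~sidewall | ~geometry.pole_mask)

    def test_short_cell_warns_empty(self):
        cfg = CellSimConfig(length=3.0, width=1.0, kappa=0.0, seed=4)
        geometry, _ = generate_synthetic_cell(cfg)
        with pytest.warns(UserWarning):
            sidewall, _ = region_masks(geometry)
        assert not sidewall.any()


class TestCorrections:
    def test_straight_cell_identity(self, straight_cell):
        geometry, intensity = straight_cell
        profile = build_boundary_profile(geometry, intensity)
        for mode in ("curvature", "intensity"):
            corr = correct_for_bending(profile, mode)
            assert np.allclose(corr.intensity, profile.intensity)
            if mode == "curvature":
                sel = profile.sidewall_mask
                assert np.allclose(corr.contour_curv[sel],
                                   profile.contour_curv[sel], atol=1e-9)

    def test_pure_bend_curvature_corrects_to_zero(self, bent_cell):
        geometry, intensity = bent_cell
        profile = build_boundary_profile(geometry, intensity,
                                         use_true_kappa=True)
        corr = correct_for_bending(profile, "curvature")
        sel = profile.sidewall_mask
        assert np.abs(corr.contour_curv[sel]).max() < 0.02

    def test_pure_bend_intensity_corrects_to_uniform(self, bent_cell):
        geometry, intensity = bent_cell
        profile = build_boundary_profile(geometry, intensity,
                                         use_true_kappa=True)
        corr = correct_for_bending(profile, "intensity", alpha=0.2)
        sel = profile.sidewall_mask
        assert corr.intensity[sel].std() < 1e-9

    def test_divergent_curvature_rejected(self):
        cfg = CellSimConfig(length=10, width=1, kappa=0.2, seed=5)
        geometry, intensity = generate_synthetic_cell(cfg)
        profile = build_boundary_profile(geometry, intensity)
        profile.centerline_curv[:] = 2.5   # |kappa| w / 2 > 1
        with pytest.raises(ValueError):
            correct_for_bending(profile, "curvature")


class TestEnrichment:
    def test_uniform_intensity_flat_at_one(self, straight_cell):
        geometry, intensity = straight_cell
        profile = build_boundary_profile(geometry, intensity)
        curve = enrichment_curve(profile, profile.sidewall_mask)
        assert np.allclose(curve.mean_intensity, 1.0)
        anchor_bin = curve.mean_intensity[np.argmin(np.abs(curve.centers))]
        assert anchor_bin == pytest.approx(1.0, abs=1e-12)

    def test_bent_cell_negative_slope(self, bent_cell):
        """Coupling enriches the concave (negative-c) face."""
        geometry, intensity = bent_cell
        profile = build_boundary_profile(geometry, intensity)
        with pytest.warns(UserWarning):
            curve = enrichment_curve(profile, profile.sidewall_mask)
        assert curve.slope() < 0

    def test_min_frac_drops_sparse_bins(self, straight_cell):
        geometry, intensity = straight_cell
        profile = build_boundary_profile(geometry, intensity)
        profile.contour_curv[0] = 5.0   # lone outlier bin
        curve = enrichment_curve(profile, None, min_frac=0.01)
        assert 5.0 not in np.round(curve.centers, 6)


class TestGaussianProxy:
    def test_formula(self):
        assert gaussian_curvature_proxy(0.1, 1.0) == pytest.approx(0.2)
        assert gaussian_curvature_proxy(0.0, 1.0) == 0.0
        with pytest.raises(ValueError):
            gaussian_curvature_proxy(0.1, 0.0)

    def test_straight_cylinder_near_zero(self, straight_cell):
        geometry, _ = straight_cell
        c = contour_curvature(geometry)
        profile = build_boundary_profile(geometry, np.ones(geometry.n_points))
        g = gaussian_curvature_proxy(c[profile.sidewall_mask], 1.0)
        assert np.abs(g).max() < 1e-5


class TestPeaksAndNoise:
    def test_flat_profile_no_peaks(self):
        peaks, density = boundary_peaks(np.full(300, 2.0), noise_sigma=0.1,
                                        contour_length=10.0)
        assert len(peaks) == 0 and density == 0.0

    def test_rendered_peaks_density(self):
        """5 clear peaks on a 10 um contour give density 0.5 per um."""
        x = np.arange(400, dtype=float)
        prof = np.zeros(400)
        for c in (40, 120, 200, 280, 360):
            prof += 5.0 * np.exp(-0.5 * ((x - c) / 3) ** 2)
        peaks, density = boundary_peaks(prof, noise_sigma=0.1,
                                        contour_length=10.0)
        assert len(peaks) == 5
        assert density == pytest.approx(0.5)

    def test_subthreshold_peaks_excluded(self):
        x = np.arange(200, dtype=float)
        prof = 1.0 * np.exp(-0.5 * ((x - 100) / 3) ** 2)
        peaks, _ = boundary_peaks(prof, noise_sigma=1.0, noise_factor=3.0)
        assert len(peaks) == 0

    def test_noise_floor_scales_linearly(self):
        rng = np.random.default_rng(11)
        base = rng.normal(0, 1.0, (128, 128))
        lo = noise_floor(10.0 + 2.0 * base)
        hi = noise_floor(10.0 + 4.0 * base)
        assert hi / lo == pytest.approx(2.0, rel=0.1)
        assert noise_floor(np.full((64, 64), 3.0)) == pytest.approx(0.0, abs=1e-12)


class TestColocalization:
    def test_identity_and_independence(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 400)
        assert pearson_colocalization(a, a) == pytest.approx(1.0)
        b = rng.normal(0, 1, 400)
        assert abs(pearson_colocalization(a, b)) < 0.15

    def test_shift_reduces_correlation_as_autocorrelation(self):
        """Correlation of a shifted copy equals the profile autocorrelation."""
        from scipy import ndimage
        rng = np.random.default_rng(13)
        a = ndimage.gaussian_filter1d(rng.normal(0, 1, 200), 4, mode="wrap")
        shifted = np.roll(a, 10)
        r = pearson_colocalization(a, shifted)
        am = a - a.mean()
        expected = (am * np.roll(am, 10)).sum() / (am * am).sum()
        assert r == pytest.approx(expected, abs=1e-9)
        assert r < 0.99

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_colocalization(np.ones(50), np.arange(50.0))


class TestSlopeReductionConcordance:
    def test_three_corrections_concordant(self):
        """Straight-mask, curvature- and intensity-correction all flatten
        the curvature-intensity relation of bending-only cells by >= 90%."""
        from conftest import mixed_bend_cells
        cells = mixed_bend_cells(seed=200, noise=0.02)
        profiles = [build_boundary_profile(g, i) for g, i in cells]
        raw = pooled_enrichment_curve(
            [(p, p.sidewall_mask) for p in profiles]).slope()
        straight = pooled_enrichment_curve(
            [(p, p.straight_mask) for p in profiles]).slope()
        curv = pooled_enrichment_curve(
            [(correct_for_bending(p, "curvature"), p.sidewall_mask)
             for p in profiles]).slope()
        inten = pooled_enrichment_curve(
            [(correct_for_bending(p, "intensity"), p.sidewall_mask)
             for p in profiles]).slope()
        assert abs(raw) > 0.01
        for corrected in (straight, curv, inten):
            assert abs(corrected) <= 0.1 * abs(raw)
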