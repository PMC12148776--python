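"""ROI statistics, CNR, nonuniformity, and energy optimization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from decbct.materials import theoretical_hu
from decbct.metrics import (ROI, cnr, nonuniformity, optimize_cnr,
                            optimize_contrast_min, preset_uniformity_rois,
                            roi_stats, uniformity_check)
from decbct.recon import ImageGrid


@pytest.fixture(scope="module")
def grid():
    return ImageGrid(n_x=128, n_y=128, voxel_size=2.0)


class TestROIStats:
    def test_constant_image(self, grid):
        img = np.full((128, 128), 7.0)
        s = roi_stats(img, ROI.circle((0, 0), 20), grid)
        assert s.mean == 7.0 and s.sd == 0.0 and s.snr is None

    def test_two_value_arithmetic(self, grid):
        img = np.zeros((128, 128))
        img[:, 64:] = 10.0
        s = roi_stats(img, ROI.polygon([(-40, -40), (40, -40), (40, 40),
                                        (-40, 40)]), grid)
        assert s.mean == pytest.approx(5.0)
        assert s.sd == pytest.approx(5.0)
        assert s.snr == pytest.approx(1.0)

    def test_noise_sd_recovered_on_flat_field(self, grid):
        img = np.random.default_rng(7).normal(0.0, 2.5, size=(128, 128))
        s = roi_stats(img, ROI.circle((0, 0), 100), grid)
        assert abs(s.sd - 2.5) / 2.5 < 0.05

    def test_empty_mask_rejected(self, grid):
        tiny = ROI.circle((500.0, 500.0), 1.0)  # off-grid
        with pytest.raises(ValueError):
            roi_stats(np.zeros((128, 128)), tiny, grid)

    @given(st.floats(-50, 50))
    def test_mean_shifts_with_constant_offset(self, offset):
        grid = ImageGrid(32, 32, 1.0)
        img = np.arange(32 * 32, dtype=float).reshape(32, 32)
        base = roi_stats(img, ROI.circle((0, 0), 10), grid)
        shifted = roi_stats(img + offset, ROI.circle((0, 0), 10), grid)
        assert shifted.mean == pytest.approx(base.mean + offset, abs=1e-9)
        assert shifted.sd == pytest.approx(base.sd, abs=1e-9)


class TestCNR:
    def test_matches_direct_formula(self, grid, rng):
        img = rng.normal(0.0, 10.0, size=(128, 128))
        left = ROI.circle((-60, 0), 20)
        right = ROI.circle((60, 0), 20)
        img[left.mask(grid)] += 100.0
        a = img[left.mask(grid)]
        b = img[right.mask(grid)]
        expected = abs(a.mean() - b.mean()) / np.sqrt(
            0.5 * (a.std() ** 2 + b.std() ** 2))
        assert cnr(img, left, right, grid) == pytest.approx(expected,
                                                            rel=1e-12)
        # scalar sanity: means 100 vs 0 with sigma 10 on both sides -> ~10
        assert cnr(img, left, right, grid) == pytest.approx(10.0, rel=0.1)

    def test_identical_rois_give_zero(self, grid, rng):
        img = rng.normal(size=(128, 128))
        roi = ROI.circle((0, 0), 30)
        assert cnr(img, roi, roi, grid) == pytest.approx(0.0)

    def test_symmetric_in_roi_order(self, grid, rng):
        img = rng.normal(size=(128, 128)) + np.linspace(0, 5, 128)
        a, b = ROI.circle((-50, 0), 20), ROI.circle((50, 0), 20)
        assert cnr(img, a, b, grid) == pytest.approx(cnr(img, b, a, grid))

    def test_scale_invariant(self, grid, rng):
        img = rng.normal(5.0, 1.0, size=(128, 128))
        img[:, :64] += 3.0
        a, b = ROI.circle((-50, 0), 20), ROI.circle((50, 0), 20)
        assert cnr(3.7 * img, a, b, grid) == pytest.approx(
            cnr(img, a, b, grid), rel=1e-12)

    def test_undefined_when_both_rois_constant(self, grid):
        assert cnr(np.ones((128, 128)), ROI.circle((-50, 0), 10),
                   ROI.circle((50, 0), 10), grid) is None


class TestNonuniformity:
    def test_equal_means_give_zero(self, grid):
        rois = preset_uniformity_rois(grid)
        assert nonuniformity(np.full((128, 128), 3.0), rois, grid) == 0.0

    def test_hand_computed_example(self, grid):
        rois = preset_uniformity_rois(grid)
        img = np.full((128, 128), 10.0)
        img[rois[0].mask(grid)] = 0.0  # center ROI mean 0, others 10
        # grand mean 8 -> max deviation 8
        assert nonuniformity(img, rois, grid) == pytest.approx(8.0)

    def test_translation_invariant(self, grid, rng):
        rois = preset_uniformity_rois(grid)
        img = rng.normal(size=(128, 128))
        assert nonuniformity(img + 123.4, rois, grid) == pytest.approx(
            nonuniformity(img, rois, grid), abs=1e-9)

    def test_requires_exactly_five_rois(self, grid):
        rois = preset_uniformity_rois(grid)
        with pytest.raises(ValueError):
            nonuniformity(np.zeros((128, 128)), rois[:4], grid)


class TestPresetUniformityROIs:
    def test_five_disjoint_masks_inside_the_phantom(self, grid):
        rois = preset_uniformity_rois(grid)
        assert len(rois) == 5
        masks = [r.mask(grid) for r in rois]
        total = sum(m.sum() for m in masks)
        union = np.logical_or.reduce(masks).sum()
        assert total == union  # disjoint
        x, y = grid.coords()
        assert all(np.all(np.hypot(x[m], y[m]) <= 100.0) for m in masks)

    def test_center_roi_at_origin(self, grid):
        rois = preset_uniformity_rois(grid)
        assert rois[0].center == (0.0, 0.0)

    def test_mask_area_matches_circle_area(self):
        fine = ImageGrid(n_x=512, n_y=512, voxel_size=0.5)
        rois = preset_uniformity_rois(fine)
        expected = np.pi * 13.0**2 / 0.5**2
        assert abs(rois[0].mask(fine).sum() - expected) / expected < 0.02

    def test_roi_outside_image_rejected(self):
        small = ImageGrid(n_x=32, n_y=32, voxel_size=2.0)
        with pytest.raises(ValueError):
            preset_uniformity_rois(small)


class TestOptimization:
    def test_full_sweep_curve_has_131_points(self, noiseless_run, hu_fit,
                                             insert_rois, library):
        curve = optimize_cnr(noiseless_run["basis_images"], hu_fit,
                             insert_rois["acrylic"], ROI.circle((0, 0), 15),
                             library)
        assert len(curve) == 131

    def test_optimum_is_brute_force_extremum(self, noiseless_run, hu_fit,
                                             insert_rois, library):
        """The sweep IS brute force: optimum equals the curve's extremum,
        and repeated runs agree exactly (tie-break determinism)."""
        args = (noiseless_run["basis_images"], hu_fit, insert_rois["delrin"],
                ROI.circle((0, 0), 15), library)
        c1 = optimize_cnr(*args)
        c2 = optimize_cnr(*args)
        k = int(np.argmax(c1.values))
        assert c1.optimal_value == c1.values.max()
        assert c1.optimal_energy == c1.energies[k]
        assert c1.optimal_energy == c2.optimal_energy
        assert np.array_equal(c1.values, c2.values)

    def test_degenerate_identical_rois_tie_break_to_20_kev(
            self, noiseless_run, hu_fit, insert_rois, library):
        roi = insert_rois["water"]
        curve = optimize_cnr(noiseless_run["basis_images"], hu_fit, roi, roi,
                             library)
        assert np.all(curve.values == 0.0)
        assert curve.optimal_energy == 20.0

    def test_contrast_min_symmetric_and_near_zero_for_same_material(
            self, noiseless_run, hu_fit, insert_rois, library):
        a, b = insert_rois["water"], insert_rois["water"]
        curve = optimize_contrast_min(noiseless_run["basis_images"], hu_fit,
                                      a, b, library)
        assert np.all(curve.values == pytest.approx(0.0, abs=1e-9))
        assert curve.optimal_energy == 20.0
        ab = optimize_contrast_min(noiseless_run["basis_images"], hu_fit,
                                   insert_rois["delrin"], insert_rois["ldpe"],
                                   library)
        ba = optimize_contrast_min(noiseless_run["basis_images"], hu_fit,
                                   insert_rois["ldpe"], insert_rois["delrin"],
                                   library)
        assert np.array_equal(ab.values, ba.values)

    def test_contrast_min_finds_theoretical_hu_crossing(self, library,
                                                        hu_fit):
        """Two synthetic voxel patches whose theoretical HU curves cross:
        the argmin of |HU_1 - HU_2| lands within 2 keV of the crossing."""
        from decbct.vmi import sweep as vmi_sweep
        from decbct.recon import BasisImages, ReconImage

        e = np.arange(20, 151, dtype=float)
        basis = np.column_stack([library["aluminum"](e), library["pmma"](e)])
        # solve basis fractions for two packaged materials
        f = {}
        for mat in ("bone50", "teflon"):
            coef, *_ = np.linalg.lstsq(basis, library[mat](e), rcond=None)
            f[mat] = coef
        grid = ImageGrid(n_x=64, n_y=64, voxel_size=2.0)
        f_al = np.zeros((64, 64))
        f_pmma = np.zeros((64, 64))
        f_al[:, :32], f_pmma[:, :32] = f["bone50"]
        f_al[:, 32:], f_pmma[:, 32:] = f["teflon"]
        images = BasisImages(
            f_al=ReconImage(f_al, grid, "basis_al"),
            f_pmma=ReconImage(f_pmma, grid, "basis_pmma"))
        left = ROI.circle((-32, 0), 20)
        right = ROI.circle((32, 0), 20)
        curve = optimize_contrast_min(images, hu_fit, left, right, library)
        hu_diff = np.abs(theoretical_hu("bone50", e, library)
                         - theoretical_hu("teflon", e, library))
        crossing = e[np.argmin(hu_diff)]
        assert abs(curve.optimal_energy - crossing) <= 2.0

    def test_uniformity_check_flat_on_perfect_water_stack(self, library,
                                                          hu_fit):
        from decbct.recon import BasisImages, ReconImage

        e = np.arange(20, 151, dtype=float)
        basis = np.column_stack([library["aluminum"](e), library["pmma"](e)])
        coef, *_ = np.linalg.lstsq(basis, library["water"](e), rcond=None)
        grid = ImageGrid(n_x=128, n_y=128, voxel_size=2.0)
        images = BasisImages(
            f_al=ReconImage(np.full((128, 128), coef[0]), grid, "basis_al"),
            f_pmma=ReconImage(np.full((128, 128), coef[1]), grid,
                              "basis_pmma"))
        curve = uniformity_check(images, hu_fit, library)
        assert len(curve) == 131
        assert np.all(np.abs(curve.values) < 1e-9)
        assert curve.optimal_energy == 20.0  # tie-break
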