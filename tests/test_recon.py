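"""Ram-Lak filtered backprojection: kernel, scaling, linearity, artifacts."""

import dataclasses

import numpy as np
import pytest

from decbct.decompose import log_attenuation
from decbct.materials import MaterialLibrary
from decbct.phantom import Geometry, PhantomSpec, forward_project_poly
from decbct.recon import (ImageGrid, fbp, ramlak_filter, reconstruct_basis,
                          reconstruct_polychromatic)
from decbct.spectra import Spectrum


class TestRamLakFilter:
    def test_zero_row_stays_zero(self):
        assert np.all(ramlak_filter(np.zeros(64), 1.0) == 0)

    def test_homogeneity(self, rng):
        row = rng.normal(size=128)
        a = 3.7
        assert ramlak_filter(a * row, 0.5) == pytest.approx(
            a * ramlak_filter(row, 0.5), rel=1e-12, abs=1e-14)

    def test_impulse_response_matches_spatial_kernel_oracle(self):
        """The filtered impulse must equal the textbook discrete Ram-Lak
        kernel h[0]=1/(4 ds^2), h[odd]=-1/(pi n ds)^2, h[even]=0 (times the
        ds quadrature factor), computed here by direct convolution."""
        n = 64
        spacing_mm = 2.0
        ds = spacing_mm / 10.0  # cm
        row = np.zeros(n)
        row[n // 2] = 1.0
        filtered = ramlak_filter(row, spacing_mm)
        k = np.arange(n) - n // 2
        oracle = np.zeros(n)
        oracle[n // 2] = 1.0 / (4 * ds**2)
        odd = np.abs(k) % 2 == 1
        oracle[odd] = -1.0 / (np.pi * k[odd] * ds) ** 2
        oracle *= ds
        assert filtered == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_near_zero_dc_response_on_constant_row(self):
        # the ramp kernel sums to ~0: away from the edges a constant row
        # filters to well under 1% of the impulse peak (finite-window kernel)
        out = ramlak_filter(np.ones(256), 1.0)
        assert np.max(np.abs(out[64:192])) < 1e-2 * np.max(
            np.abs(ramlak_filter(np.eye(1, 256, 128)[0], 1.0)))


class TestFBP:
    def test_zero_sinogram_gives_zero_image(self, small_geometry, small_grid):
        sino = np.zeros((small_geometry.angles_deg.size,
                         small_geometry.n_detectors))
        assert np.all(fbp(sino, small_geometry, small_grid) == 0)

    def test_linearity(self, small_geometry, small_grid, rng):
        shape = (small_geometry.angles_deg.size, small_geometry.n_detectors)
        s1, s2 = rng.normal(size=shape), rng.normal(size=shape)
        a, b = 2.0, -0.7
        combined = fbp(a * s1 + b * s2, small_geometry, small_grid)
        separate = a * fbp(s1, small_geometry, small_grid) \
            + b * fbp(s2, small_geometry, small_grid)
        scale = np.max(np.abs(separate))
        assert np.max(np.abs(combined - separate)) / scale < 1e-10

    def test_uniform_disk_recovers_mu(self, library, small_grid):
        """20 cm water disk at mono 60 keV: central mean within 2% of mu."""
        geom = Geometry.full_scan(n_angles=660, n_detectors=256,
                                  detector_spacing=1.0)
        p = forward_project_poly(PhantomSpec.uniformity(), geom,
                                 Spectrum.delta(60), 1e7, library)
        img = fbp(log_attenuation(p), geom, small_grid)
        x, y = small_grid.coords()
        center = img[np.hypot(x, y) < 50.0]
        mu = library["water"](60)
        assert abs(center.mean() - mu) / mu < 0.02

    def test_matches_skimage_iradon_oracle(self, library):
        """Cross-check scaling and geometry against an independent FBP."""
        pytest.importorskip("skimage")
        from skimage.transform import iradon

        # half-rotation scan: matches iradon's 180-degree convention directly
        geom = Geometry(angles_deg=np.arange(360) * 0.5, n_detectors=255,
                        detector_spacing=1.0)
        p = forward_project_poly(PhantomSpec.uniformity(), geom,
                                 Spectrum.delta(60), 1e7, library)
        y = log_attenuation(p)
        grid = ImageGrid(n_x=255, n_y=255, voxel_size=1.0)
        ours = fbp(y, geom, grid)
        # iradon expects (detector, angle) with line integrals in pixel units
        theirs = iradon(y.T / 0.1, theta=geom.angles_deg,
                        filter_name="ramp", interpolation="linear",
                        circle=True, output_size=255)
        x, yy = grid.coords()
        inner = np.hypot(x, yy) < 70.0
        scale = np.abs(theirs[inner]).max()
        assert np.max(np.abs(ours[inner] - theirs[inner])) / scale < 0.02

    def test_too_few_angles_rejected(self, small_grid):
        geom = Geometry(angles_deg=np.array([10.0]), n_detectors=16,
                        detector_spacing=1.0)
        with pytest.raises(ValueError):
            fbp(np.zeros((1, 16)), geom, small_grid)


class TestReconstructBasis:
    def test_pure_pmma_phantom_round_trip(self, library, spectrum_low,
                                          spectrum_high, small_geometry,
                                          small_grid):
        """Noiseless water-free PMMA cylinder: basis fractions approach
        (f_al, f_pmma) = (0, 1) inside the disk."""
        from decbct.decompose import decompose_sinogram
        from decbct.phantom import simulate_dual_energy

        spec = PhantomSpec(background="pmma", radius=100.0)
        low, high = simulate_dual_energy(spec, small_geometry, small_geometry,
                                         spectrum_low, spectrum_high, library,
                                         seed=None)
        basis = decompose_sinogram(low, high, spectrum_low, spectrum_high,
                                   library)
        images = reconstruct_basis(basis, small_geometry, small_grid)
        x, y = small_grid.coords()
        inner = np.hypot(x, y) < 50.0
        assert images.f_pmma.values[inner].mean() == pytest.approx(1.0,
                                                                   abs=0.02)
        assert abs(images.f_al.values[inner].mean()) < 0.02

    def test_zero_sinograms_give_zero_images(self, small_geometry,
                                             small_grid, noiseless_run):
        basis = noiseless_run["basis"]
        zeroed = dataclasses.replace(
            basis, t_al=np.zeros_like(basis.t_al),
            t_pmma=np.zeros_like(basis.t_pmma))
        images = reconstruct_basis(zeroed, small_geometry, small_grid)
        assert np.all(images.f_al.values == 0)
        assert np.all(images.f_pmma.values == 0)

    def test_swapping_inputs_swaps_outputs(self, small_geometry, small_grid,
                                           noiseless_run):
        basis = noiseless_run["basis"]
        swapped = dataclasses.replace(basis, t_al=basis.t_pmma,
                                      t_pmma=basis.t_al)
        a = reconstruct_basis(basis, small_geometry, small_grid)
        b = reconstruct_basis(swapped, small_geometry, small_grid)
        assert np.array_equal(a.f_al.values, b.f_pmma.values)
        assert np.array_equal(a.f_pmma.values, b.f_al.values)


class TestReconstructPolychromatic:
    def test_delta_spectrum_equals_ground_truth_mu(self, library, small_grid):
        geom = Geometry.full_scan(n_angles=440, n_detectors=256,
                                  detector_spacing=1.0)
        p = forward_project_poly(PhantomSpec.uniformity(), geom,
                                 Spectrum.delta(80), 1e7, library)
        img = reconstruct_polychromatic(p, small_grid)
        x, y = small_grid.coords()
        inner = np.hypot(x, y) < 50.0
        mu = library["water"](80)
        assert img.values[inner].mean() == pytest.approx(mu, rel=0.02)
        assert img.kind == "polychromatic"

    def test_polychromatic_beam_hardening_cupping(self, library,
                                                  spectrum_low, small_grid):
        """80 kVp water disk: center reads lower than the edge band."""
        geom = Geometry.full_scan(n_angles=440, n_detectors=256,
                                  detector_spacing=1.0)
        p = forward_project_poly(PhantomSpec.uniformity(), geom,
                                 spectrum_low, 1e7, library)
        img = reconstruct_polychromatic(p, small_grid).values
        x, y = small_grid.coords()
        r = np.hypot(x, y)
        center = img[r < 30.0].mean()
        edge = img[(r > 75.0) & (r < 90.0)].mean()
        assert center < edge

    def test_noiseless_run_bitwise_deterministic(self, library, spectrum_low,
                                                 small_grid, small_geometry):
        p = forward_project_poly(PhantomSpec.uniformity(), small_geometry,
                                 spectrum_low, 1e7, library)
        a = reconstruct_polychromatic(p, small_grid)
        b = reconstruct_polychromatic(p, small_grid)
        assert np.array_equal(a.values, b.values)
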