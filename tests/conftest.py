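"""Shared fixtures: packaged material library, default spectra, and one
reduced-size noiseless dual-energy run reused across the module tests.

Reconstruction-quality assertions use a 220-view, 256-detector, 128^2
geometry: large enough for percent-level FBP accuracy, small enough to keep
the suite fast.  The acceptance tests run the full 660-view protocol
themselves.
"""

import numpy as np
import pytest
from hypothesis import settings

from decbct.decompose import decompose_sinogram
from decbct.hu import build_calibration, fit_hu
from decbct.materials import MaterialLibrary
from decbct.metrics import ROI
from decbct.phantom import Geometry, PhantomSpec, simulate_dual_energy
from decbct.recon import ImageGrid, reconstruct_basis
from decbct.spectra import make_spectrum
from decbct.vmi import sweep

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library():
    return MaterialLibrary.default()


@pytest.fixture(scope="session")
def spectrum_low(library):
    return make_spectrum(80, 2.5, library)


@pytest.fixture(scope="session")
def spectrum_high(library):
    return make_spectrum(140, 2.5, library)


@pytest.fixture(scope="session")
def small_geometry():
    return Geometry.full_scan(n_angles=220, n_detectors=256,
                              detector_spacing=1.0)


@pytest.fixture(scope="session")
def small_grid():
    return ImageGrid(n_x=128, n_y=128, voxel_size=2.0)


@pytest.fixture(scope="session")
def sens_phantom():
    return PhantomSpec.sensitometry()


@pytest.fixture(scope="session")
def insert_rois(sens_phantom):
    return {i.material: ROI.circle(i.center, i.radius * 0.6)
            for i in sens_phantom.inserts}


@pytest.fixture(scope="session")
def noiseless_run(library, spectrum_low, spectrum_high, small_geometry,
                  small_grid, sens_phantom):
    """Reduced-size noiseless sensitometry pipeline up to the VMI sweep."""
    p_low, p_high = simulate_dual_energy(
        sens_phantom, small_geometry, small_geometry,
        spectrum_low, spectrum_high, library, seed=None)
    basis = decompose_sinogram(p_low, p_high, spectrum_low, spectrum_high,
                               library)
    basis_images = reconstruct_basis(basis, small_geometry, small_grid)
    stack = sweep(basis_images, library)
    return {
        "projections": (p_low, p_high),
        "basis": basis,
        "basis_images": basis_images,
        "stack": stack,
    }


@pytest.fixture(scope="session")
def hu_fit(noiseless_run, insert_rois, library):
    cal = build_calibration(noiseless_run["stack"], insert_rois, library)
    return fit_hu(cal)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240317)
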