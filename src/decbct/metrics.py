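"""ROI statistics, CNR, uniformity, and VMI energy optimization.

Contrast-to-noise ratio between an insert ROI and a background ROI is

    CNR = |HU_i - HU_bkg| / sqrt((sigma_i^2 + sigma_bkg^2) / 2)

with ROI means and population standard deviations.  Nonuniformity is the
clinical five-ROI check: the largest absolute difference between the grand
mean of the five ROI means and each individual ROI mean.  Optimization is a
brute-force scan over the fast-synthesized VMI stack (1 keV steps), so the
reported optimum is the exact extremum of the materialized curve; ties break
to the lowest energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as _MplPath

from .materials import MaterialLibrary
from .recon import BasisImages, ImageGrid
from .vmi import sweep

__all__ = [
    "ROI",
    "ROIStats",
    "EnergyCurve",
    "roi_stats",
    "cnr",
    "nonuniformity",
    "preset_uniformity_rois",
    "optimize_cnr",
    "optimize_contrast_min",
    "uniformity_check",
]


@dataclass(frozen=True)
class ROI:
    """Circular or polygonal region of interest in physical (mm) coordinates."""

    shape: str                       # "circle" | "polygon"
    center: tuple[float, float] | None = None  # mm (circle)
    radius: float | None = None                # mm (circle)
    vertices: tuple | None = None              # ((x, y) mm, ...) (polygon)

    def __post_init__(self):
        if self.shape == "circle":
            if self.center is None or self.radius is None or self.radius <= 0:
                raise ValueError("circle ROI needs a center and radius > 0")
        elif self.shape == "polygon":
            if self.vertices is None or len(self.vertices) < 3:
                raise ValueError("polygon ROI needs >= 3 vertices")
        else:
            raise ValueError(f"unknown ROI shape {self.shape!r}")

    @classmethod
    def circle(cls, center, radius) -> "ROI":
        return cls(shape="circle", center=tuple(center), radius=float(radius))

    @classmethod
    def polygon(cls, vertices) -> "ROI":
        return cls(shape="polygon",
                   vertices=tuple(tuple(v) for v in vertices))

    def mask(self, grid: ImageGrid) -> np.ndarray:
        """Boolean voxel mask on the target grid; must be non-empty."""
        x, y = grid.coords()
        if self.shape == "circle":
            m = (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 \
                <= self.radius**2
        else:
            pts = np.column_stack([x.ravel(), y.ravel()])
            m = _MplPath(self.vertices).contains_points(pts).reshape(x.shape)
        if not m.any():
            raise ValueError("ROI resolves to an empty mask on this grid")
        return m


@dataclass(frozen=True)
class ROIStats:
    """Mean, population SD and SNR = |mean|/SD over one ROI."""

    mean: float
    sd: float
    snr: float | None  # None when sd == 0 (SNR undefined)
    n_voxels: int


@dataclass(frozen=True)
class EnergyCurve:
    """A metric evaluated across the VMI energy sweep, with its optimum."""

    energies: np.ndarray
    values: np.ndarray
    metric: str
    direction: str                   # "max" | "min"
    optimal_energy: float
    optimal_value: float

    def __post_init__(self):
        if self.direction not in ("max", "min"):
            raise ValueError("direction must be 'max' or 'min'")
        if self.energies.shape != self.values.shape:
            raise ValueError("energies/values shape mismatch")

    def __len__(self):
        return self.energies.size


def roi_stats(image: np.ndarray, roi: ROI,
              grid: ImageGrid) -> ROIStats:
    """ROI mean, population SD and SNR on one image."""
    vals = np.asarray(image)[roi.mask(grid)]
    mean = float(vals.mean())
    sd = float(vals.std())  # population SD
    snr = abs(mean) / sd if sd > 0 else None
    return ROIStats(mean=mean, sd=sd, snr=snr, n_voxels=vals.size)


def cnr(image: np.ndarray, roi_i: ROI, roi_bkg: ROI,
        grid: ImageGrid) -> float | None:
    """Contrast-to-noise ratio between an insert ROI and a background ROI.

    Returns None (undefined) when both standard deviations vanish.
    """
    s_i = roi_stats(image, roi_i, grid)
    s_b = roi_stats(image, roi_bkg, grid)
    noise = np.sqrt(0.5 * (s_i.sd**2 + s_b.sd**2))
    if noise == 0:
        return None
    return abs(s_i.mean - s_b.mean) / noise


def nonuniformity(image: np.ndarray, five_rois, grid: ImageGrid) -> float:
    """Largest deviation of any of five ROI means from their grand mean, HU."""
    rois = list(five_rois)
    if len(rois) != 5:
        raise ValueError("the uniformity check requires exactly five ROIs")
    means = np.array([roi_stats(image, r, grid).mean for r in rois])
    return float(np.max(np.abs(means - means.mean())))


def preset_uniformity_rois(grid: ImageGrid, phantom_radius: float = 100.0,
                           roi_radius: float = 13.0) -> list[ROI]:
    """The clinical five-ROI layout: center plus the four cardinal points.

    The cardinal ROIs sit at 70% of the phantom radius; the 13 mm default
    ROI radius corresponds to the conventional 26-pixel radius at 0.5 mm
    voxels, kept in physical units so the check is grid-independent.
    """
    ring = 0.7 * phantom_radius
    centers = [(0.0, 0.0), (0.0, ring), (0.0, -ring), (-ring, 0.0),
               (ring, 0.0)]
    half_x = grid.n_x * grid.voxel_size / 2
    half_y = grid.n_y * grid.voxel_size / 2
    for cx, cy in centers:
        if abs(cx) + roi_radius > half_x or abs(cy) + roi_radius > half_y:
            raise ValueError("preset uniformity ROI falls outside the image")
    return [ROI.circle(c, roi_radius) for c in centers]


def _metric_curve(stack_hu, metric_fn, metric_name, direction):
    values = np.array([metric_fn(img) for img in stack_hu.images], dtype=float)
    if direction == "max":
        i = int(np.argmax(values))  # argmax takes the first (lowest) energy on ties
    else:
        i = int(np.argmin(values))
    return EnergyCurve(
        energies=stack_hu.energies.copy(), values=values,
        metric=metric_name, direction=direction,
        optimal_energy=float(stack_hu.energies[i]),
        optimal_value=float(values[i]),
    )


def _hu_sweep(basis_images, hufit, library, e_min, e_max, step):
    from .hu import apply_hu

    stack = sweep(basis_images, library, e_min=e_min, e_max=e_max, step=step)
    return apply_hu(stack, None, hufit)


def optimize_cnr(basis_images: BasisImages, hufit, roi_i: ROI, roi_bkg: ROI,
                 library: MaterialLibrary, e_min: int = 20, e_max: int = 150,
                 step: int = 1) -> EnergyCurve:
    """CNR between two ROIs across the sweep; optimum is the argmax."""
    stack_hu = _hu_sweep(basis_images, hufit, library, e_min, e_max, step)
    grid = basis_images.grid

    def metric(img):
        v = cnr(img, roi_i, roi_bkg, grid)
        return 0.0 if v is None else v

    return _metric_curve(stack_hu, metric, "cnr", "max")


def optimize_contrast_min(basis_images: BasisImages, hufit, roi_1: ROI,
                          roi_2: ROI, library: MaterialLibrary,
                          e_min: int = 20, e_max: int = 150,
                          step: int = 1) -> EnergyCurve:
    """|HU_1 - HU_2| across the sweep; optimum is the argmin."""
    stack_hu = _hu_sweep(basis_images, hufit, library, e_min, e_max, step)
    grid = basis_images.grid

    def metric(img):
        return abs(roi_stats(img, roi_1, grid).mean
                   - roi_stats(img, roi_2, grid).mean)

    return _metric_curve(stack_hu, metric, "contrast", "min")


def uniformity_check(basis_images: BasisImages, hufit,
                     library: MaterialLibrary, e_min: int = 20,
                     e_max: int = 150, step: int = 1,
                     phantom_radius: float = 100.0) -> EnergyCurve:
    """Five-ROI nonuniformity across the sweep; optimum is the argmin."""
    stack_hu = _hu_sweep(basis_images, hufit, library, e_min, e_max, step)
    grid = basis_images.grid
    rois = preset_uniformity_rois(grid, phantom_radius=phantom_radius)

    def metric(img):
        return nonuniformity(img, rois, grid)

    return _metric_curve(stack_hu, metric, "nonuniformity", "min")
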