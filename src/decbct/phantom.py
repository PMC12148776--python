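"""Digital Catphan-like phantom and polychromatic forward projection.

The phantom is a 2-D slice model: a background cylinder (disk) of water with
optional disjoint cylindrical material inserts.  Two standard slices are
provided: a sensitometry module carrying nine inserts of known materials, and
a homogeneous uniformity module.  Projections are computed analytically from
ray-circle chord lengths (exact line integrals, no rasterization error) under
a 2-D parallel-beam geometry - the central plane of the clinical full-fan
cone-beam scan, where FDK reduces to ordinary filtered backprojection.

The polychromatic detector signal for a ray with per-material path lengths
L_m (cm) is

    I = I0 * sum_E S(E) * exp(-sum_m mu_m(E) * L_m)

with S(E) the normalized tube spectrum in 1 keV bins.  Poisson counting
noise is optionally applied to the expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .materials import MaterialLibrary
from .spectra import Spectrum

__all__ = [
    "Insert",
    "PhantomSpec",
    "Geometry",
    "ProjectionSet",
    "path_lengths",
    "forward_project_poly",
    "add_poisson_noise",
    "simulate_dual_energy",
]

#: Default incident counts per detector element, emulating an approximately
#: equal dose partition between the low- and high-kV scans
#: (80 kVp 20 mA 60 ms vs 140 kVp 20 mA 10 ms).
DEFAULT_I0 = {80.0: 6.0e5, 140.0: 2.0e5}


@dataclass(frozen=True)
class Insert:
    """Cylindrical material insert: center (mm, mm), radius (mm), material."""

    center: tuple[float, float]
    radius: float
    material: str


@dataclass(frozen=True)
class PhantomSpec:
    """Background cylinder plus disjoint cylindrical inserts (2-D slice)."""

    background: str = "water"
    radius: float = 100.0  # mm
    inserts: tuple[Insert, ...] = ()

    def __post_init__(self):
        for ins in self.inserts:
            cx, cy = ins.center
            if np.hypot(cx, cy) + ins.radius > self.radius + 1e-9:
                raise ValueError(f"insert {ins.material!r} extends outside "
                                 "the background cylinder")
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1:]:
                d = np.hypot(a.center[0] - b.center[0],
                             a.center[1] - b.center[1])
                if d < a.radius + b.radius - 1e-9:
                    raise ValueError("inserts overlap")

    @property
    def materials(self) -> tuple[str, ...]:
        return (self.background,) + tuple(i.material for i in self.inserts)

    @classmethod
    def sensitometry(cls, radius: float = 100.0,
                     insert_radius: float = 12.0) -> "PhantomSpec":
        """Nine-insert sensitometry module: inserts on a ring at 60% of the
        phantom radius, water background."""
        mats = ["vacuum", "pmp", "ldpe", "polystyrene", "acrylic",
                "delrin", "bone50", "teflon", "water"]
        ring = 0.6 * radius
        inserts = []
        for k, m in enumerate(mats):
            ang = 2 * np.pi * k / len(mats)
            inserts.append(Insert(
                center=(ring * np.cos(ang), ring * np.sin(ang)),
                radius=insert_radius, material=m))
        return cls(background="water", radius=radius, inserts=tuple(inserts))

    @classmethod
    def uniformity(cls, radius: float = 100.0) -> "PhantomSpec":
        """Homogeneous water cylinder (uniformity module)."""
        return cls(background="water", radius=radius, inserts=())


@dataclass(frozen=True)
class Geometry:
    """2-D parallel-beam acquisition geometry.

    Detector elements are centered on the rotation axis; element k sits at
    offset (k - (n-1)/2) * spacing mm along the detector axis.
    """

    angles_deg: np.ndarray
    n_detectors: int = 512
    detector_spacing: float = 0.5  # mm

    def __post_init__(self):
        a = np.asarray(self.angles_deg, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("need a 1-D array of projection angles")
        if np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing")
        if a[0] < 0 or a[-1] >= 360:
            raise ValueError("angles must lie in [0, 360)")
        object.__setattr__(self, "angles_deg", a)

    @property
    def detector_offsets(self) -> np.ndarray:
        """Detector element offsets from the rotation axis, mm."""
        k = np.arange(self.n_detectors, dtype=float)
        return (k - (self.n_detectors - 1) / 2) * self.detector_spacing

    @property
    def fov(self) -> float:
        """Detector span, mm."""
        return self.n_detectors * self.detector_spacing

    @classmethod
    def full_scan(cls, n_angles: int = 660, n_detectors: int = 512,
                  detector_spacing: float = 0.5,
                  jitter: float = 0.0,
                  rng: np.random.Generator | None = None) -> "Geometry":
        """Uniform full-rotation scan, optionally with per-angle jitter.

        ``jitter`` is the maximum angular perturbation as a fraction of the
        angular step (<= 0.5 keeps the list strictly increasing); it emulates
        the non-reproducible gantry angles of sequential scans.
        """
        step = 360.0 / n_angles
        angles = np.arange(n_angles) * step
        if jitter > 0:
            if jitter > 0.5:
                raise ValueError("jitter fraction must be <= 0.5")
            if rng is None:
                raise ValueError("jitter requires an rng")
            angles = angles + rng.uniform(-jitter, jitter, n_angles) * step
            angles = np.mod(angles, 360.0)
            angles.sort()
            # keep strictly increasing after the wrap
            angles = np.unique(angles)
            if angles.size < n_angles:  # vanishing-probability duplicate
                missing = n_angles - angles.size
                angles = np.sort(np.concatenate(
                    [angles, angles[:missing] + step * 1e-6]))
        return cls(angles_deg=angles, n_detectors=n_detectors,
                   detector_spacing=detector_spacing)


@dataclass(frozen=True)
class ProjectionSet:
    """Detector intensities for one scan: shape (n_angles, n_detectors)."""

    intensities: np.ndarray
    i0: float
    angles_deg: np.ndarray
    spectrum: Spectrum
    geometry: Geometry = field(repr=False, default=None)
    noisy: bool = False

    def __post_init__(self):
        inten = np.asarray(self.intensities, dtype=float)
        if inten.ndim != 2:
            raise ValueError("intensities must be 2-D (angles, detectors)")
        if np.any(inten < 0):
            raise ValueError("negative detector intensities")
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "angles_deg",
                           np.asarray(self.angles_deg, dtype=float))


def path_lengths(spec: PhantomSpec, geometry: Geometry) -> dict[str, np.ndarray]:
    """Exact per-ray chord lengths through each material, cm.

    Returns a dict material -> array (n_angles, n_detectors).  Insert chords
    are subtracted from the background chord, so for every ray the material
    lengths sum to the background-cylinder chord length.
    """
    theta = np.deg2rad(geometry.angles_deg)[:, None]      # (A, 1)
    s = geometry.detector_offsets[None, :]                # (1, D)
    nx, ny = np.cos(theta), np.sin(theta)

    def chord(center, radius):
        d = np.abs(center[0] * nx + center[1] * ny - s)
        h2 = radius**2 - d**2
        return 2.0 * np.sqrt(np.maximum(h2, 0.0)) / 10.0  # mm -> cm

    out: dict[str, np.ndarray] = {}
    bkg = chord((0.0, 0.0), spec.radius)
    for ins in spec.inserts:
        c = chord(ins.center, ins.radius)
        out[ins.material] = out.get(ins.material, 0.0) + c
        bkg = bkg - c
    out[spec.background] = out.get(spec.background, 0.0) + bkg
    return out


def forward_project_poly(spec: PhantomSpec, geometry: Geometry,
                         spectrum: Spectrum, i0: float,
                         library: MaterialLibrary) -> ProjectionSet:
    """Analytic polychromatic forward projection (expected counts, noiseless)."""
    lengths = path_lengths(spec, geometry)
    mats = list(lengths)
    L = np.stack([lengths[m] for m in mats])              # (M, A, D)
    mu = np.stack([library[m](spectrum.energies) for m in mats])  # (M, E)
    intensities = np.zeros(L.shape[1:])
    for j, w in enumerate(spectrum.weights):
        line = np.tensordot(mu[:, j], L, axes=(0, 0))     # (A, D)
        intensities += w * np.exp(-line)
    intensities *= i0
    return ProjectionSet(intensities=intensities, i0=float(i0),
                         angles_deg=geometry.angles_deg, spectrum=spectrum,
                         geometry=geometry, noisy=False)


def add_poisson_noise(projections: ProjectionSet,
                      seed) -> ProjectionSet:
    """Sample Poisson counts around the expected intensities.

    Zero counts are clamped to 0.5 so downstream log-attenuation stays
    finite.  ``seed`` may be an int or a ``numpy.random.Generator``;
    a fixed seed reproduces the sample exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    counts = rng.poisson(projections.intensities).astype(float)
    counts[counts == 0] = 0.5
    return replace(projections, intensities=counts, noisy=True)


def simulate_dual_energy(spec: PhantomSpec,
                         geometry_low: Geometry, geometry_high: Geometry,
                         spectrum_low: Spectrum, spectrum_high: Spectrum,
                         library: MaterialLibrary,
                         i0_low: float | None = None,
                         i0_high: float | None = None,
                         seed: int | None = None
                         ) -> tuple[ProjectionSet, ProjectionSet]:
    """Sequential-scan dual-energy acquisition of one phantom slice.

    The two geometries may carry different (jittered) angle lists, emulating
    the independent gantry trajectories of two sequential scans.  With
    ``seed=None`` the expected (noiseless) counts are returned; otherwise
    Poisson noise is applied to both scans from one seeded generator.
    """
    if i0_low is None:
        i0_low = DEFAULT_I0.get(spectrum_low.kvp, 5.0e5)
    if i0_high is None:
        i0_high = DEFAULT_I0.get(spectrum_high.kvp, 5.0e5)
    low = forward_project_poly(spec, geometry_low, spectrum_low, i0_low, library)
    high = forward_project_poly(spec, geometry_high, spectrum_high, i0_high,
                                library)
    if seed is not None:
        rng = np.random.default_rng(seed)
        low = add_poisson_noise(low, rng)
        high = add_poisson_noise(high, rng)
    return low, high
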