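"""Projection-domain two-material (Al/PMMA) decomposition.

Each ray of the paired dual-energy sinograms yields two measured
log-attenuations (y_low, y_high).  The forward model for basis thicknesses
t = (t_Al, t_PMMA) under spectrum s is

    yhat_s(t) = -ln sum_E S_s(E) exp(-mu_Al(E) t_Al - mu_PMMA(E) t_PMMA)

and decomposition solves yhat_s(t) = y_s for both spectra simultaneously.
The solver is a damped Newton iteration with the analytic Jacobian (the
transmission-weighted mean basis attenuations), initialized from the exact
2x2 linear solve at the two spectra's effective energies.  Thicknesses are
not constrained to be non-negative: clamping would bias the noise statistics
of the synthesized monoenergetic images.

Because the two sequential scans sample slightly different gantry angles,
sinogram rows are paired by circular nearest-neighbor angle matching before
decomposition, with the low-kV scan as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import MaterialLibrary
from .phantom import ProjectionSet
from .spectra import Spectrum, effective_energy

__all__ = [
    "BasisSinograms",
    "log_attenuation",
    "match_angles_nearest",
    "decompose_ray",
    "decompose_sinogram",
]

COUNT_CLAMP = 0.5  # counts; keeps -ln(I/I0) finite on zero-count detectors


@dataclass(frozen=True)
class BasisSinograms:
    """Equivalent Al/PMMA thicknesses per ray, cm, plus convergence flags."""

    t_al: np.ndarray
    t_pmma: np.ndarray
    converged: np.ndarray
    angles_deg: np.ndarray
    matched_angles_deg: np.ndarray  # high-kV angles paired to each row
    detector_spacing: float
    n_detectors: int

    def __post_init__(self):
        for name in ("t_al", "t_pmma"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if self.t_al.shape != self.t_pmma.shape or \
                self.t_al.shape != self.converged.shape:
            raise ValueError("basis sinogram arrays must share one shape")

    @property
    def fraction_converged(self) -> float:
        return float(np.mean(self.converged))


def log_attenuation(projections: ProjectionSet,
                    clamp: float = COUNT_CLAMP) -> np.ndarray:
    """y = -ln(I / I0) with counts clamped to at least ``clamp``."""
    if projections.i0 <= 0:
        raise ValueError("incident intensity i0 must be positive")
    i = np.maximum(projections.intensities, clamp)
    return -np.log(i / projections.i0)


def match_angles_nearest(set_low: ProjectionSet,
                         set_high: ProjectionSet
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair each low-kV projection with the circularly nearest high-kV one.

    Returns ``(idx, angles_low, matched_high_angles)`` where ``idx`` indexes
    rows of the high-kV sinogram.  Angular distance is computed on the
    circle (period 360 deg); ties go to the smaller high-kV angle.
    """
    a_low = np.asarray(set_low.angles_deg, dtype=float)
    a_high = np.asarray(set_high.angles_deg, dtype=float)
    if a_low.size == 0 or a_high.size == 0:
        raise ValueError("cannot match empty projection sets")
    diff = np.abs(a_low[:, None] - a_high[None, :])
    diff = np.minimum(diff, 360.0 - diff)
    # argmin returns the first (smallest-angle) index on ties
    idx = np.argmin(diff, axis=1)
    return idx, a_low, a_high[idx]


def _spectral_forward(t_al, t_pmma, mu_al, mu_pmma, weights):
    """yhat and the two Jacobian entries for one spectrum, vectorized over
    rays.  mu_* are (E,) at the spectrum energies; t_* any shape."""
    expo = np.exp(-(np.multiply.outer(t_al, mu_al)
                    + np.multiply.outer(t_pmma, mu_pmma)))  # (..., E)
    transmitted = expo @ weights
    yhat = -np.log(transmitted)
    j_al = (expo @ (weights * mu_al)) / transmitted
    j_pmma = (expo @ (weights * mu_pmma)) / transmitted
    return yhat, j_al, j_pmma


def _newton_solve(y_low, y_high, spectrum_low, spectrum_high,
                  mu_al_low, mu_pmma_low, mu_al_high, mu_pmma_high,
                  mu_at, tol, max_iter):
    """Vectorized damped Newton over an arbitrary batch of rays."""
    y = np.stack([np.asarray(y_low, float), np.asarray(y_high, float)], -1)
    shape = y.shape[:-1]

    # initialization: exact 2x2 solve at the effective energies
    e_low = effective_energy(spectrum_low)
    e_high = effective_energy(spectrum_high)
    m = np.array([[mu_at("aluminum", e_low), mu_at("pmma", e_low)],
                  [mu_at("aluminum", e_high), mu_at("pmma", e_high)]])
    det = np.linalg.det(m)
    if abs(det) < 1e-12:
        raise ValueError("effective-energy basis matrix is singular; "
                         "spectra are too similar to separate the basis")
    t = y @ np.linalg.inv(m).T  # (..., 2)

    def residual(t_al, t_pmma):
        yh_l, jl_a, jl_p = _spectral_forward(
            t_al, t_pmma, mu_al_low, mu_pmma_low, spectrum_low.weights)
        yh_h, jh_a, jh_p = _spectral_forward(
            t_al, t_pmma, mu_al_high, mu_pmma_high, spectrum_high.weights)
        r = np.stack([yh_l - y[..., 0], yh_h - y[..., 1]], -1)
        jac = np.stack([np.stack([jl_a, jl_p], -1),
                        np.stack([jh_a, jh_p], -1)], -2)  # (..., 2, 2)
        return r, jac

    converged = np.zeros(shape, dtype=bool)
    r, jac = residual(t[..., 0], t[..., 1])
    rnorm = np.max(np.abs(r), axis=-1)
    for _ in range(max_iter):
        active = (rnorm > tol) & ~converged
        converged |= rnorm <= tol
        if not np.any(active):
            break
        det = (jac[..., 0, 0] * jac[..., 1, 1]
               - jac[..., 0, 1] * jac[..., 1, 0])
        singular = np.abs(det) < 1e-300
        safe_det = np.where(singular, 1.0, det)
        step = np.empty_like(t)
        step[..., 0] = (jac[..., 1, 1] * r[..., 0]
                        - jac[..., 0, 1] * r[..., 1]) / safe_det
        step[..., 1] = (-jac[..., 1, 0] * r[..., 0]
                        + jac[..., 0, 0] * r[..., 1]) / safe_det
        step[singular] = 0.0
        lam = np.where(active & ~singular, 1.0, 0.0)
        # step halving until the residual norm decreases
        improved = np.zeros(shape, dtype=bool)
        for _ in range(12):
            trial = t - lam[..., None] * step
            r_t, jac_t = residual(trial[..., 0], trial[..., 1])
            rn_t = np.max(np.abs(r_t), axis=-1)
            better = active & ~improved & (rn_t < rnorm)
            t = np.where(better[..., None], trial, t)
            r = np.where(better[..., None], r_t, r)
            jac = np.where(better[..., None, None], jac_t, jac)
            rnorm = np.where(better, rn_t, rnorm)
            improved |= better
            lam = np.where(active & ~improved, lam / 2, lam)
            if not np.any(active & ~improved):
                break
    converged |= rnorm <= tol
    return t[..., 0], t[..., 1], converged


def decompose_ray(y_low: float, y_high: float,
                  spectrum_low: Spectrum, spectrum_high: Spectrum,
                  library: MaterialLibrary,
                  tol: float = 1e-8, max_iter: int = 50
                  ) -> tuple[float, float, bool]:
    """Decompose a single ray; returns (t_al, t_pmma, converged), cm."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    mu_al_l = library["aluminum"](spectrum_low.energies)
    mu_p_l = library["pmma"](spectrum_low.energies)
    mu_al_h = library["aluminum"](spectrum_high.energies)
    mu_p_h = library["pmma"](spectrum_high.energies)
    t_al, t_pmma, conv = _newton_solve(
        np.array([y_low]), np.array([y_high]), spectrum_low, spectrum_high,
        mu_al_l, mu_p_l, mu_al_h, mu_p_h,
        lambda mat, e: library[mat](e), tol, max_iter)
    return float(t_al[0]), float(t_pmma[0]), bool(conv[0])


def decompose_sinogram(set_low: ProjectionSet, set_high: ProjectionSet,
                       spectrum_low: Spectrum, spectrum_high: Spectrum,
                       library: MaterialLibrary,
                       tol: float = 1e-8, max_iter: int = 50
                       ) -> BasisSinograms:
    """Angle-match and decompose a full dual-energy sinogram pair."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    idx, a_low, matched = match_angles_nearest(set_low, set_high)
    y_low = log_attenuation(set_low)
    y_high = log_attenuation(set_high)[idx]
    if y_low.shape != y_high.shape:
        raise ValueError("paired sinograms must share a detector count")
    mu_al_l = library["aluminum"](spectrum_low.energies)
    mu_p_l = library["pmma"](spectrum_low.energies)
    mu_al_h = library["aluminum"](spectrum_high.energies)
    mu_p_h = library["pmma"](spectrum_high.energies)
    t_al, t_pmma, conv = _newton_solve(
        y_low, y_high, spectrum_low, spectrum_high,
        mu_al_l, mu_p_l, mu_al_h, mu_p_h,
        lambda mat, e: library[mat](e), tol, max_iter)
    geom = set_low.geometry
    return BasisSinograms(
        t_al=t_al, t_pmma=t_pmma, converged=conv,
        angles_deg=a_low, matched_angles_deg=matched,
        detector_spacing=geom.detector_spacing if geom is not None else 1.0,
        n_detectors=y_low.shape[1],
    )
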