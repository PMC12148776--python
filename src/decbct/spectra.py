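"""Polychromatic x-ray tube spectra.

A simple bremsstrahlung model stands in for the clinical on-board-imager
beams: Kramers' linear ramp ``max(kVp - E, 0)`` shaped by Beer-Lambert
transmission through an aluminium filtration layer, sampled in 1 keV bins and
renormalized to unit total fluence.  Characteristic tungsten lines and bowtie
spatial dependence are omitted; neither changes any algorithmic pathway
downstream (decomposition, reconstruction and synthesis only consume the
normalized weights S(E)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import MaterialLibrary

__all__ = ["Spectrum", "make_spectrum", "effective_energy"]

_E_MIN = 20.0
_E_MAX = 150.0


@dataclass(frozen=True)
class Spectrum:
    """Normalized photon fluence weights on a 1 keV grid.

    ``energies`` runs from 20 keV to min(kvp - 1, 150) keV; weights are
    non-negative, sum to 1 and vanish for E >= kvp by construction.
    """

    kvp: float
    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.shape != w.shape or e.ndim != 1 or e.size == 0:
            raise ValueError("energies/weights must be matching 1-D arrays")
        if np.any(w < 0):
            raise ValueError("spectrum weights must be non-negative")
        if np.any(e >= self.kvp) and np.any(w[e >= self.kvp] > 0):
            raise ValueError("non-zero weight at or above the tube potential")
        s = w.sum()
        if not np.isclose(s, 1.0, atol=1e-12):
            raise ValueError("spectrum weights must sum to 1")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)

    @classmethod
    def delta(cls, energy_kev: float) -> "Spectrum":
        """Monoenergetic beam (single unit-weight bin); handy for tests."""
        return cls(
            kvp=energy_kev + 1,
            energies=np.array([float(energy_kev)]),
            weights=np.array([1.0]),
        )


def make_spectrum(
    kvp: float,
    filtration_mm_al: float = 2.5,
    library: MaterialLibrary | None = None,
) -> Spectrum:
    """Kramers ramp x Al-filtration spectrum, normalized.

    Parameters
    ----------
    kvp : float
        Tube potential in kV, 30..150.
    filtration_mm_al : float
        Equivalent aluminium filtration thickness in mm (>= 0).
    library : MaterialLibrary, optional
        Source of the aluminium attenuation table (defaults to the packaged
        set).
    """
    if kvp <= _E_MIN:
        raise ValueError(f"tube potential {kvp} kV is at or below the "
                         f"{_E_MIN:g} keV grid floor")
    if not (30 <= kvp <= 150):
        raise ValueError("supported tube potentials are 30-150 kV")
    if filtration_mm_al < 0:
        raise ValueError("filtration must be non-negative")
    if library is None:
        library = MaterialLibrary.default()
    energies = np.arange(_E_MIN, min(kvp - 1, _E_MAX) + 0.5)
    mu_al = library["aluminum"](energies)  # cm^-1
    weights = np.maximum(kvp - energies, 0.0) * np.exp(
        -mu_al * filtration_mm_al / 10.0
    )
    weights = weights / weights.sum()
    return Spectrum(kvp=float(kvp), energies=energies, weights=weights)


def effective_energy(spectrum: Spectrum) -> float:
    """Fluence-weighted mean energy, keV."""
    return float(np.sum(spectrum.weights * spectrum.energies))
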