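"""Linear attenuation coefficient tables and energy interpolation.

Attenuation in the diagnostic energy range (20-150 keV) is dominated by two
processes: the photoelectric effect (steeply falling, roughly as E^-3, strong
for high-Z materials) and Compton scattering (slowly falling, proportional to
electron density, with the energy dependence of the Klein-Nishina cross
section).  Every material table shipped with this package is generated from a
two-parameter model

    mu(E) = a_pe * E^-3 + a_kn * f_KN(E)

where ``f_KN`` is the total Klein-Nishina cross section normalized to 1 at
60 keV.  Because aluminium and PMMA span this two-dimensional function space,
any packaged material is an exact linear combination of the two basis
materials, which makes the dual-energy decomposition exactly invertible in
the noiseless limit - the property the round-trip tests rely on.

Tables are stored on a coarse 10 keV grid (20, 30, ..., 150 keV) and
interpolated to 1 keV with a natural cubic spline, mirroring the coarse
NIST-style tabulation + spline refinement used in practice.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "VMI_ENERGIES",
    "KNOT_ENERGIES",
    "MaterialTable",
    "MaterialLibrary",
    "AttenuationModel",
    "klein_nishina",
    "mu_of",
    "theoretical_hu",
]

#: The 1 keV virtual-monoenergetic-image energy grid: 20..150 keV, 131 points.
VMI_ENERGIES: np.ndarray = np.arange(20, 151, dtype=float)

#: The coarse tabulation grid: 20, 30, ..., 150 keV (14 knots).
KNOT_ENERGIES: np.ndarray = np.arange(20, 151, 10, dtype=float)

_ELECTRON_REST_KEV = 511.0


def klein_nishina(energy_kev):
    """Total Klein-Nishina cross section, normalized to 1 at 60 keV.

    Parameters
    ----------
    energy_kev : float or array_like
        Photon energy in keV; must satisfy 1 <= E <= 1000.

    Returns
    -------
    float or ndarray
        sigma_KN(E) / sigma_KN(60 keV), dimensionless.
    """
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e <= 0):
        raise ValueError("photon energy must be positive")
    if np.any((e < 1) | (e > 1000)):
        raise ValueError("energy outside the supported 1-1000 keV range")
    out = _kn_sigma(e) / _kn_sigma(60.0)
    if np.isscalar(energy_kev):
        return float(out)
    return out


def _kn_sigma(energy_kev):
    """Unnormalized total Klein-Nishina cross section (units of the Thomson
    cross section, constant prefactor dropped)."""
    a = np.asarray(energy_kev, dtype=float) / _ELECTRON_REST_KEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log1p(2 * a) / a)
    t2 = np.log1p(2 * a) / (2 * a)
    t3 = -(1 + 3 * a) / (1 + 2 * a) ** 2
    return t1 + t2 + t3


@dataclass(frozen=True)
class AttenuationModel:
    """Photoelectric + Compton parameterization of mu(E).

    Attributes
    ----------
    a_pe : float
        Photoelectric amplitude, cm^-1 keV^3 (>= 0).
    a_kn : float
        Compton amplitude, cm^-1; multiplies the Klein-Nishina factor
        normalized to 1 at 60 keV (>= 0).
    """

    a_pe: float
    a_kn: float

    def __post_init__(self):
        if self.a_pe < 0 or self.a_kn < 0:
            raise ValueError("attenuation amplitudes must be non-negative")

    def mu(self, energy_kev):
        """Linear attenuation coefficient mu(E) in cm^-1."""
        e = np.asarray(energy_kev, dtype=float)
        out = self.a_pe * e**-3 + self.a_kn * klein_nishina(e)
        return float(out) if np.isscalar(energy_kev) else out

    def table(self, name: str, density: float = 1.0) -> "MaterialTable":
        """Tabulate the model on the coarse 10 keV knot grid."""
        return MaterialTable(
            name=name,
            knot_energies=KNOT_ENERGIES.copy(),
            mu=self.mu(KNOT_ENERGIES),
            density=density,
        )


@dataclass(frozen=True)
class MaterialTable:
    """Tabulated linear attenuation coefficients for one material.

    ``mu`` holds cm^-1 values on ``knot_energies`` (the 10 keV grid); a
    natural cubic spline through the knots provides 1 keV resolution.
    A physical material has mu > 0 everywhere; the all-zero ``vacuum`` table
    is the single permitted exception.
    """

    name: str
    knot_energies: np.ndarray
    mu: np.ndarray
    density: float = 1.0
    _spline: CubicSpline = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        ke = np.asarray(self.knot_energies, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        if ke.shape != mu.shape or ke.ndim != 1 or ke.size < 4:
            raise ValueError("need matching 1-D knot/mu arrays with >= 4 knots")
        if np.any(np.diff(ke) <= 0):
            raise ValueError("knot energies must be strictly increasing")
        if ke.min() < 20 or ke.max() > 150:
            raise ValueError("knot energies must lie within [20, 150] keV")
        if np.any(mu < 0):
            raise ValueError("attenuation coefficients must be non-negative")
        object.__setattr__(self, "knot_energies", ke)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(
            self, "_spline", CubicSpline(ke, mu, bc_type="natural")
        )

    def __call__(self, energy_kev):
        """Spline-interpolated mu(E), cm^-1; E must be within [20, 150]."""
        e = np.asarray(energy_kev, dtype=float)
        if np.any((e < self.knot_energies[0]) | (e > self.knot_energies[-1])):
            raise ValueError(
                f"energy outside tabulated range "
                f"[{self.knot_energies[0]:g}, {self.knot_energies[-1]:g}] keV"
            )
        out = self._spline(e)
        return float(out) if np.isscalar(energy_kev) else out


class MaterialLibrary(Mapping):
    """Immutable name -> :class:`MaterialTable` mapping."""

    def __init__(self, tables):
        seen = {}
        for t in tables:
            if t.name in seen:
                raise ValueError(f"duplicate material table {t.name!r}")
            seen[t.name] = t
        self._tables = seen

    def __getitem__(self, name: str) -> MaterialTable:
        try:
            return self._tables[name]
        except KeyError:
            raise KeyError(
                f"no attenuation table for material {name!r}; "
                f"known: {sorted(self._tables)}"
            ) from None

    def __iter__(self):
        return iter(self._tables)

    def __len__(self):
        return len(self._tables)

    @classmethod
    def from_csv(cls, path) -> "MaterialLibrary":
        """Load tables from CSV with columns
        material, energy_keV, mu_per_cm, density_g_cm3."""
        df = pd.read_csv(path, float_precision="round_trip")
        tables = []
        for name, grp in df.groupby("material", sort=True):
            grp = grp.sort_values("energy_keV")
            tables.append(
                MaterialTable(
                    name=name,
                    knot_energies=grp["energy_keV"].to_numpy(float),
                    mu=grp["mu_per_cm"].to_numpy(float),
                    density=float(grp["density_g_cm3"].iloc[0]),
                )
            )
        return cls(tables)

    def to_csv(self, path) -> None:
        rows = []
        for name in sorted(self._tables):
            t = self._tables[name]
            for e, m in zip(t.knot_energies, t.mu):
                rows.append((name, e, m, t.density))
        pd.DataFrame(
            rows, columns=["material", "energy_keV", "mu_per_cm", "density_g_cm3"]
        ).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def default(cls) -> "MaterialLibrary":
        """The packaged table set (basis, water, vacuum, and Catphan-like
        insert materials), generated once by ``scripts/make_attenuation_tables.py``."""
        ref = importlib.resources.files("decbct.data") / "attenuation_tables.csv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_csv(p)


def mu_of(material: str, energy_kev, library: MaterialLibrary):
    """Spline-interpolated linear attenuation coefficient, cm^-1.

    Natural cubic spline through the material's 10 keV knots; reproduces the
    knot values exactly.  Raises for unknown materials or energies outside
    [20, 150] keV.
    """
    return library[material](energy_kev)


def theoretical_hu(material: str, energy_kev, library: MaterialLibrary):
    """Hounsfield units from first principles: 1000 (mu_m - mu_w) / mu_w."""
    mu_w = library["water"](energy_kev)
    if np.any(np.asarray(mu_w) == 0):
        raise ZeroDivisionError("water attenuation is zero; HU undefined")
    mu_m = library[material](energy_kev)
    return 1000.0 * (mu_m - mu_w) / mu_w
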