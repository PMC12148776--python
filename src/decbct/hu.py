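"""Energy-dependent Hounsfield-unit calibration.

The HU scale is energy-dependent: HU = 1000 (mu - mu_w(E)) / mu_w(E), so a
separate linear calibration would normally be needed at every VMI energy.
Instead a single ten-parameter fit maps an attenuation pixel value p (cm^-1)
at energy E (keV) to HU:

    HU(p, E) = A(E) * p + B(E),      A(E) = sum_k a_k (E/100)^k,
                                     B(E) = sum_k b_k (E/100)^k,   k = 0..4

i.e. linear in attenuation (as the HU scale is) with a quartic energy
dependence in both the gain and the offset.  The coefficients are fitted by
ordinary least squares to ROI-mean pixel values of the insert materials at
the eight calibration energies 20, 30, 40, 50, 60, 80, 100 and 150 keV,
against the theoretical HU computed from the attenuation tables.  Energies
are rescaled by 1/100 before forming the polynomial design for numerical
conditioning; coefficients are stored in that rescaled basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .materials import MaterialLibrary, theoretical_hu
from .metrics import ROI, roi_stats
from .vmi import VMIStack

__all__ = [
    "CALIBRATION_ENERGIES",
    "CONSISTENCY_ENERGIES",
    "HUFit",
    "CalibrationSet",
    "build_calibration",
    "fit_hu",
    "apply_hu",
    "hu_consistency_report",
]

#: Energies (keV) at which the fit is calibrated.
CALIBRATION_ENERGIES = (20, 30, 40, 50, 60, 80, 100, 150)
#: Energies (keV) at which HU consistency is reported.
CONSISTENCY_ENERGIES = (40, 50, 60, 80, 100, 150)

_ESCALE = 100.0
_DEGREE = 4


@dataclass(frozen=True)
class CalibrationSet:
    """(material, energy, ROI-mean pixel value, theoretical HU) records."""

    records: pd.DataFrame  # columns: material, energy_kev, pixel_value, hu

    def __post_init__(self):
        required = {"material", "energy_kev", "pixel_value", "hu"}
        if not required <= set(self.records.columns):
            raise ValueError(f"calibration records need columns {required}")
        e = self.records["energy_kev"].to_numpy()
        if not set(np.unique(e)) <= set(map(float, CALIBRATION_ENERGIES)):
            raise ValueError("calibration energies must be a subset of "
                             f"{CALIBRATION_ENERGIES}")

    def __len__(self):
        return len(self.records)

    @property
    def n_energies(self) -> int:
        return self.records["energy_kev"].nunique()


@dataclass(frozen=True)
class HUFit:
    """Coefficients of HU(p, E) = A(E) p + B(E), quartic in E/100."""

    a: np.ndarray  # gain coefficients, HU per cm^-1
    b: np.ndarray  # offset coefficients, HU
    residual_rmse: float  # HU, over the calibration records
    energy_scale: float = _ESCALE

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != (_DEGREE + 1,) or b.shape != (_DEGREE + 1,):
            raise ValueError("expected 5 gain and 5 offset coefficients")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    def gain(self, energy_kev):
        """A(E), HU per cm^-1."""
        return np.polynomial.polynomial.polyval(
            np.asarray(energy_kev, float) / self.energy_scale, self.a)

    def offset(self, energy_kev):
        """B(E), HU."""
        return np.polynomial.polynomial.polyval(
            np.asarray(energy_kev, float) / self.energy_scale, self.b)

    def to_dict(self) -> dict:
        return {
            "model": "HU(p,E) = A(E)*p + B(E); A,B quartic in E/energy_scale",
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "residual_rmse_hu": self.residual_rmse,
            "energy_scale_kev": self.energy_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HUFit":
        return cls(a=np.asarray(d["a"]), b=np.asarray(d["b"]),
                   residual_rmse=float(d["residual_rmse_hu"]),
                   energy_scale=float(d.get("energy_scale_kev", _ESCALE)))


def build_calibration(stack: VMIStack, insert_rois: dict[str, ROI],
                      library: MaterialLibrary,
                      energies=CALIBRATION_ENERGIES) -> CalibrationSet:
    """Collect one (ROI-mean, theoretical HU) record per insert and energy."""
    missing = [e for e in energies if e not in stack.energies]
    if missing:
        raise ValueError(f"VMI stack lacks calibration energies {missing}")
    rows = []
    for material, roi in insert_rois.items():
        mask = roi.mask(stack.grid)
        for e in energies:
            img = stack.at(e)
            rows.append({
                "material": material,
                "energy_kev": float(e),
                "pixel_value": float(img[mask].mean()),
                "hu": float(theoretical_hu(material, e, library)),
            })
    return CalibrationSet(records=pd.DataFrame(rows))


def fit_hu(calibration: CalibrationSet) -> HUFit:
    """Least-squares fit of the ten-coefficient energy-dependent HU mapping."""
    df = calibration.records
    if len(df) < 10 or calibration.n_energies < 2:
        raise ValueError(
            "underdetermined calibration: need >= 10 records at >= 2 "
            "distinct energies to identify the quartic gain and offset")
    e = df["energy_kev"].to_numpy(float) / _ESCALE
    p = df["pixel_value"].to_numpy(float)
    hu = df["hu"].to_numpy(float)
    powers = np.vander(e, _DEGREE + 1, increasing=True)  # (n, 5)
    design = np.hstack([powers * p[:, None], powers])    # (n, 10)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient calibration design (rank {rank} < 10): the "
            "energy-polynomial terms cannot all be identified; add energies "
            "or materials")
    coef, *_ = np.linalg.lstsq(design, hu, rcond=None)
    resid = design @ coef - hu
    return HUFit(a=coef[:5], b=coef[5:],
                 residual_rmse=float(np.sqrt(np.mean(resid**2))))


def apply_hu(mu_values, energy_kev: float, fit: HUFit):
    """Map attenuation values (cm^-1) to HU at one energy.

    Accepts a bare array, a :class:`~decbct.recon.ReconImage` (returns a new
    HU-tagged image) or a :class:`~decbct.vmi.VMIStack` (maps every energy).
    """
    from .recon import ReconImage

    if isinstance(mu_values, VMIStack):
        images = np.stack([
            apply_hu(img, e, fit)
            for img, e in zip(mu_values.images, mu_values.energies)
        ])
        return VMIStack(energies=mu_values.energies, images=images,
                        grid=mu_values.grid, provenance=mu_values.provenance)
    e = float(energy_kev)
    if not (20 <= e <= 150):
        raise ValueError("energy outside the calibrated 20-150 keV range")
    if isinstance(mu_values, ReconImage):
        vals = fit.gain(e) * mu_values.values + fit.offset(e)
        return ReconImage(values=vals, grid=mu_values.grid, kind="hu",
                          energy_kev=e)
    return fit.gain(e) * np.asarray(mu_values, float) + fit.offset(e)


def hu_consistency_report(hu_stack: VMIStack, insert_rois: dict[str, ROI],
                          library: MaterialLibrary,
                          energies=CONSISTENCY_ENERGIES) -> dict:
    """Compare ROI-mean HU against theoretical HU per insert and energy.

    Returns a dict with a tidy per-cell table (material, energy, measured,
    theoretical, error) and the pooled RMSE over all cells.
    """
    rows = []
    for material, roi in insert_rois.items():
        mask = roi.mask(hu_stack.grid)
        for e in energies:
            measured = float(hu_stack.at(e)[mask].mean())
            theory = float(theoretical_hu(material, e, library))
            rows.append({
                "material": material,
                "energy_kev": float(e),
                "measured_hu": measured,
                "theoretical_hu": theory,
                "error_hu": measured - theory,
            })
    table = pd.DataFrame(rows)
    rmse = float(np.sqrt(np.mean(table["error_hu"].to_numpy() ** 2)))
    return {"table": table, "rmse_hu": rmse}
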