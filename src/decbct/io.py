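"""Artifact readers and writers.

Sinograms and VMI stacks are stored as HDF5, images as NIfTI with a JSON
metadata sidecar, curves and tables as CSV, fits and reports as JSON, and
configuration as YAML.  Every file carries a schema version and units
metadata; readers refuse files written under a different schema version.
write -> read is the identity for every artifact type.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .decompose import BasisSinograms
from .hu import HUFit
from .metrics import EnergyCurve
from .phantom import Geometry, ProjectionSet
from .recon import ImageGrid, ReconImage
from .spectra import Spectrum
from .vmi import VMIStack

SCHEMA_VERSION = "1"

__all__ = [
    "write_projections", "read_projections",
    "write_basis_sinograms", "read_basis_sinograms",
    "write_image", "read_image",
    "write_spectrum", "read_spectrum",
    "write_vmi_stack", "read_vmi_stack",
    "write_curve", "read_curve", "plot_curve",
    "write_hufit", "read_hufit",
    "write_json", "read_json",
    "load_config_yaml", "dump_config_yaml",
]


def _check_schema(obj, path):
    v = obj.attrs.get("schema_version") if hasattr(obj, "attrs") \
        else obj.get("schema_version")
    if isinstance(v, bytes):
        v = v.decode()
    if str(v) != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema version {v!r} does not match the supported "
            f"version {SCHEMA_VERSION!r}")


# ---------------------------------------------------------------- sinograms

def write_projections(path, projections: ProjectionSet,
                      spectrum_id: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["units"] = "detector counts"
        f.attrs["i0"] = projections.i0
        f.attrs["kvp"] = projections.spectrum.kvp
        f.attrs["spectrum_id"] = spectrum_id or f"{projections.spectrum.kvp:g}kvp"
        f.attrs["noisy"] = projections.noisy
        geom = projections.geometry
        f.attrs["detector_spacing_mm"] = geom.detector_spacing
        f.create_dataset("intensities", data=projections.intensities)
        f.create_dataset("angles_deg", data=projections.angles_deg)
        f.create_dataset("spectrum_energies_kev",
                         data=projections.spectrum.energies)
        f.create_dataset("spectrum_weights", data=projections.spectrum.weights)


def read_projections(path) -> ProjectionSet:
    with h5py.File(path, "r") as f:
        _check_schema(f, path)
        spectrum = Spectrum(kvp=float(f.attrs["kvp"]),
                            energies=f["spectrum_energies_kev"][:],
                            weights=f["spectrum_weights"][:])
        angles = f["angles_deg"][:]
        geom = Geometry(angles_deg=angles,
                        n_detectors=f["intensities"].shape[1],
                        detector_spacing=float(f.attrs["detector_spacing_mm"]))
        return ProjectionSet(intensities=f["intensities"][:],
                             i0=float(f.attrs["i0"]),
                             angles_deg=angles, spectrum=spectrum,
                             geometry=geom, noisy=bool(f.attrs["noisy"]))


def write_basis_sinograms(path, basis: BasisSinograms) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["units"] = "cm (equivalent basis-material thickness)"
        f.attrs["detector_spacing_mm"] = basis.detector_spacing
        f.create_dataset("t_al", data=basis.t_al)
        f.create_dataset("t_pmma", data=basis.t_pmma)
        f.create_dataset("converged", data=basis.converged)
        f.create_dataset("angles_deg", data=basis.angles_deg)
        f.create_dataset("matched_angles_deg", data=basis.matched_angles_deg)


def read_basis_sinograms(path) -> BasisSinograms:
    with h5py.File(path, "r") as f:
        _check_schema(f, path)
        return BasisSinograms(
            t_al=f["t_al"][:], t_pmma=f["t_pmma"][:],
            converged=f["converged"][:].astype(bool),
            angles_deg=f["angles_deg"][:],
            matched_angles_deg=f["matched_angles_deg"][:],
            detector_spacing=float(f.attrs["detector_spacing_mm"]),
            n_detectors=f["t_al"].shape[1])


# ------------------------------------------------------------------- images

_UNITS = {"polychromatic": "cm^-1", "basis_al": "dimensionless",
          "basis_pmma": "dimensionless", "vmi": "cm^-1", "hu": "HU"}


def write_image(path, image: ReconImage) -> None:
    """NIfTI image + JSON sidecar carrying kind/units/energy metadata."""
    path = Path(path)
    affine = np.diag([image.grid.voxel_size, image.grid.voxel_size, 1.0, 1.0])
    nib.save(nib.Nifti1Image(image.values.astype(np.float64), affine), path)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "kind": image.kind,
        "units": _UNITS.get(image.kind, "unknown"),
        "energy_kev": image.energy_kev,
        "voxel_size_mm": image.grid.voxel_size,
        "n_x": image.grid.n_x,
        "n_y": image.grid.n_y,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_image(path) -> ReconImage:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    _check_schema(sidecar, path)
    data = np.asarray(nib.load(path).dataobj)
    grid = ImageGrid(n_x=sidecar["n_x"], n_y=sidecar["n_y"],
                     voxel_size=sidecar["voxel_size_mm"])
    return ReconImage(values=data, grid=grid, kind=sidecar["kind"],
                      energy_kev=sidecar["energy_kev"])


def write_vmi_stack(path, stack: VMIStack) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["units"] = "cm^-1" if stack.provenance != "hu" else "HU"
        f.attrs["provenance"] = stack.provenance
        f.attrs["voxel_size_mm"] = stack.grid.voxel_size
        f.create_dataset("energies_kev", data=stack.energies)
        f.create_dataset("images", data=stack.images)


def read_vmi_stack(path) -> VMIStack:
    with h5py.File(path, "r") as f:
        _check_schema(f, path)
        images = f["images"][:]
        grid = ImageGrid(n_x=images.shape[2], n_y=images.shape[1],
                         voxel_size=float(f.attrs["voxel_size_mm"]))
        prov = f.attrs["provenance"]
        if isinstance(prov, bytes):
            prov = prov.decode()
        return VMIStack(energies=f["energies_kev"][:], images=images,
                        grid=grid, provenance=str(prov))


# ---------------------------------------------------------------- spectra

def write_spectrum(path, spectrum: Spectrum) -> None:
    df = pd.DataFrame({"energy_keV": spectrum.energies,
                       "weight": spectrum.weights})
    with open(path, "w") as f:
        f.write(f"# schema_version={SCHEMA_VERSION} kvp={spectrum.kvp:g}\n")
        df.to_csv(f, index=False, float_format="%.17g")


def read_spectrum(path) -> Spectrum:
    with open(path) as f:
        header = f.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing spectrum metadata header")
        meta = dict(item.split("=", 1) for item in header[1:].split())
        _check_schema(meta, path)
        df = pd.read_csv(f, float_precision="round_trip")
    return Spectrum(kvp=float(meta["kvp"]),
                    energies=df["energy_keV"].to_numpy(float),
                    weights=df["weight"].to_numpy(float))


# ---------------------------------------------------------- curves and fits

def write_curve(path, curve: EnergyCurve) -> None:
    df = pd.DataFrame({"energy_keV": curve.energies, "value": curve.values})
    with open(path, "w") as f:
        f.write(f"# schema_version={SCHEMA_VERSION} metric={curve.metric} "
                f"direction={curve.direction} "
                f"optimal_energy_keV={curve.optimal_energy:g} "
                f"optimal_value={curve.optimal_value!r}\n")
        df.to_csv(f, index=False)


def read_curve(path) -> EnergyCurve:
    with open(path) as f:
        header = f.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing curve metadata header")
        meta = dict(item.split("=", 1) for item in header[1:].split())
        _check_schema(meta, path)
        df = pd.read_csv(f)
    return EnergyCurve(
        energies=df["energy_keV"].to_numpy(float),
        values=df["value"].to_numpy(float),
        metric=meta["metric"], direction=meta["direction"],
        optimal_energy=float(meta["optimal_energy_keV"]),
        optimal_value=float(meta["optimal_value"]))


def plot_curve(path, curve: EnergyCurve) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.energies, curve.values, lw=1.5)
    ax.axvline(curve.optimal_energy, color="tab:orange", ls="--",
               label=f"optimum {curve.optimal_energy:g} keV")
    ax.set_xlabel("VMI energy (keV)")
    ax.set_ylabel(curve.metric)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_hufit(path, fit: HUFit) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **fit.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_hufit(path) -> HUFit:
    payload = json.loads(Path(path).read_text())
    _check_schema(payload, path)
    return HUFit.from_dict(payload)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(
        json.dumps({"schema_version": SCHEMA_VERSION, **payload}, indent=1,
                   default=_jsonify))


def read_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    _check_schema(payload, path)
    return payload


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"cannot serialize {type(obj)}")


# ------------------------------------------------------------------- config

def load_config_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def dump_config_yaml(path, config: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)
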