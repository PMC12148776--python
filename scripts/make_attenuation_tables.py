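"""Regenerate the packaged attenuation-table fixture.

Each material is parameterized by a relative electron density (rho_e, water=1)
and an effective atomic number Z_eff, converted to the two-process model

    mu(E) = a_pe * E^-3 + a_kn * f_KN(E),   f_KN(60 keV) = 1

with amplitudes anchored to water at 60 keV (total 0.206 cm^-1, of which
0.180 cm^-1 Compton):

    a_kn = 0.180 * rho_e
    a_pe = 5616  * rho_e * (Z_eff / 7.42)^3      [cm^-1 keV^3]

The photoelectric amplitude scales with electron density times an effective-Z
power, the Compton amplitude with electron density alone - the standard
qualitative behaviour in the diagnostic range.  The resulting tables are
synthetic analogs of the Catphan insert materials, not NIST data: they are
K-edge free, monotone decreasing, and exactly spanned by the Al/PMMA basis,
which the decomposition round-trip tests exploit.

Usage:  python scripts/make_attenuation_tables.py
Writes: src/decbct/data/attenuation_tables.csv  (deterministic)
"""

from pathlib import Path

from decbct.materials import AttenuationModel, MaterialLibrary

A_PE_WATER = 5616.0  # cm^-1 keV^3 -> 0.026 cm^-1 at 60 keV
A_KN_WATER = 0.180   # cm^-1 at 60 keV
Z_WATER = 7.42

# name -> (density g/cm3, relative electron density, Z_eff)
MATERIALS = {
    "water":       (1.000, 1.000, 7.42),
    "aluminum":    (2.699, 2.343, 13.00),
    "pmma":        (1.190, 1.147, 6.47),
    "acrylic":     (1.190, 1.147, 6.47),   # acrylic is PMMA
    "pmp":         (0.853, 0.853, 5.44),
    "ldpe":        (0.920, 0.925, 5.44),
    "polystyrene": (1.050, 0.998, 5.70),
    "delrin":      (1.420, 1.363, 6.95),
    "teflon":      (2.160, 1.868, 8.43),
    "bone50":      (1.400, 1.470, 11.60),
}


def build_library() -> MaterialLibrary:
    tables = []
    for name, (density, rho_e, z_eff) in MATERIALS.items():
        model = AttenuationModel(
            a_pe=A_PE_WATER * rho_e * (z_eff / Z_WATER) ** 3,
            a_kn=A_KN_WATER * rho_e,
        )
        tables.append(model.table(name, density=density))
    # all-zero vacuum table (air insert stand-in; HU exactly -1000)
    tables.append(AttenuationModel(0.0, 0.0).table("vacuum", density=0.0))
    return MaterialLibrary(tables)


if __name__ == "__main__":
    out = Path(__file__).resolve().parents[1] / "src" / "decbct" / "data"
    out.mkdir(parents=True, exist_ok=True)
    lib = build_library()
    lib.to_csv(out / "attenuation_tables.csv")
    print(f"wrote {out / 'attenuation_tables.csv'} ({len(lib)} materials)")
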