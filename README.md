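# decbct

Dual-energy cone-beam CT (DE-CBCT) produces *virtual monoenergetic images*
(VMIs) with better soft-tissue contrast and fewer beam-hardening artifacts
than the polychromatic scans a linac's on-board imager delivers. The
practical obstacle is speed: the common production route synthesizes
monoenergetic projections and runs a full reconstruction *per energy*, which
makes a fine (1 keV) search for the optimal VMI energy prohibitively slow.

`decbct` is a scriptable library + CLI for the fast alternative: reconstruct
the two basis-material images **once**, then synthesize any VMI as a voxelwise
linear combination. It covers the whole workflow on a synthetic Catphan-like
phantom:

- polychromatic dual-energy simulation (80/140 kVp sequential scans,
  analytic parallel-beam projections, Poisson noise, gantry-angle jitter
  with nearest-neighbor angle matching),
- projection-domain decomposition into equivalent aluminum/PMMA thicknesses
  (damped Newton with the exact spectral forward model),
- Ram-Lak filtered backprojection of basis and polychromatic sinograms,
- fast VMI synthesis over 20–150 keV in 1 keV steps (131 images),
- a single energy-dependent Hounsfield-unit calibration,
- automated CNR-maximization, contrast-minimization and five-ROI uniformity
  optimization over the energy sweep.

## Method

A ray with equivalent basis thicknesses `t_Al`, `t_PMMA` (cm) under a
normalized tube spectrum `S(E)` attenuates as

    I = I0 · Σ_E S(E) · exp(−μ_Al(E)·t_Al − μ_PMMA(E)·t_PMMA).

Two spectra give two equations per ray, solved for `(t_Al, t_PMMA)` by
Newton iteration. Reconstructing the thickness sinograms yields basis
fraction images `f_Al`, `f_PMMA`, and the VMI at energy `E` is simply

    μ_E = f_Al · μ_Al(E) + f_PMMA · μ_PMMA(E),

which, by linearity of filtered backprojection, is identical (to floating
point) to reconstructing monoenergetic projections at `E` — but costs one
weighted sum instead of one reconstruction. Attenuation tables are kept on a
10 keV grid and refined to 1 keV by natural cubic splines.

HU mapping uses one ten-parameter fit across all energies,

    HU(p, E) = A(E)·p + B(E),   A and B quartic polynomials in E,

calibrated against theoretical insert HU at 20, 30, 40, 50, 60, 80, 100 and
150 keV. Image quality metrics follow the clinical definitions:
`CNR = |HU_i − HU_bkg| / sqrt((σ_i² + σ_bkg²)/2)`, and nonuniformity is the
largest deviation of five preset ROI means from their grand mean.

## Worked example

Run the complete noiseless workflow (simulate → decompose → reconstruct →
sweep → calibrate → optimize) on the synthetic phantom:

    decbct demo --preset noiseless -o run/

which prints

    n_vmis=131 hu_rmse=8.06 HU cnr_opt=62 keV min_nonuniformity=0.030 HU

meaning: the 20–150 keV sweep produced 131 VMIs; pooled over the nine
phantom inserts and six report energies (40–150 keV), the calibrated HU
deviate from theory by 8.06 HU RMSE; acrylic-vs-water CNR peaks at 62 keV;
and the best VMI of the uniformity module is flat to 0.030 HU. `run/`
contains the sinograms (HDF5), basis/polychromatic images (NIfTI), the VMI
stack, the HU fit (JSON), metric-vs-energy curves (CSV + PNG) and
`summary.json`. Stages can equally be run one at a time (`decbct simulate`,
`decompose`, `reconstruct`, `vmi`, `calibrate`, `optimize`, `benchmark`);
see `decbct --help`.

With the `default-noise` preset the scans carry Poisson counting noise and
the CNR optimization recovers soft-tissue optima in the mid-50 keV range,
with narrow peaks that a 10 keV grid would straddle — the motivation for the
1 keV sweep.

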