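# Methods

## Scope and design

The package implements the fast virtual-monoenergetic-image (VMI) workflow
for dual-energy cone-beam CT as a desk-scale, fully synthetic pipeline. The
guiding principle is that every claim exercised here — projection-domain
two-material decomposition, the equivalence of post-reconstruction VMI
synthesis with per-energy reconstruction, the single energy-dependent HU
calibration, and brute-force metric optimization over a 1 keV sweep — is a
property of the *algorithms*, not of any particular scanner. The simulation
is therefore built to make those properties exactly testable rather than to
mimic one device.

### Geometry: 2-D parallel beam

The clinical acquisition is a full-fan, full-rotation cone-beam scan
reconstructed with FDK. On the central plane FDK reduces to ordinary 2-D
filtered backprojection, and every pathway in scope (decomposition, FBP
linearity, HU calibration, optimization) is independent of the cone angle.
The package therefore models the central plane only, with a parallel-beam
geometry: 660 projections over 360°, 512 detector elements at 0.5 mm
(25.6 cm field of view). Projections are computed analytically from
ray–circle chord lengths, so forward data are exact line integrals with no
rasterization error; a rasterized projector exists only as a cross-check in
the test suite.

Sequential scanning is emulated by giving the two scans independently
jittered gantry-angle lists (uniform jitter up to half the angular step,
seeded); decomposition pairs rows by circular nearest-neighbor matching
with the low-kV list as reference, ties toward the smaller angle.

### Materials: a two-process attenuation model

In the 20–150 keV range attenuation is dominated by the photoelectric
effect and Compton scattering, so every packaged material is generated from

    mu(E) = a_pe · E^-3 + a_kn · f_KN(E),

with `f_KN` the total Klein–Nishina cross section normalized to 1 at
60 keV. Amplitudes derive from a relative electron density and an effective
atomic number per material, anchored to water (0.206 cm⁻¹ at 60 keV, of
which 0.180 cm⁻¹ Compton). The packaged set (water, aluminum, PMMA/acrylic,
PMP, LDPE, polystyrene, Delrin, Teflon, 50%-bone analog, and an all-zero
vacuum table for the air insert) is written once to a CSV fixture by
`scripts/make_attenuation_tables.py` at full floating-point precision.

Two consequences are deliberate. First, the tables are synthetic analogs,
not NIST/manufacturer data — absolute HU values are physically plausible
(Teflon ≈ +980 HU, LDPE ≈ −150 HU at 60 keV) but not reproductions of any
published insert. Second, because aluminum and PMMA span the model's
two-dimensional function space, every phantom material is an *exact* linear
combination of the basis pair; noiseless decomposition is then exactly
invertible, which turns round-trip accuracy into a sharp correctness test
instead of a model-mismatch measurement. Tables are stored on the 10 keV
grid (20…150) and interpolated to 1 keV with a natural cubic spline
(second derivative zero at both ends) applied to μ directly; interpolating
ln μ instead would change values by well under the percent level on these
K-edge-free curves but would break the exact-span property.

### Spectra

Tube spectra use Kramers' bremsstrahlung ramp `max(kVp − E, 0)` filtered by
2.5 mm Al (Beer–Lambert, using the packaged aluminum table) in 1 keV bins,
renormalized. Characteristic lines, detector response, scatter and the
bowtie filter are omitted; none of them changes an algorithmic pathway, and
the bowtie affects only real projections. Default incident fluences
(6×10⁵ counts/element at 80 kVp, 2×10⁵ at 140 kVp) emulate the roughly
equal dose partition of the clinical 20 mA · 60 ms / 20 mA · 10 ms exposure
pair; Poisson noise is sampled from the expected counts, with zero counts
clamped to 0.5 before the log transform.

### Decomposition

Per ray, the two measured log-attenuations are inverted for
`(t_Al, t_PMMA)` by a damped Newton iteration (step halving, ≤ 50
iterations, tolerance 1e-8 on the log-attenuation residual) with the
analytic Jacobian — the transmission-weighted mean basis attenuations —
initialized from the exact 2×2 solve at the two spectra's effective
energies. The solver is vectorized over all rays. Thicknesses are not
constrained non-negative: under Poisson noise, near-zero-thickness rays
legitimately decompose to small negative values, and clamping would bias
VMI noise statistics. Non-converged rays (singular Jacobian or iteration
limit) are flagged, not repaired; the noiseless and default-noise phantom
runs converge on every ray.

### Reconstruction

Filtered backprojection uses the discrete Ram-Lak kernel
(`h[0] = 1/(4Δs²)`, `h[odd] = −1/(πnΔs)²`, zero at even lags), applied in
the frequency domain after zero-padding to the next power of two; building
the frequency response from the sampled spatial kernel keeps the DC term
consistent with the finite detector. Backprojection interpolates linearly
in the detector coordinate with per-angle Δθ weights; full-rotation scans
are halved since each line is measured twice. The default grid is 256×256
at 1.0 mm (configurable to the clinical 0.5 mm; the coarser default keeps
the full 660-view pipeline under a minute on one CPU core). A uniform-disk
phantom reconstructs to its known μ within 2% in the central region, and an
independent FBP implementation (scikit-image's `iradon`) agrees to the same
level in the tests.

### HU calibration

One ten-coefficient least-squares fit maps attenuation to HU across all
energies: `HU(p,E) = A(E)·p + B(E)` with both the gain and the offset
quartic in E. Energies are rescaled by 1/100 before forming the polynomial
design (condition number, not values, is affected); coefficients are stored
in the rescaled basis. Giving the offset the same quartic order as the gain
is the symmetric choice; the nested-model property (the energy-dependent
fit can never fit worse than a single energy-independent line) is asserted
in the tests. The fit is calibrated on ROI means of the nine insert
materials at 20/30/40/50/60/80/100/150 keV against theoretical HU computed
from the packaged tables, and reported against the six-energy consistency
set 40–150 keV. The calibration requires at least 10 records at ≥ 2
distinct energies and fails loudly on rank-deficient designs.

The residual of this fit on the noiseless pipeline (≈ 8 HU RMSE) is real,
not numerical: A(E) must track `1000/μ_water(E)`, which a quartic can only
approximate over 20–150 keV, with the largest errors at 40 keV for the
high-Z inserts — the same qualitative error structure a per-energy
calibration would remove at the cost of 131 separate fits.

### Metrics and optimization

ROI statistics use population standard deviation; SNR is `|mean|/SD`
(undefined, not infinite, on constant regions). CNR follows the symmetric
two-ROI definition with the ½(σ²+σ²) noise pooling. The five-ROI
uniformity layout places 13 mm-radius circles (the conventional 26-pixel
radius at 0.5 mm voxels, kept in physical units so the check is
grid-independent) at the center and at 70% of the phantom radius in the
four cardinal directions. Optimization is brute force by construction: the
full VMI stack is materialized, the metric evaluated at every energy, and
the optimum is the exact extremum with ties broken to the lowest energy.
CNR is evaluated on HU-mapped images for report readability; since the HU
map is affine at fixed energy, the optimum is identical on raw μ images.

## What the synthetic data do and do not show

The generator reproduces the *mechanisms* the workflow manipulates:
polychromatic beam hardening (the 80 kVp water cylinder shows genuine
cupping, and decomposed VMIs remove it), Poisson noise propagation through
decomposition (anti-correlated basis noise, mid-energy CNR optima in the
50–60 keV range with narrow peaks), and sequential-scan angle mismatch. It
does not reproduce scatter, detector lag/glare, bowtie fluence gradients,
real insert compositions or vendor spectra, so absolute HU errors, CNR
values and optimal energies are simulation analogs: passing tests validate
the algorithms and their implementation, not agreement with any specific
physical scanner.

## Numerical choices and edge cases

- Energies are integers on the VMI grid; spectral sums use the same 1 keV
  bins. Spline evaluation outside 20–150 keV raises.
- Zero-count clamp 0.5 counts; log-attenuation refuses non-positive I0.
- Vacuum rays decompose to exactly (0, 0); the vacuum table is the single
  permitted all-zero table.
- The equivalence test between fast and typical VMI production uses max
  relative deviation ≤ 1e-8; observed values are at the 1e-15 rounding
  floor.
- Jitter keeps angle lists strictly increasing; a duplicate after the
  360° wrap (probability ~0) is perturbed by a microstep.
- Benchmark timings are hardware-dependent and informational; only the
  ordering (fast marginal cost < typical marginal cost) is asserted.

## Known limitations

- 2-D central plane only; no cone-angle effects, no 3-D FDK.
- Two-material basis only (no iodine/K-edge materials), matching the
  20–150 keV, K-edge-free material set.
- Calibration-free decomposition: the solver is given the true simulation
  spectra. A calibration-based polynomial decomposition for unknown spectra
  is out of scope.
- Image-domain decomposition, blended images and relative-electron-density
  maps are not implemented.
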