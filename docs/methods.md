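# Methods

This note documents the models, parameter choices and numerical conventions
behind `fpmfa`, and what the synthetic studies do and do not demonstrate.

## Optical forward model

A thin pure-phase object o(**r**) on the high-resolution (HR) grid is
illuminated by tilted plane waves from an LED matrix.  LED positions map to
carrier frequencies ν_n = (sin θ_x, sin θ_y)/λ with
sin θ = offset/√(offset² + height²); LEDs are ordered center-outward by
|ν_n| so that the first image is the on-axis bright-field one used for
initialization.  For each LED the HR spectrum is shifted by ν_n **rounded to
the nearest spectral sample**, multiplied by the pupil over the
low-resolution (LR) spectral window, inverse-transformed and squared.  The
same integer rounding is used in reconstruction, so simulator and
reconstructor share one discretization and exact-data fixed points exist.

Conventions: DC-centered spectra everywhere, with `norm="forward"` FFTs on
both grids (forward transform divides by the pixel count).  Under this
normalization a window crop needs no extra scale factor: a unit object
yields a unit bright-field image exactly.  The HR/LR grid ratio is
⌈(NA_MO + λ·max|ν_n|)/NA_MO⌉ rounded up to an even integer, so every
shifted pupil window fits inside the HR spectrum.

Detection noise is optional: per-pixel shot noise at a configurable photon
budget (photons per unit intensity), additive Gaussian read noise, clipped
at zero, all seeded.

## Retrieval algorithm

Sequential object+pupil retrieval with amplitude replacement.  Per LED:
φ = O_w·P on the LR window, Φ = IFT(φ), Φ′ = √I·Φ/|Φ| (where |Φ| = 0 the
ratio is defined as 1, keeping Φ′ = √I at zero phase), φ′ = FT(Φ′), then

* object: O_w ← O_w + G·(φ′ − φ), G = |P|P*/(max|P|·(|P|² + δ₁)),
* pupil:  P ← P + H·(φ′ − φ), H = |O_w|O_w*/(max|O|·(|O_w|² + δ₂)),

followed by projection of P onto its circular support (radius NA_MO/λ).
Both step maps use the pre-update quantities; max|O| runs over the full
current HR spectrum, max|P| over the LR grid.  δ₁ = δ₂ = 10⁻⁴ by default
(relative to unit-normalized spectral amplitudes); the values are
configurable because no canonical choice exists — they only guard the
division and do not visibly affect converged results in the tested range
10⁻⁶–10⁻².  J = 20 outer loops by default with an optional early stop at
relative misfit 10⁻⁶; the misfit Σ‖√I_n − |Φ_n|‖²/Σ‖√I_n‖² is recorded per
outer loop and a 10× increase over the first loop aborts with the history.

Initialization: O⁽⁰⁾ is the Fourier-embedded spectrum of the up-sampled
central image's square root (zero phase); P⁽⁰⁾ is the unit-amplitude
support circle.  No phase unwrapping is performed — synthetic diatom phases
stay below π — but a warning fires if ≥1% of pixels sit within 1% of ±π.
Phase maps can be background-flattened by subtracting a sigma-clipped
second-order polynomial fit (three clipping rounds at 2.5 σ).

Resolution tests use a two-point target whose second point carries a π/2
phase offset.  Two *in-phase* points under coherent imaging blur together
well above the textbook limit; in quadrature their intensities add
incoherently, so the classical two-point criterion applies both to the LR
image and to the coherent synthetic-aperture reconstruction being compared.

## Synthetic diatom scenes

The generator emulates a settled thin film of chain-forming diatoms as a
pure-phase object.  Parameters (defaults in parentheses):

* frustule ellipse 4 × 7 µm (minor × major), peak phase 1.2 rad with
  ±12% lognormal cell-to-cell variation; chains of mean length 4 cells
  abutting along the pervalvar axis;
* areal density (2000 cells/mm²; calibration studies use 6000/mm²).  The
  emulated experiment concentrates cultures to ~190,000 cells/ml and images
  3.3 mm² fields holding thousands of cells; our miniature 64–80 µm fields
  are ~2500× smaller, so density is raised to keep tens of cells per field
  and descriptor statistics usable.  `areal_density_from_cells_per_ml`
  converts volume densities for users who want the film-physics view.
* stress severity s ∈ [0, 1] drives the morphological damage through a
  concave law sev = s^0.6 (dose–response curves are steep at low dose and
  saturate, which is also what makes the low-dose discrimination possible):
  a fraction 0.85·sev of cells lyses (peak phase ×0.55), each lysed cell
  extrudes 3 + 4·sev cytoplasm blobs (radius 0.6–1.6 µm, phase 0.25–0.5
  rad) at distances growing with sev, chains fragment (mean length
  ×(1 − 0.6·sev)) and the surviving peak phase declines ×(1 − 0.45·sev).
* dose → severity: s = dose/55 µM for the 72 h exposure (T3) and dose/110
  for 48 h (T2), clipped at 1.  Both vanish at dose 0, which *builds in*
  the negative-control congruence of the two exposure series; the 2×
  ratio encodes the longer internalization time.

**Miniature-field variance corrections.**  A real field of view averages
thousands of cells; a 64 µm synthetic field holds a few dozen, so plain
independent sampling would overstate field-to-field variance relative to
the emulated study.  Three stratifications restore large-field statistics
while leaving every marginal distribution in place: chain orientations
follow a golden-ratio sequence (±0.02π jitter) instead of uniform draws;
the lysed-cell count is exactly round(p·n) with the membership random; and
per-cell leak-blob counts follow their mean via remainder carry with
golden-angle bearings.  These choices model population-level quantities
(orientation isotropy, lysed fraction, leak load) as properties of the
dosed sample rather than of the miniature field.  Scene placement is
rejection sampling with a crowding limit; an impossible density fails after
bounded retries reporting the achieved density.

What the generator does **not** model: absorption (|o| = 1), 3-D structure
and defocus of the sample, LED intensity mis-calibration or positional
errors, chromatic bandwidth, detector saturation, and any biology beyond
the morphological summary above (no growth, motility, plasmolysis stages).
Passing tests therefore demonstrate the correctness and internal
sensitivity of the pipeline, not field performance on real cultures.

## Descriptors

Gliding-box (Allain–Cloitre) lacunarity over fully-inside boxes at unit
step: Λ(r) = E[m²]/E[m]².  Only fully-inside positions are counted so
results are bit-reproducible and edge effects are excluded.  GL is the
geometric mean of Λ over a dyadic ladder (Λ spans decades across scales;
the geometric mean is the scale-symmetric summary; arithmetic mean and
log-log slope are available).  LL is Λ at a single diatom-sized scale;
MSL = GL/LL.

For a **calibration series** the analysis settings are frozen per
experiment (`AssaySettings`): fixed binarization threshold 0.25 rad (low
enough to capture the faint cytoplasm leaks that carry the dose signal —
a per-image Otsu threshold settles near the bright frustule level and
misses them), ladder 0.5–8 µm, local box fixed at the 4 µm frustule minor
axis (the species is known in a calibration assay; re-estimating the scale
per image would let leak debris shrink it at high dose), and GLCM
quantization of 64 levels over the fixed 0.1–0.6 rad window (the 0.1 rad
floor sits above the reconstruction's background phase ripple,
σ ≈ 0.05 rad, so the texture statistics respond to the sample rather than
to retrieval artifacts).  Outside calibration work, per-image automatic
choices (Otsu threshold, median component diameter, percentile quantization
range) are the defaults.

Δs is the max − min of the per-offset GLCM Shannon entropies (bits) at
distance 1 and angles 0°, 45°, 90°, 135°, with symmetric normalized
matrices.  Its dose response is carried by the growing fine-grained leak
content, which widens the systematic entropy gap between axial and diagonal
(√2-step) offsets.

## Dose assay

The MSL–dose calibration is a bounded least-squares fit of a·e^(bx) + c
with b > 0 (monotone by construction; the three-parameter form lets two
exposure series share a dose-0 intercept).  The Δs low-dose calibration is
an ordinary cubic over doses ≤ 15 µM.  Inversion is closed-form for the
exponential and Brent root-finding for a monotone cubic (monotone-envelope
interpolation on a 4097-point grid otherwise); measurements outside the
curve's range clamp to the nearest dose-domain endpoint with an
out-of-range flag, so a control field below the dose-0 value reads as
dose 0.

The decision table uses half-open intervals [lo, hi) with boundary values
assigning upward and an unbounded top interval.  Classification inverts the
fitted curves to *dose space* and bins there, so the printed dose
boundaries are reusable across recalibrations; the equivalent raw-value
thresholds are recoverable by mapping the boundaries through the curves.
The entropy step runs only when the MSL estimate lands in the lowest
interval, giving 4 + 3 = 7 distinct labels (3 for the flatter T2 variant).

The end-to-end synthetic study calibrates on 4 fields per dose at
{0, 5, 10, 15, 25, 35, 50} µM (T3 severities), reconstructs every field
through the full FPM chain (320² LR grid, 25 LEDs, J = 8, pupil recovery
off for speed on aberration-free stacks), and classifies 3 held-out fields
per dose.  Problem sizes were chosen so the whole study runs in ~75 s on
one CPU; accuracy is stable at 81–95% across seeds.

## Known limitations

* Sub-pixel spectral shifts are not interpolated; LED frequencies off the
  spectral lattice incur up to half a sample of shift error.
* There is no single canonical definition of GL, LL or Δs in the fractal-
  and texture-analysis literature; the geometric-mean ladder, the fixed
  local scale and the max−min offset range are this package's documented
  choices, each isolated behind configuration so alternatives can be
  swapped in.
* The divergence guard compares outer-loop misfits against the first loop;
  pathological stacks that diverge within the first loop surface as
  non-finite-value errors instead.
* Lacunarity is 2-D; thick or overlapping samples are outside the model.
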