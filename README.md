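# fpmfa — Fourier-ptychographic microscopy with multi-scale fractal analysis

`fpmfa` is a simulation, reconstruction and analysis toolkit for an
image-based ecotoxicological assay: live diatoms (*Skeletonema*-like
chain-forming microalgae) are used as bio-probes of copper pollution in
water, imaged label-free by Fourier Ptychographic Microscopy (FPM), and the
resulting quantitative phase-contrast maps are summarized by fractal and
texture descriptors that calibrate against the Cu dose.  The package is
aimed at computational-imaging and aquatic-ecotoxicology researchers who
want to prototype, test or extend the method without a physical FPM bench:
every stage from the raw LED-array acquisition to the final dose-interval
call is implemented and can be driven either from Python or from the
`fpmfa` command line.

## The method

**Forward model.**  An LED at carrier frequency ν_n illuminates a thin
object o(**r**); the objective passes the shifted spectrum through a
circular pupil P(ν) of radius NA_MO/λ, and the camera records

    I_n(r) = |IFT{ O(ν − ν_n) P(ν) }|²,   n = 1 … N.

**Reconstruction.**  Object and pupil are retrieved jointly by a sequential
Gerchberg–Saxton–Fienup scheme.  For each LED the model field
φ(ν) = O(ν − ν_n)P(ν) is propagated to the detector, its amplitude is
replaced by √I_n, and the corrected field φ′ updates both estimates:

    O(ν) ← O(ν) + G · (φ′(ν + ν_n) − φ(ν + ν_n)),
    P(ν) ← P(ν) + H · (φ′(ν) − φ(ν)),

with step maps G = |P|P*/(max|P|·(|P|² + δ₁)) and
H = |O_w|O_w*/(max|O|·(|O_w|² + δ₂)).  A full pass over the N LEDs is one
outer loop, repeated J times; the final spectrum is inverse-transformed into
the high-resolution complex field whose argument is the phase-contrast map.
The synthetic aperture NA_MO + λ·max|ν_n| roughly doubles the lateral
resolution of the 4× objective.

**Descriptors.**  The phase map is binarized and probed with gliding boxes:
Λ(r) = E[m²]/E[m]² over all r×r box masses m.  Three scalars summarize it —
GL (geometric mean of Λ over a dyadic ladder of scales), LL (Λ at a single
diatom-sized scale) and the dose descriptor **MSL = GL/LL**.  A gray-level
co-occurrence matrix per offset direction yields the range entropy
**Δs = max − min** of the per-offset Shannon entropies (bits).

**Two-step dose call.**  MSL calibrates against dose with an exponential
a·e^(bx) + c; inverting it bins a measured field into
[0, 17.5), [17.5, 22.5), [22.5, 30) or [30, ∞) µM (72 h exposure).  Only
when the estimate falls in the lowest interval, a cubic Δs calibration
refines it into [0, 2.5), [2.5, 7.5), [7.5, 12.5) or [12.5, 17.5) µM —
seven possible labels in total.

## Worked example

`examples/` holds one short script per capability.  Reconstruction quality
(`examples/02_reconstruct_phase_map.py`):

```
noiseless stack, 25 LEDs, J=20 outer loops:
  relative misfit 4.10e-04 -> 9.48e-07
  phase RMSE vs ground truth: 0.0457 rad
  (the peak diatom phase is ~1.2 rad, so the map is quantitative)
8 µm defocus, pupil recovery off: phase RMSE 0.0861 rad
8 µm defocus, pupil recovery on : phase RMSE 0.0701 rad
```

The retrieval reproduces the simulated phase to < 0.05 rad, and switching
on pupil recovery absorbs an unknown defocus aberration.  Descriptors
(`examples/03_fractal_descriptors.py`):

```
control (0 µM) : GL= 8.412  LL= 6.444  MSL= 1.305  Δs=0.0535 bits
severe stress  : GL= 7.094  LL= 4.271  MSL= 1.661  Δs=0.0811 bits
```

Copper stress lyses cells and leaks cytoplasm into the medium: gaps at the
diatom scale fill in, LL drops faster than GL, and MSL rises — the monotone
trend that the calibration curves exploit.
`examples/04_dose_calibration_and_classification.py` fits both curves on a
synthetic dose series and classifies held-out fields into the seven
intervals.

The same pipeline is scriptable from the shell:

```bash
fpmfa simulate  --config run.yaml --seed 1 --out sim/
fpmfa reconstruct --stack sim/stack.tif --config run.yaml --out rec/
fpmfa analyze   --phase rec/reconstruction_phase.tif --out desc.csv
fpmfa calibrate --in calibration.csv --exposure T3 --out model.json
fpmfa classify  --model model.json --msl 1.45 --entropy 0.06
```

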