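# Methods

## Calibration model

A raw capture is modelled as counts
`I_raw = D + g(x,y) · S(λ) · R(x,y,λ) + ε`, where `D` is the sensor dark
offset, `g` the spatial illumination/optics gain, `S` the spectral
illumination shape and `ε` read noise.  Flat-field correction

```
R(x,y,λ) = (I_raw − I_dark) / (I_gray − I_dark) · R_tile(λ)
```

is exact for this model whenever the dark and gray frames share `D`, `g`
and `S` with the scene capture: the gain field cancels in the ratio (this
invariance is asserted to 1e−9 in the test suite for arbitrary positive
per-pixel, per-band gain fields).

Numerical choices:

* Negative numerators (counts below dark, from noise) are floored at 0, so
  reflectance is non-negative everywhere.
* Reflectance above 1 (specular highlights) is **retained**, not clipped —
  clipping happens only at colorimetric integration (lower bound 0).  The
  count of above-unity samples is exposed as a quality indicator so users
  can mask specular regions.
* Denominators with magnitude below `epsilon = 1e−6 × full_scale` mark the
  pixel `unstable_reference`; such pixels get reflectance 0 and are
  excluded from every downstream mean.  The default reflects that a dead
  reference pixel carries no information, not that 0 is a plausible value.
* Dark and gray references may be full cubes, per-band spectra or scalars;
  spectra/scalars are broadcast, which is convenient for synthetic work
  and for cameras whose references are spatially stable.
* The gray tile's calibrated spectrum is a user input (two-column CSV).
  The default is a flat 0.40 spectrum — a typical mid-gray diffuse ceramic
  — used when no calibration certificate is available.

## Colorimetry

Tristimulus integration uses the CIE 1931 2° color-matching functions and
the D65 spectral power distribution, bundled as package data at the
canonical 10 nm tabulation over 380–780 nm and resampled by piecewise
linear interpolation onto the camera's band centers.  The 10 nm tabulation
was chosen because camera grids are themselves interpolated onto it;
nested-grid agreement (5 nm vs 10 nm integration of a smooth spectrum) is
within 0.2 in Y, well below the color differences of interest, and the
white point lands within 0.3 of the standard D65/2° values.  The
normalisation `k = 100 / Σ S·ȳ·Δλ` is computed per grid, so Y of a perfect
reflector is exactly 100 on any grid by construction.

Integration weights are trapezoidal band widths, valid on non-equidistant
grids.  The colorimetric integration range is the intersection of the
camera bands with 400–780 nm; near-infrared bands carry no CMF support and
are ignored for color.

CIELAB uses the exact rational constants (ε = 216/24389, κ = 24389/27)
with the two-branch cube-root/linear function; the white point is the
tristimulus of R ≡ 1 under the same table, so neutral spectra map to
a* = b* = 0 identically.

CIEDE2000 implements the complete published procedure — G rescaling of a*
with the 25⁷ term, C′/h′ in degrees, the ±360° hue-difference and mean-hue
branch rules (achromatic pairs with C′₁C′₂ = 0 take Δh′ = 0 and mean hue
h′₁ + h′₂), ΔH′ = 2√(C′₁C′₂)·sin(Δh′/2), SL/SC/SH, and the rotation term
RT.  Parametric factors default to kL = kC = kH = 1, the reference
condition.  The term breakdown is stored with each value and recombines to
the total within 1e−12.  The implementation agrees with scikit-image's
independent implementation to 1e−6 over 1000 random Lab pairs and with the
published worked-example pair (50, 2.6772, −79.7751) vs (50, 0, −82.7485)
→ 2.0425.

Threshold verdicts compare each ΔE against the dental 50:50% thresholds
matching its formula (PT 1.2/0.8, AT 2.7/1.8 for ΔE*ab/ΔE00).  Values
exactly at a threshold classify upward (≥ PT is perceptible, ≥ AT is
unacceptable).  Printed/reported values are rounded half-up to 2 decimals;
banker's rounding would occasionally disagree with conventionally printed
figures at the third decimal.

## Regions and statistics

Row 0 is the top of the image; in the chin-rest capture geometry that is
the gingival side, so the cervical third is the minimal-row band.  This
convention is fixed once here and relied on everywhere; flipping an image
vertically swaps cervical and incisal exactly.

Automatic segmentation thresholds the Lab image (valid ∧ L* ≥ 45 ∧
chroma ≤ 40 by default — teeth are bright and weakly chromatic relative to
gingiva and background) and keeps the largest 4-connected component.  An
externally drawn mask bypasses this entirely.

Thirds divide the mask's bounding rows [r0, r1] at `r0 + round(h/3)` and
`r0 + round(2h/3)` (h = r1 − r0 + 1): a geometric, deterministic stand-in
for the anatomical thirds.  The three bands intersected with the mask
partition it by construction.  Equal row-bands (not equal pixel counts)
were chosen because crown thirds are defined along the cervical–incisal
axis, not by area.

Per-third statistics are arithmetic mean and sample SD (n−1) of L*, a*, b*
over valid pixels, computed **in Lab space**.  Averaging Lab values and
averaging spectra-then-converting differ because the transform is
nonlinear; the Lab-space mean matches how per-third values are reported in
shade studies.  An optional specular-percentile exclusion exists but is
off by default.

## Between- and within-tooth comparisons

Between-teeth ΔE is computed between per-third *mean* colors (difference
of means), and a pair's overall ΔE is the unweighted arithmetic mean of
its three per-third ΔE values.  These two conventions are adopted as the
operative definitions because, applied to the published per-third group
means, they reproduce every published overall value (0.57, 0.58, 7.42,
7.39 for ΔE*ab; 0.48, 0.45, 5.74, 5.71 for ΔE00) and all per-third and
within-tooth range endpoints at 2 dp — no other simple definition does.
Within-tooth comparisons are ΔE between the mean colors of the three third
pairs (C–M, C–I, M–I).

Note a small internal inconsistency in the published discussion of the
worked example: the central-incisor C–M range is quoted there as
6.02–6.15, while the abstract and the per-third table give 5.01–6.07
(6.15 is the UCI1 C–I value).  The table-consistent values are treated as
canonical here.

## Synthetic scenes

The generator emulates the study conditions of an intra-oral line-scan
capture: a 512 × 512 frame with 204 bands over 400–1000 nm, four
rectangular "incisors" (centrals 60 × 90 px, laterals 45 × 80 px, scaled
with the frame), a centred Gaussian vignette of amplitude 0.3 (width
0.5 × frame), a linear ±10% spectral tilt across the range, dark level
1000 counts, gain 40000 counts per unit radiance on a 16-bit scale, and
additive Gaussian read noise of 160 counts ≈ 1% of the gray-tile signal —
truncated to the sensor range.  Noisy captures are quantised to uint16
like a real sensor; noise-free renders stay float64 so that the zero-noise
exact-inversion property is testable at 1e−9.

Tooth spectra are monotone sigmoid edges
`R(λ) = clip(base + amp / (1 + exp(−(λ − edge)/slope)), 0, 1)` — low in
the blue, rising to a red/NIR plateau, the generic shape of dental hard
tissue.  Per-third presets (cervical: base 0.22, amp 0.42, edge 535 nm,
slope 33 nm; middle: 0.42/0.30/495/45; incisal: 0.33/0.27/505/48) were
chosen so the converted colors show the documented crown gradient —
cervical redder (a* ≈ 6.4) and yellower (b* ≈ 29) than incisal
(a* ≈ 1.0, b* ≈ 13), middle lightest (L* ≈ 84) — with coordinates in the
range reported for natural incisors (the single-edge model cannot tune a*
and b* fully independently, so cervical b* runs somewhat high).  Spectral
parameters interpolate linearly between third anchors at normalised crown
depths 1/6, 1/2, 5/6, giving a smooth gradient with no artificial jump at
the third boundaries.  The background is a flat dark 0.06 reflectance.

Ground truth (noise-free reflectance, exact masks, per-third Lab profiles)
is computed through the *same* colorimetry tables as the pipeline under
test, so recovery tests measure pipeline error, not tabulation choices.

What the generator does **not** emulate: per-pixel biological variability
within a third (real per-third SDs across a tooth surface are unknown;
synthetic within-third variation comes only from the smooth gradient and
noise), specular highlights and BRDF effects, tooth-shaped outlines,
gingiva spectra, shot-noise scaling of sensor noise, and inter-subject
variation (the published SDs are across participants).  Passing recovery
tests therefore demonstrates correctness of the calibration and
colorimetric chain under realistic noise — not robustness to segmentation
error or specularity on real teeth.

## Problem sizes and determinism

The test suite and acceptance checks run the forward model at reduced
sizes (96 × 96 × 40 and 128 × 128 × 60) — ample for per-third means over
≥ 75 pixels while keeping the suite fast; the full 512 × 512 × 204 default
renders in seconds and is exercised via the CLI.  Every stochastic step
takes an explicit seed (`numpy.random.default_rng`), and identical seeds
give bit-identical cubes.

## Known limitations

* Standard ENVI headers only (`key = value`, brace-wrapped wavelength
  list; u16/f32/f64, BSQ/BIL/BIP, either endianness).  Vendor dialect
  extensions are carried through `meta` untouched; non-ASCII metadata is
  rejected rather than silently mangled.
* No wavelength-axis calibration, stray-light correction or exposure
  optimisation; the camera is assumed spectrally calibrated.
* Segmentation is a brightness/chroma threshold plus connectivity — it
  locates one tooth per call and assumes the tooth axis is aligned with
  image rows (chin-rest protocol); no rotation estimation.
* Observers/illuminants other than CIE 1931 2°/D65 are pluggable through
  `ObserverIlluminantTable` but not bundled.
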