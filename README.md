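# dentalhsi — hyperspectral dental colorimetry

`dentalhsi` turns hyperspectral reflectance captures of anterior teeth into
clinically interpretable color statements.  It is aimed at dental-optics
researchers who measure tooth color with line-scan hyperspectral cameras
(400–1000 nm, ~200 bands) and need a reproducible pipeline from raw sensor
counts to CIELAB color differences judged against the perceptibility and
acceptability thresholds used in restorative dentistry.

## What it computes

1. **Calibration.** Raw counts are converted to spectral reflectance by
   dark/gray flat-field correction using a dark frame and a matt diffuse
   gray tile captured with identical settings:

   *R*(x, y, λ) = [*I*raw − *I*dark] / [*I*gray − *I*dark] · *R*tile(λ)

   This cancels the sensor offset and any spatially/spectrally non-uniform
   illumination.  Saturated and dead-reference pixels are flagged and
   excluded downstream.

2. **Colorimetry.** Reflectance is integrated against the CIE 1931 2°
   observer color-matching functions under illuminant D65
   (X = k·Σ R·S·x̄·Δλ, trapezoidal Δλ, Y(perfect reflector) = 100), then
   mapped to CIELAB.  Color differences use both

   * ΔE*ab = √(ΔL*² + Δa*² + Δb*²), and
   * ΔE00, the full CIEDE2000 formula with the G chroma rescaling,
     SL/SC/SH weighting functions, kL/kC/kH parametric factors and the RT
     rotation term,

   and each value carries a verdict against the dental 50:50% thresholds
   (PT: ΔE*ab = 1.2, ΔE00 = 0.8; AT: ΔE*ab = 2.7, ΔE00 = 1.8).

3. **Tooth regions.** Each crown is segmented (or a mask supplied), split
   into **cervical / middle / incisal thirds** by equal division of its
   bounding rows (row 0 = gingival side), and the mean ± SD of L*, a*, b*
   is extracted per third.

4. **Analysis.** Per-third and overall differences between *contralateral*
   incisors (UCI1–UCI2, ULI1–ULI2), *adjacent* incisors (UCI1–ULI1,
   UCI2–ULI2) and between the thirds of one tooth.  A pair's *overall*
   ΔE is the unweighted mean of its three per-third values, each computed
   between per-third mean colors.

5. **Synthetic scenes.** Because in-vivo captures of this kind are not
   publicly deposited, `dentalhsi.synthetic` renders four-incisor scenes
   with a cervical→incisal spectral gradient, vignetted and spectrally
   tilted illumination, dark offset and sensor noise — together with exact
   ground-truth reflectance, masks and noise-free color profiles — so the
   entire pipeline is testable end to end.

## Worked example

The published group means per crown third of the four upper incisors ship
as a fixture.  Running the report on them:

```python
from dentalhsi import build_report, table1_fixture, round_half_up

tables = build_report(table1_fixture())
pairs = tables["pairs"]
sel = pairs[(pairs.formula == "CIELAB") & (pairs.scope == "overall")]
print(sel.assign(delta_e=sel.delta_e.map(round_half_up)).to_string(index=False))
```

prints

```
     pair      relation formula   scope  delta_e  verdict
UCI1-UCI2 contralateral  CIELAB overall     0.57 below_PT
ULI1-ULI2 contralateral  CIELAB overall     0.58 below_PT
UCI1-ULI1      adjacent  CIELAB overall     7.42 above_AT
UCI2-ULI2      adjacent  CIELAB overall     7.39 above_AT
```

i.e. the two central (and the two lateral) incisors differ imperceptibly —
a contralateral tooth is a valid shade reference — while central and
lateral incisors on the same side differ far beyond what is clinically
acceptable.  The within-tooth table shows every third-to-third difference
above AT (ΔE*ab 5.01–8.16): a single tooth is not one color.

The same flow is available from the shell:

```bash
dentalhsi simulate  --out scene --size 512 --bands 204 --seed 1
dentalhsi calibrate --raw scene/raw.hdr --dark scene/dark.hdr --gray scene/gray.hdr --out refl.hdr
dentalhsi extract   --cube refl.hdr --mask scene/mask_UCI1.tiff --tooth-id UCI1 --out uci1.csv
dentalhsi report    --profiles scene/truth_profiles.csv --out-dir report
```

## Layout

| module | role |
| --- | --- |
| `dentalhsi.envi` | ENVI header+binary cube I/O (BSQ/BIL/BIP, u16/f32/f64), spectral cropping |
| `dentalhsi.calibration` | flat-field correction, saturation detection, spectrum resampling |
| `dentalhsi.colorimetry` | CIE tables, reflectance→XYZ→CIELAB, ΔE*ab, CIEDE2000, PT/AT verdicts |
| `dentalhsi.regions` | Lab images, tooth masks, third splitting, per-third statistics |
| `dentalhsi.analysis` | pair/within-tooth comparisons and report tables |
| `dentalhsi.synthetic` | ground-truth scene generator and the worked-example fixture |
| `dentalhsi.cli` | `simulate` / `calibrate` / `extract` / `diff` / `report` |

See `docs/methods.md` for the model details, defaults and limitations.
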