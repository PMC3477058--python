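# retscreen

Automated retinal screening from standard raster images, as a tested Python
library and CLI:

- **Diabetic retinopathy (DR)** — from a color fundus photograph: adaptive
  histogram equalization, optic-disc localization (brightest-region
  thresholding at `I_max − 0.02` with a maximum-area rule), blood-vessel
  extraction (difference of gray-scale closings at two scales), hard-exudate
  detection (difference of dilations + hole filling, disc removed), fovea
  localization (parabola fitted to the main vessel, darkest pixel 2–3 optic-disc
  diameters from the vertex), microaneurysm/hemorrhage (MAHM) detection
  (gray-scale hole filling thresholded at the red-channel mean, vessels
  removed), and a 5-level severity grade (none / mild / moderate / severe /
  proliferative) from the lesion distribution over ten fovea-centered
  sub-regions.
- **Glaucoma screening** — from a grayscale OCT B-scan: 10×10 σ=4 Gaussian +
  3×3 median pre-smoothing, 8-neighbor Perona–Malik anisotropic diffusion,
  anterior RNFL boundary from the binarized gradient (158-px area filter at
  the reference 329×689 geometry, 25-px length filter, cubic gap filling)
  refined by a greedy active contour, posterior boundary with the full cleanup
  cascade (100-px / 70-px area filters, RPE rejection, 50-point median), and
  per-column thickness at 6 µm/px. A mean RNFL thickness below **105 µm**
  flags the scan as glaucomatous.
- **Phantoms** — seeded synthetic fundus and OCT generators with exact
  ground-truth masks, landmarks and boundary traces (multiplicative
  gamma speckle with configurable look count), so every stage is testable
  without clinical data.

## CLI

```sh
# generate phantoms (image + ground-truth bundle)
retscreen phantom fundus --seed 1 --out demo_fundus
retscreen phantom oct --seed 1 --looks 4 --out demo_oct

# grade DR severity from a fundus image
retscreen dr-grade demo_fundus/fundus.png --out dr_out

# RNFL thickness + glaucoma screen; several scans aggregate per patient
retscreen rnfl demo_oct/oct.png --out rnfl_out
retscreen rnfl scan1.png scan2.png scan3.png --per-patient

# all tunables live in a JSON config
retscreen dr-grade img.png --config config.json
```

`dr-grade` writes a JSON report plus lesion masks (PNG) and component tables
(CSV); `rnfl` writes a JSON report plus per-column boundary/thickness CSVs.
Every tunable (morphology scales, thresholds, diffusion and snake parameters,
grading cutoffs, axial pitch) is exposed through `retscreen.PipelineConfig`,
which round-trips losslessly through JSON.

## Library layout

| module | contents |
| --- | --- |
| `retscreen.types` | raster/landmark/trace domain types and parameter sets |
| `retscreen.morphology` | gray-scale morphology with pinned border semantics |
| `retscreen.fundus_segmentation` | preprocessing and the five fundus detectors |
| `retscreen.dr_grading` | ten-region partition + severity rule |
| `retscreen.oct_denoise` | Gaussian/median smoothing, anisotropic diffusion |
| `retscreen.oct_rnfl` | boundary estimation, greedy snake, thickness, classifier |
| `retscreen.phantoms` | seeded synthetic generators with exact ground truth |
| `retscreen.pipelines` / `retscreen.cli` | end-to-end flows and the `retscreen` CLI |
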