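# dxafemur

A toolkit for dual-energy X-ray absorptiometry (DXA) image processing of
the proximal femur: high-contrast display-image generation from paired
high-/low-energy detector counts, denoising, image-quality metrics,
pixel-wise bone / soft-tissue / air segmentation, and bone-mineral-density
(BMD) estimation — all exercisable on a built-in synthetic dual-energy
femur phantom, so that every stage is testable without clinical data.

It is aimed at researchers prototyping DXA segmentation and BMD pipelines
who need a controllable, fully ground-truthed stand-in for scanner data.

## The model

A DXA scan measures detector counts at two X-ray energies.  With
`σ_b`, `σ_s` the areal densities (g/cm²) of bone and soft tissue along a
ray and `μ` the per-material, per-energy mass attenuation coefficients,
the expected counts follow the two-material Beer–Lambert law

    LEᵢ = LE₀ · exp(−μ_bone^LE σ_b − μ_soft^LE σ_s),     HEᵢ analogous.

Because bone attenuates the low-energy beam disproportionately, the two
images separate the materials.  The toolkit derives three display images:

* **IBD** (bone-density image, also the per-pixel BMD map):

      Rst = ln(LE₀ / mean LEᵢ) / ln(HE₀ / mean HEᵢ)
      IBD = Rst · (ln(HEᵢ/HE₀) − ln(LEᵢ/LE₀)) / (u_l − u_h·Rst)

  On noise-free phantoms IBD is affine in the true `σ_b`, so regression
  against ground truth recovers BMD with R² > 0.999.
* **ILR** (log-ratio image): `(T − ln(HEᵢ+LEᵢ)/ln(u_l+u_h))^(B+C)`.
* **CI** (collage image): a sigmoid-modulated log-contrast of the two
  energies; the highest-contrast input for segmentation.

Around these sit the pipeline stages: non-local means / Gaussian /
db2-wavelet (hard & soft VisuShrink) denoising; MSR, SNR and CNR quality
metrics on 10×10 ROIs; a deterministic multi-Otsu 3-class baseline
segmenter plus a small trainable encoder–decoder (NumPy, Adadelta,
weighted cross-entropy); morphological binary smoothing of masks; and
evaluation by Jaccard/Dice, threshold-gated dataset accuracy
(JI ≥ 0.92, sensitivity ≥ 95 %, specificity ≥ 93 %), five-fold splits,
and per-ROI BMD with R² agreement.

## Worked example

```python
import numpy as np
from dxafemur import (
    PhantomSpec, make_dataset, make_ci, normalize_to_8bit, denoise_scan,
    default_quality_rois, quality_report, baseline_segment, smooth_mask,
    mean_dice, bmd_map, roi_bmd,
)

spec = PhantomSpec.default()                      # 128x128, Poisson noise
(scan, truth), = make_dataset(1, spec, seed=7)

# image quality before/after wavelet-soft denoising of the collage image
display = normalize_to_8bit(make_ci(scan))
denoised = denoise_scan(scan, "cwt-st", stage="post", display=display)
obj_roi, bg_roi = default_quality_rois(spec)
report = quality_report(display.pixels, denoised.pixels, obj_roi, bg_roi,
                        technique="cwt-st")
print(report.to_frame().to_string(index=False))

# segmentation and BMD against the phantom's ground truth
mask = smooth_mask(baseline_segment(display))
print(f"mean Dice vs truth: {mean_dice(mask, truth.labels):.3f}")
bmd = roi_bmd(bmd_map(scan), truth.labels, truth.rois)
for name, value in bmd.values.items():
    print(f"{name:>5s}: measured {value:.3f}  true {truth.true_bmd[name]:.3f} g/cm2")
```

prints

```
Technique Index  Original   Denoised
   cwt-st   MSR 32.799406 237.106440
   cwt-st   SNR 40.267991  57.418324
   cwt-st   CNR 39.986948  57.130734
mean Dice vs truth: 0.979
 neck: measured 2.230  true 0.884 g/cm2
 ward: measured 2.860  true 1.229 g/cm2
   gt: measured 1.608  true 0.544 g/cm2
```

Wavelet-soft denoising raises the SNR of the noisy collage image by
about 17 dB; the untrained baseline segmenter recovers the 3-class
partition at mean Dice 0.979.  The measured ROI values are in IBD
display units — an affine function of true areal density (here
≈ 4.5·(0.4·σ_b + 0.14)), which is why agreement is assessed by R²
rather than absolute error.

A `dxafemur` command-line interface wraps the same stages
(`simulate`, `contrast`, `denoise`, `quality`, `segment`, `evaluate`,
`bmd`); see `dxafemur --help`.

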