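# Methods

This note documents the models, conventions and design choices behind
`dxafemur`, and what the synthetic phantom does and does not emulate.

## Synthetic dual-energy femur phantom

The phantom (`dxafemur.phantom`) renders a proximal femur from 2D
parametric primitives — head disk, neck band (a thick segment joining
head and shaft), shaft rectangle, and greater/lesser trochanter bumps —
inside an elliptical soft-tissue body; everything else is air.  Labels
are 0 = air, 1 = soft tissue, 2 = bone, and bone always lies strictly
inside the body (the beam over bone also traverses soft tissue).

**Areal densities.**  Bone areal density is a smooth random field
(bicubic upsampling of a 9×9 Gaussian grid) *rank-mapped* to a uniform
distribution on 0.4–1.4 g/cm², the clinically relevant femoral range.
The rank map gives every phantom an identical bone-density histogram
while the spatial pattern varies, the design used by calibrated step
phantoms: regional means (and hence ROI BMD) differ between phantoms,
but the whole-image attenuation budget — and therefore the scan-level
calibration ratio `Rst` — stays stable across a dataset.  Soft-tissue
areal density is uniform over the body at 2.0 g/cm² (the uniform-phantom
convention; the range is configurable).  These two choices matter: with
per-phantom min–max rescaling of the bone field and jittered soft-tissue
thickness, the per-scan `Rst` scatters by ~0.6 % and the across-phantom
affinity of the BMD map degrades below R² ≈ 0.998; the frozen design
holds R² ≈ 0.9994–0.9997 over 50 phantoms.

**Physics.**  Expected counts follow the two-material Beer–Lambert law.
The mass attenuation defaults (bone 0.65/0.25, soft 0.27/0.20 cm²/g at
LE/HE) are invented but realistic for a ≈40/70 keV pair; the invariants
`μ^LE > μ^HE` per material and a higher LE/HE ratio for bone than for
soft tissue (dual-energy separability) are enforced.  Incident counts
default to 5·10⁴ (HE) and 4·10⁴ (LE) per pixel.  Noise is Poisson on the
expected count (the physical default for count data), optionally
additive Gaussian or none; counts are clamped to ≥ 1 after noise so the
logarithms downstream are always finite.  The scan's calibration
constants `u_l`, `u_h` are set to the bone attenuation coefficients.

**Datasets.**  `make_dataset` jitters the geometry per item (head
center/radius, neck width, shaft size/position, trochanter radii; up to
±3 px at 128×128) to emulate patient variation, and draws a fresh
density field and noise realization; everything is reproducible from one
seed.  Named ROIs (femoral neck, Ward's area, greater trochanter) are
derived from the geometry, and per-ROI true BMD is the mean bone areal
density over bone pixels inside the ROI.

**What the phantom does not emulate:** 3D anatomy and projection,
scatter, beam hardening, detector cross-talk, cortical/trabecular
structure, implants, and patient positioning errors.  Passing tests
therefore demonstrate correctness of the algorithms under ideal
two-material physics, not clinical-grade performance.

## Display images

All logarithms are natural.  `Rst` is read as the ratio of whole-image
mean log-attenuations, `ln(LE₀/mean LEᵢ) / ln(HE₀/mean HEᵢ)`, making it
a dimensionless beam-calibration ratio; a scan whose mean count equals
the incident count is rejected as degenerate.  In the bone-density image
the calibration factor multiplies the whole log-difference,
`IBD = Rst·(ln(HEᵢ/HE₀) − ln(LEᵢ/LE₀)) / (u_l − u_h·Rst)`; the
singular case `u_l = u_h·Rst` raises an error.  IBD output is in display
units: it is affine in `σ_b` when the soft-tissue thickness is uniform,
and the toolkit treats it as the BMD map up to that affine relation
(agreement is assessed with R², never absolute units).

For the log-ratio image, a negative base `(T − ln(HEᵢ+LEᵢ)/ln(u_l+u_h))`
is clipped to 0 before the non-integer power `B+C`, keeping the map
total and monotone; `u_l + u_h = 1` is rejected.  For the collage image,
with `r = ln(LEᵢ/HEᵢ)`, the sigmoid `1/(1+exp(−δ(r−μ)))` divides only
the symmetric log-difference `−2r`, the brightness/contrast sum `B+C`
scales that quotient, and `−ln LEᵢ` is an additive term; a constant-ratio
scan is legal (δ = 0, sigmoid ½).  `T = 2.0`, `B = 1.0`, `C = 0.5` by
default; B and C enter only through their sum.  8-bit normalization is
linear min–max to [0, 255] with round-half-to-even; a constant image
maps to all zeros.

## Denoising

* Non-local means: classic patch-similarity weights
  `w = exp(−d²/h²)` with `d²` the mean squared difference between
  patches, uniform patch weighting, no noise-variance offset; defaults
  21×21 search window, 7×7 patch, `h = 10` intensity units (sized for
  0–255 display images).  Implemented as one box filter per search
  offset, which is exactly the literal definition on a padded image —
  the test suite checks equality with quadruple loops to 1e−8.
* Gaussian: truncated, renormalized 5×5 kernel, σ = 1.5 px.
* Wavelet shrinkage: db2, 3 decomposition levels, hard or soft
  thresholding of all detail bands with the universal (VisuShrink)
  threshold `T = σ̂·√(2 ln n)`, `σ̂ = median|finest diagonal|/0.6745`;
  the approximation band is untouched.  The method names `cwt-st` /
  `cwt-ht` follow the field's tables; the transform is the discrete one
  (db2 is a discrete wavelet).

All filters are deterministic, shape-preserving and use the same
edge-inclusive (half-sample symmetric) boundary reflection, so constant
images are fixed points.  Filters apply either to the HE/LE count images
before display generation (stage `pre`, the default) or to a display
image (stage `post`); both orders occur in practice.

## Image quality

MSR divides the whole-image mean by the standard deviation inside a
background ROI (this whole-image-mean convention is unusual but is the
stated definition this toolkit follows); SNR and CNR are amplitude
ratios in decibels, `20·log₁₀(μ_obj/σ_bg)` and
`20·log₁₀(|μ_obj−μ_bg|/σ_bg)`.  Standard deviations are population
(ddof = 0) so hand oracles are exact.  Default ROIs are 10×10: object
inscribed in the shaft bone, background in corner air — equal sizes, as
SNR/CNR require.  Degenerate statistics (zero σ, non-positive object
mean, equal means) raise errors rather than returning infinities.

## Segmentation

The deterministic baseline classifies by two thresholds chosen by
3-class between-class-variance maximization (multi-Otsu) on the
histogram, assuming the display ordering air < soft < bone (true of the
bone-density and collage images); a constant image becomes all air.  It
exists so the evaluation stack is exercisable without training, and is
not expected to reach trained-CNN gate levels: on noise-free phantoms it
attains mean Dice ≈ 0.98, but its bone sensitivity (~91 %) sits below
the 95 % gate because the dimmest bone overlaps soft tissue in display
intensity, so the gated dataset accuracy of an untrained thresholder is
low — reported as computed.

The trainable model is a small from-scratch NumPy encoder–decoder
(conv3×3 → maxpool → conv3×3 → nearest-upsample → conv3×3 → 1×1 conv,
8 base channels, softmax over 3 per-class score maps, argmax labels with
ties resolved bone > soft > air).  Training uses weighted cross-entropy
`H = −mean_pix Σ_c w_c y_c ln(max(ŷ_c, 1e−7))` with weights defaulting
to inverse class frequency (unit weights give the plain loss), Adadelta
(ρ = 0.95, ε = 1e−6) scaled by learning rate 0.2, batch size 25, and
reduce-on-plateau (factor 0.5, patience 10).  Being pure NumPy, a fixed
seed gives bit-identical training curves on one backend; across BLAS
backends only qualitative properties (loss decrease) are promised.
Desk-scale runs in the test suite use 40 phantoms at 64×64 for 30
epochs; the 200-epoch default suits larger studies.

Augmentation applies one identical geometric transform (random flips,
scaling about the center, integer translation; nearest-neighbor for
masks, vacated pixels become air) to image and mask; a dataset is
expanded by an integer multiplier and optionally truncated to an exact
target count (e.g. 350 × 6 → 1800).

Binary smoothing opens then closes each class indicator with a disk
(radius 2 by default) and recombines by argmax; ties between claiming
classes resolve bone > soft > air, and a pixel claimed by no smoothed
indicator keeps its input label (a literal all-zero "tie" would dump
isolated pixels into bone and measurably corrupt speckled masks).  The
result is always a valid partition and is idempotent on smooth masks.

## Evaluation

Per-class one-vs-rest confusion counts give JI = |A∩B|/|A∪B| and
Dice = 2|A∩B|/(|A|+|B|) (the identity Dice = 2JI/(1+JI) is tested
exhaustively), sensitivity and specificity in percent, FPR/FNR.  The
standard Jaccard index is the default; a `ji_variant="printed"` option
evaluates the |A∩B|/(|A|+|B|) form — bounded by 0.5 and therefore unable
to clear a 0.92 gate — for study.  Empty-class conventions: absent from
both masks → JI = Dice = 1; absent from one → 0; empty-denominator rates
default to 100 % (sensitivity/specificity) and 0 (FPR/FNR).

An image passes when the bone-class scores clear all three gates
(JI ≥ 0.92 AND sensitivity ≥ 95 AND specificity ≥ 93; conjunctive,
boundary-inclusive); dataset accuracy is 100 × the pass fraction.
Plain pixel accuracy is reported alongside, since published summary
tables do not always say which statistic they print.  Five-fold splits
shuffle once from a seed and partition indices into test folds of size
⌊n/5⌋ or ⌈n/5⌉.  Per-ROI BMD is the mean of the BMD map (identically
the bone-density display image) over bone-labeled pixels in the ROI;
an ROI with no bone pixels is reported absent with count 0.  Agreement
between BMD measurement sets is the squared Pearson correlation.

## A note on denoising and truth-mask BMD recovery

Pre-denoising the count images does **not** improve ROI-BMD recovery
when the ROI pixels are taken from ground-truth masks: averaging ~100+
bone pixels already suppresses Poisson noise on the ROI mean to ~0.05 %,
while wavelet smoothing bleeds soft-tissue attenuation into boundary
bone pixels and biases the mean.  Measured over 50 phantoms the
no-filter R² exceeds the wavelet-soft R² at every dose tested, and the
gap widens as dose falls.  Denoising helps the *segmentation* that
defines the ROI pixels (mean Dice with wavelet pre-denoising ≥ without,
and all filters raise SNR/CNR); any BMD benefit of denoising therefore
flows through better masks, not through the masked mean itself.

## Problem sizes and numerical choices

Tests and the acceptance script use 128×128 phantoms (64×64 for
training runs), datasets of 10–50 phantoms, 16×16 images for
brute-force filter oracles, and tolerances of 1e−8 for filter/oracle
equality and reconstruction.  The scan-bundle format stores counts as
16-bit integers scaled by a recorded `count_scale`, so integer-count
scans round-trip bit-exactly and simulated fractional counts survive to
quantization precision.  Coordinates are row-major, 0-based, half-open
rectangles everywhere.
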