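# Methods

## Scope and model

`endofeat` implements a descriptor-first view of endoscopic bleeding
detection: nine hand-crafted visual features are computed as per-pixel
activation maps, fused with RGB as extra CNN input channels, and used
directly for weakly supervised localization. The package covers everything
around the network — descriptors, ROI detection, channel fusion and
first-layer adaptation, localization and its IoU scoring, classification
metrics, dataset balancing/augmentation/fold assignment — but deliberately
ships no CNN architectures or training loops; those are standard components
a user brings from their deep-learning framework of choice.

## The descriptors

**F1 (blood color region)** is implemented exactly as specified by its
pseudocode: `c1` measures the excess of red as `min(r/b, r/g)/255`
normalized over [0.003, 0.01] (byte ratios 0.77–2.55), `c2` measures the
green/blue proximity, and the map is `norm(c1·c2⁵, 0.02, 1.1)` with pixels
of `r < 30` and pixels outside the ROI cleared. Green and blue are floored
at 1 before division. One reading note: the ratio expression is
element-wise division (`r·b⁻¹`), not subtraction by one; this matches the
descriptor's stated intent ("minimum of the r/b and r/g ratios") and the
excess-red literature it builds on.

**F2–F9 parameters are this package's declared defaults.** Only F1's
constants are published; the remaining descriptors are described
qualitatively. The choices here, all exposed in `DescriptorParams`:

- *Smoothness gate (F2/F5)*: local standard deviation of gray intensity in
  an 11-px window, mapped through `1 − norm(σ, 2, 30)` (0–255 intensity
  units). Liquid blood pools are nearly flat (σ ≈ 0 → gate ≈ 1); textured
  mucosa or noise suppresses the gate.
- *Boundary test (F3/F6)*: regions are connected components of the base
  map at activation ≥ 0.5. A region passes when ≥ 20% of its 1-px contour
  band carries a Sobel gradient above 30 intensity/px; passing regions are
  painted with their own activation (the map marks where the blood is, not
  only its rim), failing regions are cleared.
- *F4 relaxation*: `c1` window widened to [0.0015, 0.01] (ratios from
  0.38) and the `c2` exponent lowered to 2, accepting oranges and browner
  reds that F1 rejects.
- *F7*: pixels with F1 activation ≥ 0.5 ("blood-colored" at full
  strength), minus connected components larger than 1% of the ROI area —
  only spots, streaks and sprays remain.
- *F8*: wide-red test `r > g + 20 and r > b + 20` on ROI pixels after
  excluding near-saturated highlights (`min(r,g,b) > 230`) and near-black
  pixels (`max(r,g,b) < 30`); the covered fraction f is mapped through
  `norm(f, 0.25, 0.75)`, which fixes 0.5 as the 50%-coverage point.
- *F9*: mean per-channel intensity variance inside the ROI through
  `norm(v, 50, 1500)`, times one minus the fraction of ROI pixels whose
  Sobel magnitude exceeds 40 intensity/px through `norm(e, 0.01, 0.12)`.
  Blur preserves variance at the scales that matter while collapsing the
  edge fraction, so blurred frames score higher.

F8 and F9 are image-level statements; they are emitted as constant maps
over the ROI (zero outside) so that the 12-channel stacking contract is
identical for all nine features.

## ROI detection

The ROI algorithm is a reconstruction — reference material describes only
its purpose (exclude the black border and overlay text). Pixels with
`max(r,g,b) > 12` are candidate organ area; the largest connected
component is kept (overlay text blocks are small, isolated, and die here),
closed with a 15-px elliptical kernel, hole-filled, and finally a 3-px
boundary band is peeled *conditionally*: only boundary pixels darker than
60 are removed. The conditional peel — rather than a blanket erosion —
keeps mixed border pixels out of the descriptors while making the detector
a fixed point under re-application to the masked frame (a blanket erosion
shrinks the mask by 3 px on every application and can never be idempotent).

## Fusion contracts

RGB is scaled to [0, 1] so all 12 channels share one dynamic range. The
224 × 224 resize uses per-channel cubic interpolation with overshoot
clipped back into [0, 1]; features are computed at native resolution first,
resized after. First-layer expansion preserves the three RGB kernel slices
bit-exactly; `zero` init is the default because it is exactly
function-preserving on inputs with zeroed feature channels, `mean-replicate`
is offered as a transfer-learning warm start. Ensembling is the arithmetic
mean of model output probabilities.

## Localization and scoring

Fmap = mean of channels F1–F7, then min-max normalization and a 0.5
threshold. The constant-valued F8/F9 channels are excluded — they carry no
location information. A constant (degenerate) map binarizes to all-zero:
no pixel is distinguished, and declaring the entire frame a detection
would be meaningless. The bounding box covers *all* above-threshold pixels,
not just the largest component, and no small-component filtering is applied
before boxing. Empty prediction vs non-empty reference scores IoU 0;
empty vs empty scores 1. Coordinates are 0-based half-open, making
`area = (r1−r0)·(c1−c0)` exact.

## Metrics

Score ≥ threshold counts as positive (ties to positive). ROC AUC uses the
trapezoidal/probabilistic convention (equals the pairwise win rate with
ties at half weight). Operating points are attained conservatively with no
interpolation: `sens@f` is the maximum sensitivity among thresholds whose
achieved FPR ≤ f, `spec@s` the maximum specificity among thresholds whose
achieved sensitivity ≥ s. The three high-sensitivity operating points are
specificities at forced sensitivity (0.95/0.99/0.999) — the `spec@` family —
even though one widely seen metric table mislabels them `sens@`. When the
negative count is below 1/f the requested FPR cannot be resolved and a
warning is attached to the result.

## Dataset preparation

Blood samples with fewer than 100 images are balanced by cyclic
duplication of their own images up to exactly 100; non-blood samples are
never balanced and no image is ever removed. Folds are assigned by
randomly partitioning *examinations* (not images) into k groups, so frames
of one examination can never leak across folds. The augmentation battery
(rotation ±15°, flips, shear ±0.1, perspective jitter ≤ 5%, blur σ ≤ 1.5,
noise σ ≤ 8, hue ±10°, saturation ×[0.8, 1.2], PCA color shift with
eigen-perturbation scale ≤ 0.1) draws each magnitude uniformly from its
range per application; ranges are declared defaults, as only the transform
set itself is prescribed.

## The synthetic generator

The generator emulates exactly the properties the descriptors key on:
a bright field of view (disc or rounded rectangle) on a near-black border
with overlay-like text blocks; mucosa of color (185, 125, 105) with
low-frequency texture (smoothed Gaussian noise, σ_texture 6 px, amplitude
6); blood ellipses of color (150, 22, 28) — ratios r/g ≈ 6.8, r/b ≈ 5.4,
|g−b| = 6, firmly in F1's high-activation regime; orange distractors
(180, 100, 50) in F4's range but with a wide green/blue gap; specular
highlight discs; bubble rings; optional global blur. Ground-truth blood and
field-of-view masks are exact by construction.

What it does *not* emulate: interlacing artifacts, illumination gradients,
depth-dependent color shifts, peristalsis motion blur, stool/bile fluids,
and the long-tailed difficulty of real endoscopic frames. Passing tests on
generator output therefore demonstrates the *mechanics* of the pipeline —
correct arithmetic, masking, recovery of cleanly rendered targets — not
clinical-grade detection accuracy. One consequence worth knowing: healthy
mucosa is itself mildly red (ratio ≈ 1.5 falls inside F1's c1 window), so
mucosa carries F1 ≈ 0.23 rather than zero; separation from blood (≈ 0.80)
is by margin, which is exactly what the normalize-then-threshold
localization step exploits.

## Problem sizes and numerics

The test and acceptance batteries render frames at 360 × 288 (half PAL),
50 frames per battery; the generator's default remains 720 × 576. All
descriptor arithmetic is float64 after byte extraction, with the
`max(g,1)`/`max(b,1)` division guards. `norm` clips after scaling
(equivalent to clipping before, under the linear form). Seeded
`numpy.random.Generator` streams drive every stochastic component; repeated
runs are bit-identical.

## Known limitations

- ROI detection is tuned for dark-border endoscopic frames; frames with
  bright borders or overlays overlapping the organ area are out of contract.
- F2–F9 defaults were chosen against the synthetic study conditions; real
  deployments should expect to retune `DescriptorParams` on their data.
- The descriptor-only frame score used in the acceptance run (95th
  percentile of the F1–F7 mean inside the ROI) is a demonstration
  classifier, not a substitute for a trained CNN ensemble.
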