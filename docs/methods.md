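# Methods

## Problem setting

A whole-slide image is a pyramidal scan, typically 0.25 μm/px at level
0. Tissue-versus-background segmentation does not need cellular detail,
so detection runs on an RGB thumbnail at 10 μm/px (≈1× objective) —
roughly two orders of magnitude less data — where section boundaries,
staining patterns and gross artifacts are preserved. The output
contract is a single-channel mask restricted to {0, 255}, 255 marking
tissue. Every operation in the package maintains that invariant; masks
are serialized as 8-bit single-channel PNG.

## Detectors

### Global Otsu

Grayscale conversion uses Rec.601 luminance (0.299 R + 0.587 G +
0.114 B, rounded to nearest integer). The Otsu threshold T\* maximizes
the between-class variance ω₀ω₁(μ₀−μ₁)² over splits of the 256-bin
histogram into classes {level ≤ t} and {level > t}; ties take the
lowest qualifying t, and tissue is marked where gray ≤ T\*. This ≤
convention is the one under which the canonical degenerate cases come
out right: a two-level image of 0s and 255s yields T\* = 0 with exactly
the 0-pixels marked. A uniform thumbnail has no valid split and maps to
an all-background mask (blank glass contains no tissue) rather than an
error. No morphological post-processing is applied — the method is the
baseline, reported raw.

### Color-statistics K-means

Each pixel becomes a 2-vector (μ, σ): the mean and the population
standard deviation (ddof = 0) of its three channel values scaled to
[0, 1]. μ ∈ [0, 1]; σ ∈ [0, 0.5] by construction. A 2-cluster K-means
(k-means++ initialization, 10 restarts, tolerance 1e-4, fixed seed)
partitions the pixels; the cluster with the lower center μ — the darker
one — is tissue. Choosing by the μ rule rather than by cluster index
makes the output invariant to label permutation, and fixing the seed
makes it bit-reproducible. The raw label mask is refined by closing
then opening with the 5×5 square element. An image whose features are
all identical cannot be split and maps to all-background.

### Double-Pass

Two passes, complementary by design, fused by pixelwise OR:

1. **FilterGrays** — sharpen with the 3×3 Laplacian-boost kernel
   [[0,−1,0],[−1,5,−1],[0,−1,0]] (reflective padding, clipped to
   [0, 255]), then mark pixels whose channel spread
   max(R,G,B) − min(R,G,B) strictly exceeds 15 levels. The spread test
   rejects every achromatic pixel — glass, shadows, gray scanner
   artifacts — regardless of brightness. The mask is closed (5×5) to
   bridge small gaps and components under 5000 px are removed
   (strictly: 4999 px goes, 5000 px stays). Refinement before the area
   filter is a single closing, which preserves the area of convex and
   rectilinear components exactly, so the 5000-px rule cuts where it
   says it cuts; a net-growing dilation at this point would inflate
   every component past the threshold it is about to be measured
   against.
2. **DownKMeans** — resize the (unsharpened) thumbnail to 25% per side
   (bilinear), run 2-means on the raw RGB vectors scaled to [0, 1],
   keep the cluster whose center has lower Rec.601 luminance, resize
   the label mask back with nearest-neighbor (so it stays binary) and
   smooth with a 5×5 closing (a median filter is available via
   `DoublePassConfig.smoothing`). Clustering 1/16 of the pixels is what
   keeps the detector fast at full-thumbnail quality for region-scale
   structures.

The fused mask (pixelwise maximum of the passes) gets a final closing
then opening with the 5×5 element. All kernel sizes, the 15-level
spread threshold, the 5000-px minimum area, the 25% scale and the seed
live in `DoublePassConfig`, so alternative constants can be dropped in
without code changes.

### Morphology conventions

Structuring elements are filled squares with odd side (default 5).
Border handling pads each primitive with its neutral element:
background (0) for dilation, foreground (1) for erosion — the
convention of mainstream imaging libraries. Under it, dilation and
erosion are monotone, closing and opening are extensive/anti-extensive
and idempotent, and masks touching the image border are not shaved by
a closing (padding erosion with 0 instead would strip a 2-px frame off
any border-touching region). Connected components use 8-connectivity:
diagonally adjacent tissue fragments count as one component, which
matters for the minimum-area rule on thin or ragged sections.

## Evaluation

Predictions and ground truth are binarized (any value > 0 is tissue);
a prediction whose shape differs from the truth is resized to the
truth's shape with nearest-neighbor interpolation first. From the
pixel confusion counts with tissue positive:
IoU = TP/(TP+FP+FN), Dice = 2TP/(2TP+FP+FN). The identity
Dice = 2·IoU/(1+IoU) holds exactly and is enforced by test. When both
masks are empty both scores are defined as 1.0 — a correctly empty
prediction on a blank slide should not be penalized. The reported
scores are tissue-foreground scores; `per_class_mean` additionally
averages the tissue and background class scores for comparability with
two-class evaluations. Aggregation is the unweighted arithmetic mean
over slides, optionally per cohort. Benchmark runtime is measured
around the detector call only; including file I/O would swamp the
sub-second detection times under comparison, and the docs flag this
whenever timings are compared to externally reported numbers.

## Synthetic scenes

The generator renders what a 10 μm/px H&E thumbnail actually contains,
with an exact ground-truth mask:

- **Tissue blobs**: jittered ellipses (low-order sinusoidal boundary
  modulation), each ≥ 5000 px, merged in the ground truth when they
  overlap. Saturated stain colors are hematoxylin-purple
  (150, 90, 170) ± 20 and eosin-pink (220, 150, 180) ± 10 per-channel
  jitter.
- **Faint tissue**: pale stain (238, 220, 230) — channel spread 18 at
  full strength — interpolated toward the background from 75% of the
  blob radius outward. The spread therefore crosses the 15-level gray
  threshold *inside* the blob: chromatic detectors see the core, a
  global brightness cut usually misses the whole blob. This is the
  fixture-scale analogue of pale necrotic regions.
- **Background**: near-white glass at 245 with σ = 4 Gaussian noise
  applied as luminance noise — the same offset on all three channels —
  so the background is exactly achromatic.
- **Gray artifacts**: rectangles at constant levels 120–200 with
  R = G = B exactly (scanner shadows, coverslip edges). Because both
  the background and the rectangles are achromatic, no pixel in or
  around them can pass the spread test, even after sharpening (a 3×3
  kernel mixing only achromatic neighbors yields an achromatic result).
- **Debris**: chromatic specks, every component < 5000 px, excluded
  from the ground truth. Artifacts and debris keep a 12-px clearance
  from tissue so morphological refinement cannot bridge them to real
  sections; placement uses bounded rejection sampling and fails loudly
  if a scene cannot be packed.

Difficulty presets: `easy` (saturated blobs only), `faint` (60% faint
blobs), `artifact` (gray rectangles + debris), `sparse` (many small
nests). Default frame is 384×384 px ≈ 3.8×3.8 mm, large enough to hold
several ≥5000-px sections while keeping a 20-fixture, 3-detector
benchmark in the tens of seconds on one core. Per-fixture seeds are
spawned from the suite seed via `numpy.random.SeedSequence`, so suites
are reproducible as a whole.

What the scenes do *not* emulate: real staining texture and nuclei
(invisible at this scale anyway), pen marks and blur as distinct
artifact classes, scanner-specific color profiles, and tissue touching
the frame border. Passing on these fixtures demonstrates that each
detector implements its contract (gray rejection, faint-core recovery,
area filtering, fusion) — not that the absolute IoU values transfer to
clinical material, where cohort-dependent staining variability
dominates.

## Thumbnail extraction

From a pyramidal TIFF the extractor picks the coarsest level whose
resolution is still at or finer than the target (default 10 μm/px) and
area-average resizes to the exact scale (anti-aliased bilinear; within
1%). Microns-per-pixel discovery order: vendor `MPP = x` description
tags, then TIFF resolution tags (inch- or centimeter-based), then an
explicit override — with a hard error rather than a guessed scale when
all are absent. Alpha channels are composited over white (transparent
scanner borders are glass), 16-bit samples are rescaled by 1/257, and
grayscale inputs are promoted to RGB. Thumbnails are cached as
lossless PNG.

## Limitations

- The detectors output tissue-versus-background only; artifact
  subclasses (pen ink, blur, folds) are not distinguished, so residual
  chromatic artifacts (e.g. pen marks, which are *not* achromatic) are
  kept as tissue by design of the spread test.
- Faint tissue whose chromatic spread never reaches 15 levels is
  invisible to FilterGrays and, if it is also bright, to both other
  detectors; the hybrid reduces but does not eliminate faint-tissue
  false negatives.
- The 5000-px minimum area is resolution-bound (≈0.5 mm² at 10 μm/px);
  detached micro-islands below it are dropped deliberately.
- Deep-learning detectors are supported only through the registry as
  external callables; no trained weights ship with the package.
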