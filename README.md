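# tissuedetect

Annotation-free tissue detection in whole-slide image (WSI) thumbnails.

Digital-pathology pipelines start by deciding where the tissue is: a
gigapixel H&E scan is mostly blank glass, and every downstream model —
tumor classifiers, artifact QC, foundation-model pre-training — wastes
compute and accumulates false positives unless it is restricted to a
tissue mask. Supervised segmentation models do this well but need
annotated training data and, for fast inference, a GPU. `tissuedetect`
implements three classical, fully unsupervised detectors that operate on
a low-resolution thumbnail (≈10 μm/px, where tissue boundaries survive
but single cells do not), plus the evaluation harness to benchmark them
— or any external detector — against ground-truth masks.

## Detectors

All detectors map an H×W×3 RGB thumbnail to a binary mask (255 = tissue,
0 = background):

- **Global Otsu** (`otsu`): grayscale the thumbnail, find the threshold
  T\* maximizing the between-class variance ω₀ω₁(μ₀−μ₁)² of the
  intensity histogram, mark pixels at or below T\* (stained tissue is
  dark). Parameter-free and very fast; assumes a bimodal histogram.
- **Color-statistics K-means** (`kmeans`): embed each pixel as
  (μ, σ) — mean and population spread of its RGB channels scaled to
  [0, 1] — partition with 2-means, take the lower-μ (darker) cluster as
  tissue, and smooth with 5×5 closing + opening. Sees chromatic texture
  that a single brightness cut misses, at the cost of clustering every
  pixel.
- **Double-Pass** (`doublepass`): a hybrid of two complementary passes
  fused by pixelwise OR. *FilterGrays* sharpens the thumbnail and keeps
  pixels whose channel spread max(R,G,B) − min(R,G,B) exceeds 15
  levels — rejecting achromatic glass, shadows and gray artifacts —
  then closes gaps and drops components under 5000 px (≈0.5 mm² at
  10 μm/px). *DownKMeans* clusters raw RGB vectors at 25% scale and
  keeps the darker cluster. The union recovers faint (pale, low-spread)
  tissue that thresholding misses while staying CPU-cheap.

The metrics are the standard overlap scores with tissue as the positive
class: IoU = TP/(TP+FP+FN) and Dice = 2TP/(2TP+FP+FN) = 2·IoU/(1+IoU),
aggregated as unweighted means over slides.

Because public benchmarks require multi-hundred-gigabyte slide
downloads, the package ships a seeded generator of H&E-like thumbnails
with exact ground-truth masks (stained blobs, faint low-saturation
regions, achromatic gray artifacts, sub-threshold debris) so the whole
pipeline is testable offline.

## Worked example

```sh
python examples/detect_tissue.py
```

```
thumbnail 384x384 at 10.0 um/px, tissue area 36646 px

otsu threshold T* = 192 (tissue = gray <= T*)
      otsu: IoU 0.998  Dice 0.999  (36587 px marked)
    kmeans: IoU 0.999  Dice 1.000  (36663 px marked)
doublepass: IoU 0.982  Dice 0.991  (37234 px marked)
```

On a well-stained scene all three detectors agree with the ground truth
almost perfectly. The interesting case is faint tissue
(`examples/faint_tissue_rescue.py`): pale regions sit near the glass
background in brightness, so Otsu drops them, while their residual
chromatic spread still triggers Double-Pass's gray filter —

```
mean IoU — otsu 0.388, doublepass 0.732
```

`examples/benchmark_suite.py` runs the full benchmark protocol
(per-slide CSV, aggregate CSV, green/pink disagreement overlays) on a
generated suite.

## Command line

```sh
tissuedetect synth --n 20 --difficulty faint --seed 1 --out suite/
tissuedetect run   --method doublepass --input suite/ --out masks/
tissuedetect eval  --pred masks/ --truth suite/ --out scores.csv
tissuedetect bench --input suite/ --truth suite/ \
    --methods otsu,kmeans,doublepass --out results/
tissuedetect thumb --slide scan.svs --mpp-target 10 --out thumb.png
```

`bench` writes `per_slide.csv`, `aggregate.csv`, predicted masks and
overlay PNGs (prediction in translucent green, prediction↔truth
disagreement in pink). External detectors can be registered via
`tissuedetect.register_detector` and benchmarked by name.

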