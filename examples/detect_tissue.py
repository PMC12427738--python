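"""Run the three tissue detectors on one synthetic H&E thumbnail.

Builds a 384×384 thumbnail (≈3.8×3.8 mm at 10 μm/px) with four stained
tissue sections, runs global Otsu, color-statistics K-means and the
Double-Pass hybrid, and reports how well each mask overlaps the exact
ground truth.
"""

from tissuedetect import (
    DoublePassConfig,
    FixtureScene,
    double_pass_detect,
    evaluate_pair,
    generate_fixture,
    kmeans_colorstat_detect,
    otsu_detect,
)

thumb, truth, meta = generate_fixture(FixtureScene(seed=42))
print(f"thumbnail {thumb.shape[1]}x{thumb.shape[0]} at {thumb.mpp} um/px, "
      f"tissue area {int((truth > 0).sum())} px")

otsu = otsu_detect(thumb)
print(f"\notsu threshold T* = {otsu.threshold} (tissue = gray <= T*)")

masks = {
    "otsu": otsu.mask,
    "kmeans": kmeans_colorstat_detect(thumb, seed=42),
    "doublepass": double_pass_detect(thumb, DoublePassConfig(random_seed=42)),
}
for name, mask in masks.items():
    m = evaluate_pair(mask, truth, method=name)
    print(f"{name:>10}: IoU {m.iou:.3f}  Dice {m.dice:.3f}  "
          f"({int((mask > 0).sum())} px marked)")

# IoU is the fraction of the union of predicted and true tissue that both
# agree on; Dice weights the overlap twice. On this saturated, well-stained
# scene every annotation-free detector should land near 1.0.
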