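"""Annotation-free tissue detectors for slide thumbnails.

Three detectors, all mapping a :class:`~tissuedetect.core.Thumbnail` to a
binary tissue mask:

``otsu``
    Global Otsu thresholding on the grayscale thumbnail. Fast,
    parameter-free, assumes a bimodal intensity histogram (dark stained
    tissue vs. bright glass).
``kmeans``
    Color-statistics K-means: each pixel is embedded as (μ, σ) — the
    mean and population spread of its scaled RGB channels — and
    partitioned into two clusters; the darker (lower-μ) cluster is
    tissue. Captures chromatic texture that pure thresholding misses.
``doublepass``
    Hybrid of two complementary passes fused by pixelwise OR: a
    full-resolution chromatic-spread test that rejects achromatic grays
    (glass, shadows, gray artifacts) and a downsampled RGB K-means that
    recovers faint but extended tissue. The union is refined by final
    morphology.

A small registry lets external detectors (e.g. a trained segmentation
model) be benchmarked through the same interface without being
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterator, NamedTuple

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.cluster import KMeans

from .core import (
    GRAY_WEIGHTS,
    StructuringElement,
    Thumbnail,
    as_binary_mask,
    binary_morphology,
    remove_small_objects,
    sharpen,
    to_grayscale,
)

__all__ = [
    "OtsuResult",
    "DoublePassConfig",
    "DoublePassStages",
    "DetectorRegistry",
    "otsu_threshold",
    "otsu_detect",
    "colorstat_features",
    "kmeans_colorstat_detect",
    "filter_grays_pass",
    "down_kmeans_pass",
    "double_pass_stages",
    "double_pass_detect",
    "register_detector",
    "get_detector",
    "builtin_registry",
]


class DegenerateHistogramError(ValueError):
    """Raised when a histogram has fewer than two occupied bins."""


class OtsuResult(NamedTuple):
    """Threshold and mask produced by the global Otsu detector."""

    threshold: int
    mask: np.ndarray


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's optimal threshold from a 256-bin intensity histogram.

    Returns the level ``T*`` maximizing the between-class variance
    ``ω0·ω1·(μ0−μ1)²`` of the split into classes ``{level ≤ T*}`` and
    ``{level > T*}``. Ties are broken toward the lowest qualifying
    threshold.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two bins are occupied (no split exists).
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {hist.shape}")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("histogram has fewer than two occupied bins")

    levels = np.arange(256, dtype=np.float64)
    total = hist.sum()
    w0 = np.cumsum(hist) / total              # weight of class {<= t}
    m = np.cumsum(hist * levels) / total      # partial first moment
    mu_total = m[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m / w0
        mu1 = (mu_total - m) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=0.0)
    return int(np.argmax(sigma_b))            # argmax takes the first (lowest) tie


def otsu_detect(img: Thumbnail) -> OtsuResult:
    """Global Otsu tissue detection on the grayscale thumbnail.

    Stained tissue is darker than the glass background, so pixels at or
    below the Otsu threshold are marked as tissue (255). A uniform
    thumbnail (blank glass) has no split and yields an all-background
    mask with the threshold reported as the single occupied level.
    No morphological post-processing is applied.
    """
    gray = to_grayscale(img)
    hist = np.bincount(gray.ravel(), minlength=256)
    try:
        t = otsu_threshold(hist)
    except DegenerateHistogramError:
        return OtsuResult(int(gray.flat[0]), as_binary_mask(np.zeros(gray.shape, bool)))
    return OtsuResult(t, as_binary_mask(gray <= t))


def colorstat_features(img: Thumbnail) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel color statistics (μ, σ) of the RGB channels scaled to [0, 1].

    μ is the mean brightness of the three channels; σ their population
    standard deviation (ddof=0), a cheap proxy for chromatic texture.
    μ lies in [0, 1] and σ in [0, 0.5] (the maximal spread of three
    values in the unit interval).
    """
    scaled = img.pixels.astype(np.float64) / 255.0
    mu = scaled.mean(axis=2)
    sigma = scaled.std(axis=2)
    return mu, sigma


def _fit_kmeans(features: np.ndarray, seed: int) -> KMeans:
    return KMeans(
        n_clusters=2,
        init="k-means++",
        n_init=10,
        tol=1e-4,
        random_state=seed,
    ).fit(features)


def kmeans_colorstat_detect(
    img: Thumbnail,
    seed: int = 0,
    se: StructuringElement | int = 5,
) -> np.ndarray:
    """Color-statistics K-means tissue detection.

    Pixels are embedded as (μ, σ) features, split into two clusters,
    and the cluster with the lower mean brightness μ is labeled tissue.
    The raw label mask is refined by morphological closing then opening
    with a 5×5 square element. Deterministic given ``seed``. Images
    whose features are all identical (blank glass) yield an
    all-background mask.
    """
    if img.pixels.shape[0] * img.pixels.shape[1] < 2:
        raise ValueError("image must contain at least 2 pixels")
    mu, sigma = colorstat_features(img)
    feats = np.column_stack([mu.ravel(), sigma.ravel()])
    if np.ptp(feats, axis=0).max() == 0.0:
        return as_binary_mask(np.zeros(img.shape, bool))
    km = _fit_kmeans(feats, seed)
    tissue_cluster = int(np.argmin(km.cluster_centers_[:, 0]))
    mask = as_binary_mask((km.labels_ == tissue_cluster).reshape(img.shape))
    mask = binary_morphology(mask, "close", se)
    mask = binary_morphology(mask, "open", se)
    return mask


@dataclass(frozen=True)
class DoublePassConfig:
    """Tunable parameters of the Double-Pass detector.

    Attributes
    ----------
    gray_spread_threshold
        Minimal max−min RGB channel spread (intensity levels, strict)
        for a pixel to count as chromatic tissue in the FilterGrays
        pass. 15 levels rejects uniform grays while keeping faintly
        stained tissue.
    min_object_area
        Components below this pixel area are dropped in the FilterGrays
        pass (strict; exactly this area is kept). 5000 px at 10 μm/px
        ≈ 0.5 mm² of tissue.
    downsample_factor
        Per-side linear scale of the K-means pass (0.25 → clustering on
        1/16 of the pixels, for speed).
    se_side
        Side of the square structuring element used by all morphology.
    random_seed
        Seed for the K-means initialization; fixes the output bit-for-bit.
    smoothing
        How the upsampled K-means mask is smoothed: morphological
        ``"close"`` (default) or ``"median"`` filtering.
    """

    gray_spread_threshold: int = 15
    min_object_area: int = 5000
    downsample_factor: float = 0.25
    se_side: int = 5
    random_seed: int = 0
    smoothing: str = "close"

    def __post_init__(self) -> None:
        if not 0 < self.downsample_factor <= 1:
            raise ValueError("downsample_factor must be in (0, 1]")
        if not 0 <= self.gray_spread_threshold <= 255:
            raise ValueError("gray_spread_threshold must be in [0, 255]")
        if self.min_object_area <= 0:
            raise ValueError("min_object_area must be positive")
        if self.smoothing not in ("close", "median"):
            raise ValueError("smoothing must be 'close' or 'median'")
        StructuringElement(self.se_side)  # validates oddness

    def with_seed(self, seed: int) -> "DoublePassConfig":
        return replace(self, random_seed=seed)


class DoublePassStages(NamedTuple):
    """Intermediate and final masks of the Double-Pass pipeline."""

    filter_grays: np.ndarray
    down_kmeans: np.ndarray
    fused: np.ndarray
    final: np.ndarray


def filter_grays_pass(img: Thumbnail, cfg: DoublePassConfig | None = None) -> np.ndarray:
    """Chromatic-spread pass of Double-Pass.

    Sharpens the thumbnail to enhance edges, marks pixels whose RGB
    channel spread max(R,G,B) − min(R,G,B) strictly exceeds the gray
    threshold (rejecting uniform grays: glass, shadows, achromatic
    artifacts), closes small gaps, and removes components below the
    minimum area.
    """
    cfg = cfg or DoublePassConfig()
    sharp = sharpen(img).pixels.astype(np.int16)
    spread = sharp.max(axis=2) - sharp.min(axis=2)
    mask = as_binary_mask(spread > cfg.gray_spread_threshold)
    mask = binary_morphology(mask, "close", cfg.se_side)
    return remove_small_objects(mask, cfg.min_object_area)


def down_kmeans_pass(img: Thumbnail, cfg: DoublePassConfig | None = None) -> np.ndarray:
    """Downsampled K-means pass of Double-Pass.

    Resizes the thumbnail to ``downsample_factor`` per side (bilinear),
    clusters the raw RGB vectors into two groups, labels the cluster
    with the lower mean luminance as tissue, resizes the label mask
    back to full resolution (nearest-neighbor, so it stays binary) and
    smooths it. Constant images yield an all-background mask.
    """
    cfg = cfg or DoublePassConfig()
    h, w = img.shape
    dh = max(1, round(h * cfg.downsample_factor))
    dw = max(1, round(w * cfg.downsample_factor))
    if dh * dw < 2:
        raise ValueError("downsampled image must contain at least 2 pixels")
    small = _sk_resize(
        img.pixels.astype(np.float64),
        (dh, dw),
        order=1,
        anti_aliasing=False,
        preserve_range=True,
    )
    rgb = small.reshape(-1, 3) / 255.0
    if np.ptp(rgb, axis=0).max() == 0.0:
        return as_binary_mask(np.zeros((h, w), bool))
    km = _fit_kmeans(rgb, cfg.random_seed)
    luminance = km.cluster_centers_ @ GRAY_WEIGHTS
    tissue_cluster = int(np.argmin(luminance))
    small_mask = (km.labels_ == tissue_cluster).reshape(dh, dw)
    full = _sk_resize(
        small_mask.astype(np.uint8), (h, w), order=0, anti_aliasing=False,
        preserve_range=True,
    ) > 0
    mask = as_binary_mask(full)
    if cfg.smoothing == "close":
        mask = binary_morphology(mask, "close", cfg.se_side)
    else:
        from skimage.filters import median as _sk_median
        from skimage.morphology import footprint_rectangle

        fp = footprint_rectangle((cfg.se_side, cfg.se_side))
        mask = as_binary_mask(_sk_median(mask, fp))
    return mask


def double_pass_stages(img: Thumbnail, cfg: DoublePassConfig | None = None) -> DoublePassStages:
    """Run Double-Pass and return every stage.

    The fused mask is the pixelwise union (logical OR) of the two
    passes; the final mask applies closing then opening with the
    configured square element.
    """
    cfg = cfg or DoublePassConfig()
    fg = filter_grays_pass(img, cfg)
    dk = down_kmeans_pass(img, cfg)
    fused = np.maximum(fg, dk)
    final = binary_morphology(fused, "close", cfg.se_side)
    final = binary_morphology(final, "open", cfg.se_side)
    return DoublePassStages(fg, dk, fused, final)


def double_pass_detect(img: Thumbnail, cfg: DoublePassConfig | None = None) -> np.ndarray:
    """Double-Pass hybrid tissue detection (chromatic pass ∪ K-means pass)."""
    return double_pass_stages(img, cfg).final


# ---------------------------------------------------------------------------
# Registry

Detector = Callable[[Thumbnail, int], np.ndarray]


class DetectorRegistry:
    """Name → detector mapping; built-ins are always present.

    A detector is a callable ``fn(img, seed) -> mask``. External
    methods (e.g. a trained deep segmentation model driven through a
    subprocess) can be registered and benchmarked like the built-ins.
    """

    def __init__(self) -> None:
        self._detectors: dict[str, Detector] = {}
        self._register_builtins()

    def _register_builtins(self) -> None:
        self._detectors["otsu"] = lambda img, seed=0: otsu_detect(img).mask
        self._detectors["kmeans"] = lambda img, seed=0: kmeans_colorstat_detect(img, seed=seed)
        self._detectors["doublepass"] = lambda img, seed=0: double_pass_detect(
            img, DoublePassConfig(random_seed=seed)
        )

    def register(self, name: str, fn: Detector) -> None:
        if name in self._detectors:
            raise ValueError(f"detector {name!r} is already registered")
        self._detectors[name] = fn

    def resolve(self, name: str) -> Detector:
        try:
            return self._detectors[name]
        except KeyError:
            raise KeyError(
                f"unknown detector {name!r}; registered: {sorted(self._detectors)}"
            ) from None

    def names(self) -> list[str]:
        return sorted(self._detectors)

    def __contains__(self, name: str) -> bool:
        return name in self._detectors

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._detectors))


#: Process-wide default registry holding the built-in detectors.
builtin_registry = DetectorRegistry()


def register_detector(name: str, fn: Detector) -> DetectorRegistry:
    """Register an external detector in the default registry."""
    builtin_registry.register(name, fn)
    return builtin_registry


def get_detector(name: str) -> Detector:
    """Resolve a detector by name from the default registry."""
    return builtin_registry.resolve(name)
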