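"""Thumbnail extraction and raster I/O.

Whole-slide scans are pyramidal TIFFs whose level-0 resolution is
typically ~0.25 μm/px (40× objective). Tissue detection operates on an
RGB thumbnail at 10 μm/px, which preserves tissue boundaries and gross
artifacts while cutting data volume by orders of magnitude. This module
derives that thumbnail from a pyramid (reading the smallest level that
is still finer than the target and area-average resizing to the exact
scale) and round-trips thumbnails and masks through standard raster
formats.

The physical scale (microns per pixel, mpp) is discovered in order:
vendor description tags (Aperio-style ``MPP = x``), then TIFF
resolution tags, then an explicit user override — and the extraction
fails loudly rather than guessing when none is available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from skimage.transform import resize as _sk_resize

from .core import Thumbnail, as_binary_mask, validate_mask

__all__ = [
    "SlideRef",
    "compute_scale_factor",
    "extract_thumbnail",
    "load_thumbnail",
    "load_mask",
    "write_mask",
    "write_thumbnail",
    "MissingMppError",
]

DEFAULT_TARGET_MPP = 10.0


class MissingMppError(ValueError):
    """The slide carries no resolution metadata and no override was given."""


@dataclass(frozen=True)
class SlideRef:
    """Reference to a pyramidal slide file.

    ``base_mpp`` overrides (or supplies, when metadata is absent) the
    microns-per-pixel of pyramid level 0.
    """

    path: str | Path
    base_mpp: float | None = None

    def __post_init__(self) -> None:
        if self.base_mpp is not None and not self.base_mpp > 0:
            raise ValueError(f"base_mpp must be positive, got {self.base_mpp}")


def compute_scale_factor(base_mpp: float, target_mpp: float) -> float:
    """Linear downsampling factor from a base to a target resolution.

    E.g. a 0.25 μm/px scan thumbnailed at 10 μm/px is downsampled 40×
    per side.
    """
    if not (base_mpp > 0 and target_mpp > 0):
        raise ValueError("microns-per-pixel values must be positive")
    return target_mpp / base_mpp


_MPP_RE = re.compile(r"MPP\s*=\s*([0-9]*\.?[0-9]+)", re.IGNORECASE)


def _mpp_from_description(page: "tifffile.TiffPage") -> float | None:
    desc = page.description or ""
    m = _MPP_RE.search(desc)
    return float(m.group(1)) if m else None


def _mpp_from_resolution_tags(page: "tifffile.TiffPage") -> float | None:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0 or den == 0:
        return None
    pixels_per_unit = num / den
    unit = tags["ResolutionUnit"].value
    unit = getattr(unit, "value", unit)  # enum or raw int
    if unit == 2:  # inch
        microns_per_unit = 25400.0
    elif unit == 3:  # centimeter
        microns_per_unit = 10000.0
    else:
        return None
    return microns_per_unit / pixels_per_unit


def _to_rgb(arr: np.ndarray) -> np.ndarray:
    """Promote grayscale, composite alpha over white, rescale 16-bit."""
    if arr.dtype == np.uint16:
        arr = np.rint(arr / 257.0).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        rgb = arr[:, :, :3].astype(np.float64)
        alpha = arr[:, :, 3:4].astype(np.float64) / 255.0
        arr = np.rint(rgb * alpha + 255.0 * (1.0 - alpha)).astype(np.uint8)
    return np.ascontiguousarray(arr[:, :, :3]).astype(np.uint8)


def extract_thumbnail(
    slide: SlideRef | str | Path,
    target_mpp: float = DEFAULT_TARGET_MPP,
) -> Thumbnail:
    """Extract an RGB thumbnail at ``target_mpp`` from a pyramidal slide.

    Reads the smallest pyramid level whose resolution is still at or
    finer than the target, then area-average resizes to the exact
    target scale (within 1%). Raises :class:`MissingMppError` when the
    file has no usable resolution metadata and ``base_mpp`` was not
    supplied.
    """
    if not isinstance(slide, SlideRef):
        slide = SlideRef(slide)
    if not target_mpp > 0:
        raise ValueError("target_mpp must be positive")
    path = Path(slide.path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        base_page = series.pages[0]
        base_mpp = slide.base_mpp
        if base_mpp is None:
            base_mpp = _mpp_from_description(base_page)
        if base_mpp is None:
            base_mpp = _mpp_from_resolution_tags(base_page)
        if base_mpp is None:
            raise MissingMppError(
                f"{path}: no mpp metadata found; pass --mpp / base_mpp explicitly"
            )
        levels = getattr(series, "levels", None) or [series]
        base_w = levels[0].shape[1]
        # choose the smallest (coarsest) level still finer than the target
        chosen = None
        chosen_mpp = None
        for lvl in levels:
            h, w = lvl.shape[0], lvl.shape[1]
            lvl_mpp = base_mpp * (base_w / w)
            if lvl_mpp <= target_mpp and (chosen is None or lvl_mpp > chosen_mpp):
                chosen, chosen_mpp = lvl, lvl_mpp
        if chosen is None:  # pyramid entirely coarser than target: use level 0
            chosen, chosen_mpp = levels[0], base_mpp
        arr = _to_rgb(np.asarray(chosen.asarray()))
    factor = compute_scale_factor(chosen_mpp, target_mpp)
    chosen_w = arr.shape[1]
    out_h = max(1, round(arr.shape[0] / factor))
    out_w = max(1, round(arr.shape[1] / factor))
    if (out_h, out_w) != arr.shape[:2]:
        resized = _sk_resize(
            arr.astype(np.float64), (out_h, out_w), order=1,
            anti_aliasing=factor > 1, preserve_range=True,
        )
        arr = np.clip(np.rint(resized), 0, 255).astype(np.uint8)
    achieved_mpp = chosen_mpp * (chosen_w / arr.shape[1])
    return Thumbnail(arr, mpp=float(achieved_mpp), source_id=path.stem)


def load_thumbnail(path: str | Path, mpp: float = DEFAULT_TARGET_MPP) -> Thumbnail:
    """Load a PNG/JPEG/TIFF raster as an 8-bit RGB thumbnail.

    Grayscale images are promoted to RGB, alpha is composited over
    white, and 16-bit samples are rescaled to 8-bit.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=np.uint32)
                arr = np.rint(arr / 257.0).clip(0, 255).astype(np.uint8)
            elif im.mode in ("RGBA", "LA", "PA", "P"):
                arr = np.asarray(im.convert("RGBA"))
            else:
                arr = np.asarray(im.convert("RGB") if im.mode not in ("L", "RGB") else im)
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return Thumbnail(_to_rgb(arr), mpp=mpp, source_id=path.stem)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary tissue mask from a single-channel raster."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except OSError as exc:
        raise OSError(f"cannot read mask {path}: {exc}") from exc
    return as_binary_mask(arr)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a {0,255} mask as a single-channel 8-bit PNG."""
    mask = validate_mask(mask)
    path = Path(path)
    Image.fromarray(mask.astype(np.uint8), mode="L").save(path)
    return path


def write_thumbnail(img: Thumbnail, path: str | Path) -> Path:
    """Write a thumbnail as an RGB raster (format from the extension)."""
    path = Path(path)
    Image.fromarray(img.pixels, mode="RGB").save(path)
    return path
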