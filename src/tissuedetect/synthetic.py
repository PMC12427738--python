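"""Seeded generator of H&E-like thumbnails with exact ground-truth masks.

Real slide thumbnails at 10 μm/px show stained tissue sections (purple
hematoxylin, pink eosin, sometimes very faint low-saturation regions
such as pale necrosis), a near-white glass background, occasional
achromatic gray artifacts (scanner shadows, coverslip edges) and small
chromatic debris. This module renders parametric scenes with those
ingredients and returns the exact tissue mask alongside, so detectors
and metrics can be exercised end-to-end without any slide downloads.

Design choices worth knowing when reading tests built on these scenes:

* Background noise is luminance noise — the same Gaussian offset is
  added to all three channels — so background and gray artifacts are
  exactly achromatic (R=G=B). Chromatic clutter comes only from debris
  specks.
* Tissue blobs are jittered ellipses; overlapping blobs merge in the
  ground truth. Every tissue blob has area ≥ 5000 px and every debris
  speck area < 5000 px, bracketing the small-object rule.
* Faint blobs interpolate from a pale low-spread stain color in the
  core toward the background at the rim, so their RGB channel spread
  crosses the 15-level gray threshold inside the blob: a chromatic
  detector sees the core, a global intensity threshold usually misses
  the whole blob.
* Gray artifacts and debris keep a clearance margin from tissue so
  morphological refinement cannot bridge them to real tissue.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.measure import label as _sk_label

from .core import Thumbnail, as_binary_mask
from .thumbnails import write_mask, write_thumbnail

__all__ = [
    "FixtureScene",
    "GenerationError",
    "PRESETS",
    "generate_fixture",
    "generate_scenes",
    "generate_suite",
]

#: Saturated H&E stain means (RGB) with their per-pixel jitter scale.
SATURATED_PALETTE: tuple[tuple[tuple[int, int, int], float], ...] = (
    ((150, 90, 170), 20.0),   # hematoxylin purple
    ((220, 150, 180), 10.0),  # eosin pink
)

#: Faint (pale, low-spread) stain mean; channel spread 18 at full strength.
FAINT_COLOR: tuple[int, int, int] = (238, 220, 230)

#: Radius (relative to the blob boundary) inside which a faint blob is at
#: full stain strength; strength ramps linearly to 0 at the boundary.
FAINT_CORE_RHO = 0.75

#: Clearance (px) kept between tissue and artifacts/debris.
CLEARANCE = 12

MIN_BLOB_AREA = 5000
MAX_DEBRIS_AREA = 4999


class GenerationError(RuntimeError):
    """Scene could not be packed within the retry budget."""


@dataclass(frozen=True)
class FixtureScene:
    """Parametric description of one synthetic thumbnail.

    The defaults render a moderately cellular 384×384 (≈3.8×3.8 mm at
    10 μm/px) thumbnail with saturated tissue only; presets in
    :data:`PRESETS` override them per difficulty.
    """

    width: int = 384
    height: int = 384
    n_tissue_blobs: int = 4
    blob_radius_range: tuple[int, int] = (45, 70)
    faint_fraction: float = 0.0
    n_gray_artifacts: int = 0
    n_debris: int = 0
    background_level: int = 245
    background_noise: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("scene must be at least 32×32")
        lo, hi = self.blob_radius_range
        if not 0 < lo <= hi:
            raise ValueError("invalid blob radius range")
        if not 0.0 <= self.faint_fraction <= 1.0:
            raise ValueError("faint_fraction must be in [0, 1]")


#: Difficulty presets. ``easy`` = saturated blobs only; ``faint`` = mostly
#: pale low-spread tissue; ``artifact`` = achromatic rectangles and debris
#: present; ``sparse`` = many small (but ≥5000 px) tissue nests.
PRESETS: dict[str, FixtureScene] = {
    "easy": FixtureScene(n_tissue_blobs=4, faint_fraction=0.0),
    "faint": FixtureScene(n_tissue_blobs=5, faint_fraction=0.6,
                          blob_radius_range=(52, 70)),
    "artifact": FixtureScene(n_tissue_blobs=3, n_gray_artifacts=3, n_debris=4),
    "sparse": FixtureScene(n_tissue_blobs=9, blob_radius_range=(42, 50)),
}


def _blob_mask(
    rng: np.random.Generator,
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    angle: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one jittered ellipse.

    Returns the boolean mask and the normalized radius field ρ (1 on the
    jittered boundary) clipped to the frame.
    """
    h, w = shape
    cy, cx = center
    a, b = radii
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (dx * ca + dy * sa) / a
    v = (-dx * sa + dy * ca) / b
    rho = np.sqrt(u * u + v * v)
    # low-order boundary jitter: smooth, closed, small amplitude
    phi = np.arctan2(v, u)
    amp = rng.uniform(0.03, 0.08, size=2)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    boundary = 1.0 + amp[0] * np.sin(2 * phi + phase[0]) + amp[1] * np.sin(3 * phi + phase[1])
    inside = rho <= boundary
    return inside, np.divide(rho, boundary, out=np.ones_like(rho), where=boundary > 0)


def _paint_saturated(
    rng: np.random.Generator,
    canvas: np.ndarray,
    mask: np.ndarray,
    color: tuple[int, int, int],
    jitter: float,
) -> None:
    n = int(mask.sum())
    base = np.array(color, dtype=np.float64)
    px = base + rng.normal(0.0, jitter, size=(n, 3))
    canvas[mask] = np.clip(np.rint(px), 0, 255).astype(np.uint8)


def _paint_faint(
    rng: np.random.Generator,
    canvas: np.ndarray,
    mask: np.ndarray,
    rho: np.ndarray,
    background: np.ndarray,
) -> None:
    # stain strength 1 in the core, linear ramp to 0 at the boundary
    w = np.clip((1.0 - rho[mask]) / (1.0 - FAINT_CORE_RHO), 0.0, 1.0)
    stain = np.array(FAINT_COLOR, dtype=np.float64)
    bg = background[mask].astype(np.float64)
    px = bg * (1.0 - w[:, None]) + stain[None, :] * w[:, None]
    # achromatic per-pixel jitter so the channel spread stays controlled
    px += rng.normal(0.0, 2.0, size=(px.shape[0], 1))
    canvas[mask] = np.clip(np.rint(px), 0, 255).astype(np.uint8)


def _place_rect(
    rng: np.random.Generator,
    shape: tuple[int, int],
    forbidden: np.ndarray,
    side_range: tuple[int, int],
    max_tries: int,
) -> tuple[slice, slice] | None:
    h, w = shape
    for _ in range(max_tries):
        rh = int(rng.integers(*side_range))
        rw = int(rng.integers(*side_range))
        if rh + 2 > h or rw + 2 > w:
            continue
        y0 = int(rng.integers(1, h - rh))
        x0 = int(rng.integers(1, w - rw))
        ys = slice(max(0, y0 - CLEARANCE), min(h, y0 + rh + CLEARANCE))
        xs = slice(max(0, x0 - CLEARANCE), min(w, x0 + rw + CLEARANCE))
        if not forbidden[ys, xs].any():
            return slice(y0, y0 + rh), slice(x0, x0 + rw)
    return None


def generate_fixture(
    scene: FixtureScene,
) -> tuple[Thumbnail, np.ndarray, dict]:
    """Render one scene; returns (thumbnail, ground-truth mask, metadata).

    Deterministic given ``scene.seed``. The ground truth is the union
    of tissue blobs only — gray artifacts and debris are excluded.
    Metadata records the connected-component areas of the ground truth,
    the bounding boxes of gray artifacts, debris areas and the palette.

    Raises :class:`GenerationError` when artifacts or debris cannot be
    placed clear of tissue within a bounded number of retries.
    """
    rng = np.random.default_rng(scene.seed)
    h, w = scene.height, scene.width
    shape = (h, w)

    # achromatic background: one luminance noise field shared by all channels
    lum = np.clip(
        np.rint(scene.background_level + rng.normal(0.0, scene.background_noise, shape)),
        0, 255,
    ).astype(np.uint8)
    canvas = np.stack([lum] * 3, axis=-1)
    background = canvas.copy()

    gt = np.zeros(shape, dtype=bool)
    lo, hi = scene.blob_radius_range
    n_faint = int(round(scene.n_tissue_blobs * scene.faint_fraction))
    blob_kinds = ["faint"] * n_faint + ["saturated"] * (scene.n_tissue_blobs - n_faint)
    rng.shuffle(blob_kinds)

    blob_records = []
    for kind in blob_kinds:
        for _ in range(200):
            a = rng.uniform(lo, hi)
            b = rng.uniform(max(lo, 0.7 * a), a)
            margin = hi * 1.1
            cy = rng.uniform(margin, h - margin) if h > 2 * margin else h / 2
            cx = rng.uniform(margin, w - margin) if w > 2 * margin else w / 2
            angle = rng.uniform(0, np.pi)
            mask, rho = _blob_mask(rng, shape, (cy, cx), (a, b), angle)
            if int(mask.sum()) >= MIN_BLOB_AREA:
                break
        else:
            raise GenerationError("could not place a tissue blob of sufficient area")
        if kind == "saturated":
            color, jitter = SATURATED_PALETTE[int(rng.integers(len(SATURATED_PALETTE)))]
            _paint_saturated(rng, canvas, mask, color, jitter)
        else:
            _paint_faint(rng, canvas, mask, rho, background)
        gt |= mask
        blob_records.append({"kind": kind, "area": int(mask.sum())})

    artifact_boxes = []
    for _ in range(scene.n_gray_artifacts):
        box = _place_rect(rng, shape, gt, (30, 90), max_tries=200)
        if box is None:
            raise GenerationError("could not place a gray artifact clear of tissue")
        ys, xs = box
        level = int(rng.integers(120, 201))
        canvas[ys, xs] = level  # exactly achromatic
        artifact_boxes.append((ys.start, ys.stop, xs.start, xs.stop))

    debris_areas = []
    occupied = gt.copy()
    for y0, y1, x0, x1 in artifact_boxes:
        occupied[y0:y1, x0:x1] = True
    for _ in range(scene.n_debris):
        for _ in range(200):
            r = rng.uniform(5, 15)
            cy = rng.uniform(r + 1, h - r - 1)
            cx = rng.uniform(r + 1, w - r - 1)
            mask, _ = _blob_mask(rng, shape, (cy, cx), (r, r * rng.uniform(0.7, 1.0)),
                                 rng.uniform(0, np.pi))
            area = int(mask.sum())
            if area == 0 or area > MAX_DEBRIS_AREA:
                continue
            grown = binary_dilation(mask, np.ones((2 * CLEARANCE + 1,) * 2, bool))
            if not (grown & occupied).any():
                break
        else:
            raise GenerationError("could not place debris clear of tissue/artifacts")
        _paint_saturated(rng, canvas, mask, (200, 168, 185), 8.0)
        occupied |= mask
        debris_areas.append(area)

    labels = _sk_label(gt, connectivity=2)
    component_areas = np.bincount(labels.ravel())[1:].tolist()

    meta = {
        "seed": scene.seed,
        "blobs": blob_records,
        "component_areas": [int(a) for a in component_areas],
        "artifact_boxes": artifact_boxes,
        "debris_areas": debris_areas,
        "palette": {"saturated": SATURATED_PALETTE, "faint": FAINT_COLOR},
    }
    thumb = Thumbnail(canvas, mpp=10.0, source_id=f"synthetic-{scene.seed}")
    return thumb, as_binary_mask(gt), meta


def generate_scenes(
    n: int,
    difficulty: str = "easy",
    seed: int = 0,
) -> Iterator[tuple[str, Thumbnail, np.ndarray, dict]]:
    """Yield ``n`` (slide_id, thumbnail, mask, metadata) fixtures.

    Per-fixture seeds are spawned deterministically from ``seed``, so a
    suite is reproducible as a whole while fixtures differ.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    try:
        base = PRESETS[difficulty]
    except KeyError:
        raise ValueError(
            f"unknown difficulty {difficulty!r}; choose from {sorted(PRESETS)}"
        ) from None
    children = np.random.SeedSequence(seed).spawn(n)
    for i, child in enumerate(children):
        fixture_seed = int(child.generate_state(1)[0] % (2**31))
        scene = replace(base, seed=fixture_seed)
        thumb, mask, meta = generate_fixture(scene)
        slide_id = f"{difficulty}_{i:03d}"
        thumb = Thumbnail(thumb.pixels, mpp=thumb.mpp, source_id=slide_id)
        yield slide_id, thumb, mask, meta


def generate_suite(
    n: int,
    difficulty: str,
    seed: int,
    out_dir: str | Path,
) -> Path:
    """Write ``n`` paired ``<id>_img.png`` / ``<id>_mask.png`` files.

    A ``manifest.csv`` (slide_id, difficulty, seed) accompanies them.
    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slide_id", "difficulty", "seed"])
        for slide_id, thumb, mask, meta in generate_scenes(n, difficulty, seed):
            write_thumbnail(thumb, out / f"{slide_id}_img.png")
            write_mask(mask, out / f"{slide_id}_mask.png")
            writer.writerow([slide_id, difficulty, meta["seed"]])
    return manifest
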