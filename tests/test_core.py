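"""Raster primitives: grayscale, sharpening, morphology, component filtering."""

import numpy as np
import pytest

from tissuedetect.core import (
    StructuringElement,
    Thumbnail,
    binary_morphology,
    remove_small_objects,
    sharpen,
    to_grayscale,
)

from conftest import random_binary_mask


def _rgb(value, shape=(4, 4)):
    return np.full(shape + (3,), 0, np.uint8) + np.array(value, np.uint8)


# ---------------------------------------------------------------------------
# independent oracles

def _morph_oracle(mask: np.ndarray, op: str, side: int) -> np.ndarray:
    """Naive dilation/erosion by explicit neighborhood scan.

    The border is padded with each primitive's neutral element: 0 for
    dilation, 1 for erosion.
    """
    h, w = mask.shape
    r = side // 2
    padded = np.full((h + 2 * r, w + 2 * r), op == "erode", bool)
    padded[r : r + h, r : r + w] = mask > 0
    out = np.zeros((h, w), bool)
    for y in range(h):
        for x in range(w):
            window = padded[y : y + side, x : x + side]
            out[y, x] = window.any() if op == "dilate" else window.all()
    return np.where(out, 255, 0).astype(np.uint8)


def _flood_fill_areas(mask: np.ndarray) -> list[int]:
    """Component areas by BFS flood fill with 8-connectivity."""
    m = mask > 0
    seen = np.zeros_like(m)
    areas = []
    h, w = m.shape
    for sy in range(h):
        for sx in range(w):
            if m[sy, sx] and not seen[sy, sx]:
                stack = [(sy, sx)]
                seen[sy, sx] = True
                area = 0
                while stack:
                    y, x = stack.pop()
                    area += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx < w and m[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                areas.append(area)
    return areas


# ---------------------------------------------------------------------------
# Thumbnail contract

def test_thumbnail_rejects_bad_shapes_and_scale():
    with pytest.raises(ValueError):
        Thumbnail(np.zeros((4, 4), np.uint8))
    with pytest.raises(ValueError):
        Thumbnail(np.zeros((4, 4, 4), np.uint8))
    with pytest.raises(ValueError):
        Thumbnail(np.zeros((4, 4, 3), np.uint8), mpp=0.0)


# ---------------------------------------------------------------------------
# grayscale

@pytest.mark.parametrize(
    "color,expected",
    [
        ((255, 255, 255), 255),  # weights sum to 1
        ((0, 0, 0), 0),
        ((255, 0, 0), 76),       # round(0.299*255)
        ((0, 255, 0), 150),      # round(0.587*255)
        ((0, 0, 255), 29),       # round(0.114*255)
    ],
)
def test_grayscale_rec601_weights(color, expected):
    gray = to_grayscale(_rgb(color))
    assert gray.dtype == np.uint8
    assert (gray == expected).all()


def test_grayscale_rejects_non_rgb():
    with pytest.raises(ValueError):
        to_grayscale(np.zeros((4, 4), np.uint8))


# ---------------------------------------------------------------------------
# sharpening

def test_sharpen_constant_image_unchanged():
    img = Thumbnail(_rgb((37, 120, 210), (6, 7)))
    assert np.array_equal(sharpen(img).pixels, img.pixels)


def test_sharpen_saturated_image_clips_to_255():
    img = Thumbnail(_rgb((255, 255, 255), (5, 5)))
    assert (sharpen(img).pixels == 255).all()


def test_sharpen_bright_pixel_on_flat_field():
    # 5×5 field at 10 with one pixel at 200; out = 5c − (4-neighbor sum),
    # hand-computed: center boosted (→255 after clipping), 4-neighbors
    # driven negative (→0), diagonals untouched.
    px = np.full((5, 5, 3), 10, np.uint8)
    px[2, 2] = 200
    out = sharpen(Thumbnail(px)).pixels
    expected = np.full((5, 5), 10, np.uint8)
    expected[2, 2] = 255          # 5*200 - 4*10 = 960 → clip
    for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        expected[2 + dy, 2 + dx] = 0  # 5*10 - (3*10 + 200) = -180 → clip
    assert np.array_equal(out[:, :, 0], expected)
    assert np.array_equal(out[:, :, 1], expected)


# ---------------------------------------------------------------------------
# binary morphology

@pytest.mark.parametrize("op", ["dilate", "erode", "close", "open"])
def test_morphology_empty_mask_stays_empty(op):
    mask = np.zeros((10, 10), np.uint8)
    assert (binary_morphology(mask, op) == 0).all()


def test_dilate_single_pixel_gives_square_block():
    mask = np.zeros((9, 9), np.uint8)
    mask[4, 4] = 255
    out = binary_morphology(mask, "dilate", 5)
    expected = np.zeros((9, 9), np.uint8)
    expected[2:7, 2:7] = 255
    assert np.array_equal(out, expected)


def test_dilate_clips_at_borders():
    mask = np.zeros((5, 5), np.uint8)
    mask[0, 0] = 255
    out = binary_morphology(mask, "dilate", 5)
    expected = np.zeros((5, 5), np.uint8)
    expected[0:3, 0:3] = 255
    assert np.array_equal(out, expected)


def test_close_fills_two_pixel_gap():
    # two blocks separated by a 2-px gap on a 10×10 grid; compared against
    # the naive neighborhood-scan oracle
    mask = np.zeros((10, 10), np.uint8)
    mask[2:8, 1:4] = 255
    mask[2:8, 6:9] = 255
    out = binary_morphology(mask, "close", 5)
    expected = _morph_oracle(_morph_oracle(mask, "dilate", 5), "erode", 5)
    assert np.array_equal(out, expected)
    assert (out[3:7, 4:6] == 255).all()  # the gap is filled


@pytest.mark.parametrize("op", ["dilate", "erode"])
def test_primitives_match_neighborhood_oracle(op):
    rng = np.random.default_rng(3)
    for _ in range(10):
        mask = random_binary_mask(rng, (16, 16))
        assert np.array_equal(binary_morphology(mask, op, 5), _morph_oracle(mask, op, 5))


def test_even_sided_element_rejected():
    with pytest.raises(ValueError):
        StructuringElement(4)
    with pytest.raises(ValueError):
        binary_morphology(np.zeros((5, 5), np.uint8), "dilate", 4)


def test_morphology_invariants_on_random_masks():
    # idempotence of open/close, monotonicity of dilate/erode, {0,255} outputs
    rng = np.random.default_rng(7)
    for _ in range(40):
        mask = random_binary_mask(rng)
        opened = binary_morphology(mask, "open")
        closed = binary_morphology(mask, "close")
        assert np.array_equal(binary_morphology(opened, "open"), opened)
        assert np.array_equal(binary_morphology(closed, "close"), closed)
        dilated = binary_morphology(mask, "dilate")
        eroded = binary_morphology(mask, "erode")
        assert (dilated >= mask).all()
        assert (eroded <= mask).all()
        for out in (opened, closed, dilated, eroded):
            assert set(np.unique(out)) <= {0, 255}


# ---------------------------------------------------------------------------
# small-object removal

def _blob(area: int, shape=(120, 120), origin=(10, 10)) -> np.ndarray:
    """A compact rectilinear component of exactly `area` pixels."""
    mask = np.zeros(shape, np.uint8)
    side = int(np.sqrt(area))
    y, x = origin
    mask[y : y + side, x : x + side] = 255
    rem = area - side * side
    if rem:
        mask[y + side, x : x + rem] = 255
    assert (mask > 0).sum() == area
    return mask


def test_component_below_threshold_removed():
    assert (remove_small_objects(_blob(4999), 5000) == 0).all()


def test_component_at_threshold_retained():
    mask = _blob(5000)
    assert np.array_equal(remove_small_objects(mask, 5000), mask)


def test_remove_small_objects_empty_and_errors():
    empty = np.zeros((8, 8), np.uint8)
    assert (remove_small_objects(empty, 10) == 0).all()
    with pytest.raises(ValueError):
        remove_small_objects(empty, 0)


def test_retained_area_matches_flood_fill_oracle():
    rng = np.random.default_rng(21)
    for _ in range(8):
        mask = random_binary_mask(rng, (64, 64), density=0.35)
        min_area = int(rng.integers(2, 40))
        out = remove_small_objects(mask, min_area)
        assert (out <= mask).all()  # output ⊆ input
        areas = _flood_fill_areas(mask)
        expected_area = sum(a for a in areas if a >= min_area)
        assert (out > 0).sum() == expected_area
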