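"""Pad, tile, shift, mirror, and contrast-jitter images into 224x224 patches.

The detection backbone consumes fixed 224x224 inputs, so full-resolution
fundus photographs are first padded with black rows/columns on the right
and bottom until both dimensions are multiples of 224 (original pixels are
never resized or moved, keeping mask coordinates valid), then cut into a
non-overlapping grid. Training-time augmentation adds three half-stride
shifted grids, three mirrored copies per patch, and a random contrast /
brightness jitter that leaves the black background untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np

from ._utils import as_rng
from .geometry import BoundingBox

TILE = 224
#: Pixels whose brightest channel is at or below this are treated as
#: background: near-black rather than exactly zero, tolerating the
#: compression artefacts typical of clinical photographs.
DEFAULT_BLACK_THRESHOLD = 10


@dataclass(frozen=True)
class Patch:
    """A 224x224 crop with exact provenance bookkeeping.

    origin is the (x0, y0) of the crop in padded-image coordinates;
    provenance is one of {original, shifted, mirrored, jittered}.
    """

    pixels: np.ndarray
    origin: Tuple[int, int]
    source_id: str
    provenance: str = "original"

    def __post_init__(self) -> None:
        if self.pixels.shape != (TILE, TILE, 3):
            raise ValueError(f"patch pixels must be {TILE}x{TILE}x3, got {self.pixels.shape}")
        if self.origin[0] < 0 or self.origin[1] < 0:
            raise ValueError(f"patch origin must be non-negative, got {self.origin}")

    @property
    def window(self) -> BoundingBox:
        """The patch footprint as a box in padded-image coordinates."""
        x0, y0 = self.origin
        return BoundingBox(x0, y0, x0 + TILE, y0 + TILE)


@dataclass(frozen=True)
class PaddedImage:
    """An image enlarged with black fill to multiples of the tile size."""

    pixels: np.ndarray
    pad_right: int
    pad_bottom: int
    original_size: Tuple[int, int]  # (W, H)
    source_id: str = "image"

    @property
    def size(self) -> Tuple[int, int]:
        """(W', H') of the padded pixel array."""
        return self.pixels.shape[1], self.pixels.shape[0]


def pad_to_multiple(image: np.ndarray, tile: int = TILE, source_id: str = "image") -> PaddedImage:
    """Pad an H x W x 3 image with black rows/columns to tile multiples.

    The enlargement is minimal, appended on the right and bottom only, so
    original pixel coordinates are unchanged; an image already at a
    multiple is returned with zero padding. Never shrinks.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image array")
    h, w = image.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("image must have at least one pixel")
    pad_bottom = (-h) % tile
    pad_right = (-w) % tile
    padded = np.zeros((h + pad_bottom, w + pad_right, 3), dtype=image.dtype)
    padded[:h, :w] = image
    return PaddedImage(
        pixels=padded,
        pad_right=pad_right,
        pad_bottom=pad_bottom,
        original_size=(w, h),
        source_id=source_id,
    )


def pad_mask(mask: np.ndarray, tile: int = TILE) -> np.ndarray:
    """Pad a binary mask with zeros to match :func:`pad_to_multiple`."""
    h, w = mask.shape
    out = np.zeros((h + (-h) % tile, w + (-w) % tile), dtype=bool)
    out[:h, :w] = mask.astype(bool)
    return out


def tile(padded: PaddedImage) -> List[Patch]:
    """Cut the padded image into its non-overlapping 224 grid, row-major."""
    wp, hp = padded.size
    patches = []
    for y0 in range(0, hp, TILE):
        for x0 in range(0, wp, TILE):
            patches.append(
                Patch(
                    pixels=padded.pixels[y0 : y0 + TILE, x0 : x0 + TILE].copy(),
                    origin=(x0, y0),
                    source_id=padded.source_id,
                    provenance="original",
                )
            )
    return patches


def shifted_tiles(padded: PaddedImage, stride: int = 112) -> List[Patch]:
    """Half-stride offset grids for training augmentation.

    Three additional grids start at offsets (stride, 0), (0, stride) and
    (stride, stride), each stepping by the full tile; only windows fully
    inside the padded image are kept.
    """
    if not (0 < stride < TILE):
        raise ValueError(f"stride must lie in (0, {TILE})")
    wp, hp = padded.size
    patches = []
    for ox, oy in ((stride, 0), (0, stride), (stride, stride)):
        for y0 in range(oy, hp - TILE + 1, TILE):
            for x0 in range(ox, wp - TILE + 1, TILE):
                patches.append(
                    Patch(
                        pixels=padded.pixels[y0 : y0 + TILE, x0 : x0 + TILE].copy(),
                        origin=(x0, y0),
                        source_id=padded.source_id,
                        provenance="shifted",
                    )
                )
    return patches


def mirror(patch: Patch) -> List[Patch]:
    """The three mirrored variants: horizontal, vertical, and both flips.

    Each flip is an involution, origins are inherited, and the pixel
    multiset is preserved.
    """
    flips = (
        patch.pixels[:, ::-1],  # horizontal (left-right)
        patch.pixels[::-1, :],  # vertical (up-down)
        patch.pixels[::-1, ::-1],
    )
    return [
        replace(patch, pixels=np.ascontiguousarray(p), provenance="mirrored") for p in flips
    ]


def apply_contrast(
    pixels: np.ndarray,
    gain: float,
    offset: float,
    black_threshold: int = DEFAULT_BLACK_THRESHOLD,
) -> np.ndarray:
    """Mean-anchored contrast/brightness adjustment sparing the background.

    out = clip(gain * (p - mu) + mu + offset * 255) where mu is the patch
    mean over non-background pixels; pixels whose brightest channel is at
    or below black_threshold are returned unchanged, preserving the black
    surround of the fundus.
    """
    px = pixels.astype(np.float64)
    nonblack = px.max(axis=2) > black_threshold
    if not nonblack.any():
        return pixels.copy()
    mu = px[nonblack].mean()
    adjusted = np.clip(gain * (px - mu) + mu + offset * 255.0, 0, 255)
    out = px.copy()
    out[nonblack] = adjusted[nonblack]
    return np.round(out).astype(pixels.dtype)


def jitter(
    patch: Patch,
    max_frac: float = 0.2,
    black_threshold: int = DEFAULT_BLACK_THRESHOLD,
    rng=None,
) -> Patch:
    """Random contrast and brightness variation of up to ``max_frac``.

    Contrast gain ~ U[1 - max_frac, 1 + max_frac] and brightness offset
    ~ U[-max_frac, +max_frac] (of full scale) are drawn from the supplied
    rng and applied via :func:`apply_contrast`. max_frac = 0 reproduces
    the input exactly; background pixels are fixed points for any draw.
    """
    if not (0.0 <= max_frac <= 1.0):
        raise ValueError("max_frac must lie in [0, 1]")
    rng = as_rng(rng)
    gain = float(rng.uniform(1.0 - max_frac, 1.0 + max_frac))
    offset = float(rng.uniform(-max_frac, max_frac))
    out = apply_contrast(patch.pixels, gain, offset, black_threshold)
    return replace(patch, pixels=out, provenance="jittered")


def to_image_coords(box: BoundingBox, patch: Patch) -> BoundingBox:
    """Translate a patch-local box into padded-image coordinates."""
    if not box.within(TILE, TILE):
        raise ValueError(f"box {box} lies outside the {TILE}x{TILE} patch bounds")
    return box.translate(patch.origin[0], patch.origin[1])


def to_patch_coords(box: BoundingBox, patch: Patch) -> BoundingBox:
    """Inverse of :func:`to_image_coords` for boxes inside the patch window."""
    if not patch.window.contains_box(box):
        raise ValueError(f"box {box} lies outside patch window {patch.window}")
    return box.translate(-patch.origin[0], -patch.origin[1])
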