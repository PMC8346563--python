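"""Seeded generator of fundus-like images with per-pixel exudate ground truth.

Real screening photographs of the retina are a bright, roughly circular
disc on a black background, with dark vessels, a bright optic disc, and —
in diabetic retinopathy — compact bright lipid deposits (hard exudates)
annotated pixel-by-pixel by ophthalmologists. This module emulates that
structure so every downstream stage (tiling, SVM gating, detection,
overlap evaluation) is testable without external clinical data.

The model is deliberately simple: a radial orange-red gradient inside a
circular field of view, optional dark vessel curves and a bright optic
disc as confounders, additive Gaussian sensor noise, and lesions rendered
as filled ellipses whose intensity exceeds the local background by a
sampled gain, with Gaussian-softened edges. The binary ground-truth mask
marks exactly the ellipse footprints.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from ._utils import as_rng


class ConfigError(ValueError):
    """Raised for synthetic-image configurations that cannot be honoured."""


@dataclass(frozen=True)
class LesionRecord:
    """One placed lesion: centre (x, y), semi-axes (ax, ay), intensity gain."""

    center: Tuple[int, int]
    axes: Tuple[int, int]
    gain: float


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic fundus generator.

    width, height:
        Image size in pixels; at least 224 so a full tile fits.
    fundus_radius_frac:
        Field-of-view radius as a fraction of min(width, height)/2.
    n_lesions:
        Inclusive (lo, hi) range for the number of exudates per image.
    lesion_radius:
        Inclusive pixel range for each ellipse semi-axis.
    lesion_gain:
        Additive intensity range above the local background (0-255 scale).
    n_vessels:
        Number of dark vessel curves drawn from the optic-disc side.
    include_optic_disc:
        Draw a bright circular optic disc (a realistic false-positive
        source for threshold-style detectors).
    noise_sigma:
        Standard deviation of additive Gaussian noise inside the fundus.
    avoid_overlap:
        Enforce pairwise separation of lesions so each ground-truth
        connected component corresponds to one requested lesion.
    seed:
        Seed for all sampling in :func:`generate_fundus`.
    """

    width: int = 448
    height: int = 448
    fundus_radius_frac: float = 0.95
    n_lesions: Tuple[int, int] = (2, 6)
    lesion_radius: Tuple[int, int] = (3, 15)
    lesion_gain: Tuple[float, float] = (60.0, 120.0)
    n_vessels: int = 4
    include_optic_disc: bool = True
    noise_sigma: float = 4.0
    avoid_overlap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 224 or self.height < 224:
            raise ConfigError("width and height must be at least 224")
        if not (0.0 < self.fundus_radius_frac <= 1.0):
            raise ConfigError("fundus_radius_frac must lie in (0, 1]")
        for name in ("n_lesions", "lesion_radius", "lesion_gain"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigError(f"{name} must be a non-negative (lo, hi) range")
        if self.n_vessels < 0 or self.noise_sigma < 0:
            raise ConfigError("n_vessels and noise_sigma must be non-negative")
        radius = self.fundus_radius_frac * min(self.width, self.height) / 2.0
        if self.lesion_radius[1] >= radius:
            raise ConfigError(
                f"maximum lesion radius {self.lesion_radius[1]} does not fit "
                f"inside the fundus radius {radius:.1f}"
            )


@dataclass
class FundusSample:
    """A synthetic fundus image with its pixel-level ground truth."""

    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray  # H x W bool
    lesions: List[LesionRecord] = field(default_factory=list)

    @property
    def label(self) -> bool:
        """Image-level label: True iff the mask has at least one on-pixel."""
        return bool(self.mask.any())


def _fundus_geometry(config: SynthConfig):
    cx, cy = config.width / 2.0, config.height / 2.0
    radius = config.fundus_radius_frac * min(config.width, config.height) / 2.0
    yy, xx = np.mgrid[0 : config.height, 0 : config.width]
    dist = np.hypot(xx - cx + 0.5, yy - cy + 0.5)
    return cx, cy, radius, dist


def generate_fundus(config: SynthConfig) -> FundusSample:
    """Render one synthetic fundus image and its ground-truth lesion mask.

    Deterministic for a fixed config (including its seed): the same call
    yields byte-identical image and mask arrays.
    """
    rng = as_rng(config.seed)
    cx, cy, radius, dist = _fundus_geometry(config)
    inside = dist <= radius

    # Radial gradient background: brighter orange-red centre, darker rim.
    t = np.clip(dist / radius, 0.0, 1.0)
    base = np.zeros((config.height, config.width, 3), dtype=np.float64)
    centre_rgb = np.array([185.0, 92.0, 38.0])
    rim_rgb = np.array([120.0, 48.0, 18.0])
    for c in range(3):
        base[..., c] = np.where(inside, centre_rgb[c] + (rim_rgb[c] - centre_rgb[c]) * t, 0.0)

    # Optic disc: bright circle offset from centre.
    disc_center = (cx + 0.55 * radius, cy - 0.10 * radius)
    disc_radius = max(6.0, radius / 7.5)
    if config.include_optic_disc:
        ddist = np.hypot(
            np.arange(config.width)[None, :] - disc_center[0],
            np.arange(config.height)[:, None] - disc_center[1],
        )
        disc_profile = np.clip(1.0 - (ddist / disc_radius) ** 2, 0.0, 1.0)
        gain_rgb = np.array([55.0, 90.0, 95.0])
        for c in range(3):
            base[..., c] += np.where(inside, disc_profile * gain_rgb[c], 0.0)

    # Vessels: dark polyline curves radiating from the disc area.
    vessel = np.zeros((config.height, config.width), dtype=bool)
    for _ in range(config.n_vessels):
        ang = rng.uniform(0, 2 * np.pi)
        curv = rng.uniform(-0.008, 0.008)
        thickness = rng.integers(1, 3)
        x, y = disc_center
        step_ang = ang
        for _ in range(int(2.2 * radius)):
            xi, yi = int(round(x)), int(round(y))
            if 0 <= xi < config.width and 0 <= yi < config.height and inside[yi, xi]:
                y0, y1 = max(0, yi - thickness), min(config.height, yi + thickness + 1)
                x0, x1 = max(0, xi - thickness), min(config.width, xi + thickness + 1)
                vessel[y0:y1, x0:x1] = True
            step_ang += curv
            x += np.cos(step_ang)
            y += np.sin(step_ang)
            if np.hypot(x - cx, y - cy) > radius:
                break
    vessel &= inside
    base[vessel] *= 0.55

    # Lesions: bright filled ellipses strictly inside the fundus.
    n_lo, n_hi = config.n_lesions
    n_lesions = int(rng.integers(n_lo, n_hi + 1))
    mask = np.zeros((config.height, config.width), dtype=bool)
    lesions: List[LesionRecord] = []
    bump = np.zeros((config.height, config.width), dtype=np.float64)
    yy = np.arange(config.height)[:, None]
    xx = np.arange(config.width)[None, :]
    max_attempts = 200 * max(n_lesions, 1)
    attempts = 0
    while len(lesions) < n_lesions:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError(
                f"could not place {n_lesions} non-overlapping lesions inside the fundus"
            )
        ax = int(rng.integers(config.lesion_radius[0], config.lesion_radius[1] + 1))
        ay = int(rng.integers(config.lesion_radius[0], config.lesion_radius[1] + 1))
        gain = float(rng.uniform(*config.lesion_gain))
        margin = max(ax, ay) + 3
        r = rng.uniform(0, radius - margin)
        theta = rng.uniform(0, 2 * np.pi)
        lx = int(round(cx + r * np.cos(theta)))
        ly = int(round(cy + r * np.sin(theta)))
        if config.avoid_overlap:
            too_close = any(
                np.hypot(lx - p.center[0], ly - p.center[1])
                <= max(ax, ay) + max(p.axes) + 3
                for p in lesions
            )
            if too_close:
                continue
        footprint = ((xx - lx) / ax) ** 2 + ((yy - ly) / ay) ** 2 <= 1.0
        mask |= footprint
        bump += gain * footprint
        lesions.append(LesionRecord(center=(lx, ly), axes=(ax, ay), gain=gain))

    # Soft lesion edges in the image only; the mask keeps exact footprints.
    if lesions:
        soft = ndimage.gaussian_filter(bump, sigma=1.2)
        for c, share in enumerate((1.0, 0.95, 0.55)):
            base[..., c] += np.where(inside, soft * share, 0.0)

    if config.noise_sigma > 0:
        noise = rng.normal(0.0, config.noise_sigma, size=base.shape)
        base += np.where(inside[..., None], noise, 0.0)

    image = np.clip(base, 0, 255).astype(np.uint8)
    return FundusSample(image=image, mask=mask, lesions=lesions)


def sample_dataset(
    config: SynthConfig, n_images: int, positive_fraction: float
) -> List[FundusSample]:
    """Generate a list of samples in memory with the requested label split.

    The first ``round(n_images * positive_fraction)`` samples are positive
    (lesions drawn from the configured range); the remainder are healthy
    (zero lesions). Per-image seeds derive from ``config.seed``.
    """
    if n_images < 1:
        raise ValueError("n_images must be at least 1")
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValueError("positive_fraction must lie in [0, 1]")
    n_pos = int(round(n_images * positive_fraction))
    seeder = as_rng(config.seed)
    seeds = seeder.integers(0, 2**31 - 1, size=n_images)
    samples = []
    for i in range(n_images):
        n_lesions = config.n_lesions if i < n_pos else (0, 0)
        cfg_i = replace(config, seed=int(seeds[i]), n_lesions=n_lesions)
        samples.append(generate_fundus(cfg_i))
    return samples


def generate_dataset(
    config: SynthConfig,
    n_images: int,
    positive_fraction: float,
    out_dir: str,
) -> pd.DataFrame:
    """Write a synthetic dataset to disk and return its manifest.

    Layout: ``out_dir/images/img_###.png``, ``out_dir/masks/img_###.png``
    and ``out_dir/manifest.csv`` with columns
    (image_path, mask_path, label, seed). The number of positive-labelled
    rows equals ``round(n_images * positive_fraction)``.
    """
    samples = sample_dataset(config, n_images, positive_fraction)
    img_dir = os.path.join(out_dir, "images")
    mask_dir = os.path.join(out_dir, "masks")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(mask_dir, exist_ok=True)
    seeder = as_rng(config.seed)
    seeds = seeder.integers(0, 2**31 - 1, size=n_images)
    rows = []
    for i, sample in enumerate(samples):
        image_path = os.path.join(img_dir, f"img_{i:03d}.png")
        mask_path = os.path.join(mask_dir, f"img_{i:03d}.png")
        iio.imwrite(image_path, sample.image)
        iio.imwrite(mask_path, (sample.mask.astype(np.uint8) * 255))
        rows.append(
            {
                "image_path": image_path,
                "mask_path": mask_path,
                "label": int(sample.label),
                "seed": int(seeds[i]),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def coarse_expert_masks(
    sample: FundusSample,
    n_experts: int = 4,
    dilation_range: Tuple[int, int] = (5, 25),
    miss_prob: float = 0.15,
    rng=None,
) -> List[np.ndarray]:
    """Emulate coarse multi-grader annotations of one sample.

    Each simulated expert marks every lesion with probability
    ``1 - miss_prob`` as an oversized region: the lesion footprint
    dilated by an expert-and-lesion-specific radius. The result mirrors
    datasets where graders outline generous areas around lesions rather
    than exact pixels; fuse the masks with
    :func:`exudetect.annotations.consensus_mask` and evaluate against
    them in ``any_overlap`` mode.
    """
    if n_experts < 1:
        raise ValueError("need at least one expert")
    rng = as_rng(rng)
    h, w = sample.mask.shape
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    masks = []
    for _ in range(n_experts):
        m = np.zeros((h, w), dtype=bool)
        for lesion in sample.lesions:
            if rng.random() < miss_prob:
                continue
            grow = int(rng.integers(dilation_range[0], dilation_range[1] + 1))
            lx, ly = lesion.center
            ax, ay = lesion.axes
            m |= ((xx - lx) / (ax + grow)) ** 2 + ((yy - ly) / (ay + grow)) ** 2 <= 1.0
        masks.append(m)
    return masks


def load_sample(image_path: str, mask_path: str) -> FundusSample:
    """Read an image/mask pair from disk into a :class:`FundusSample`."""
    image = np.asarray(iio.imread(image_path))
    mask = np.asarray(iio.imread(mask_path)) > 127
    if mask.ndim == 3:
        mask = mask[..., 0]
    return FundusSample(image=image, mask=mask, lesions=[])
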