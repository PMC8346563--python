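"""From pixel masks to objects, patch labels, expert consensus, and folds.

Ground truth for hard exudates arrives as per-pixel binary masks. An
exudate *object* is one connected component of that mask together with
its tight axis-aligned bounding box — the unit at which detections are
later matched. This module also carries the dataset-assembly procedures
around that definition: labelling patches by box intersection, fusing
multi-expert masks by quorum, drawing the 2:1 negative:positive SVM
training set (with its black-pixel eligibility rule and four pure-black
patches), and building per-class near-equal cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from skimage import measure

from ._utils import as_rng
from .geometry import BoundingBox
from .patches import DEFAULT_BLACK_THRESHOLD, TILE, Patch, to_patch_coords


@dataclass(frozen=True)
class ExudateObject:
    """One connected lesion component and its tight bounding box."""

    box: BoundingBox
    component_id: int
    pixel_count: int

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("an exudate object has at least one pixel")
        if self.pixel_count > self.box.area:
            raise ValueError("pixel_count cannot exceed the box area")


@dataclass(frozen=True)
class FoldSplit:
    """A k-fold partition of image ids, near-equal within each label class."""

    k: int
    assignment: Dict[str, int]

    def fold_ids(self, fold: int) -> List[str]:
        return [i for i, f in self.assignment.items() if f == fold]


def mask_to_objects(mask: np.ndarray, connectivity: int = 8) -> List[ExudateObject]:
    """Extract exudate objects as connected components of a binary mask.

    connectivity 8 (the default) treats diagonal contact as the same
    lesion; 4 requires edge adjacency. Boxes are tight and half-open.
    """
    arr = np.asarray(mask)
    if arr.dtype != bool and not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError("mask must be binary")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labelled = measure.label(arr.astype(bool), connectivity=1 if connectivity == 4 else 2)
    objects = []
    for region in measure.regionprops(labelled):
        y0, x0, y1, x1 = region.bbox
        objects.append(
            ExudateObject(
                box=BoundingBox(x0, y0, x1, y1),
                component_id=int(region.label),
                pixel_count=int(region.area),
            )
        )
    return objects


def label_patch(
    objects: Sequence[ExudateObject], patch: Patch
) -> Tuple[bool, List[BoundingBox]]:
    """Label a patch by ground-truth box intersection.

    Returns (has_exudate, local_boxes): the patch is positive iff at
    least one object's box intersects its window by >= 1 pixel; each
    intersection is clipped to the window and translated into patch
    coordinates.
    """
    window = patch.window
    local_boxes = []
    for obj in objects:
        inter = obj.box.intersect(window)
        if inter is not None:
            local_boxes.append(to_patch_coords(inter, patch))
    return bool(local_boxes), local_boxes


def black_fraction(patch: Patch, black_threshold: int = DEFAULT_BLACK_THRESHOLD) -> float:
    """Fraction of pixels whose brightest channel is <= black_threshold."""
    return float((patch.pixels.max(axis=2) <= black_threshold).mean())


def consensus_mask(masks: Sequence[np.ndarray], quorum: float = 0.75) -> np.ndarray:
    """Fuse expert masks: a pixel is on iff >= ceil(quorum * n) experts mark it.

    With four experts and the default 75% quorum this is the
    at-least-three-of-four rule used for coarse multi-grader annotations.
    """
    if len(masks) == 0:
        raise ValueError("need at least one expert mask")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"expert masks differ in shape: {shapes}")
    votes = np.sum([m.astype(bool) for m in masks], axis=0)
    # tiny slack guards against float representation of quorum * n
    needed = int(np.ceil(quorum * len(masks) - 1e-9))
    return votes >= max(needed, 1)


@dataclass
class SVMDataset:
    """Labelled patch set for gate training: positives, 2:1 negatives, blacks."""

    patches: List[Patch]
    labels: np.ndarray  # 1 = exudate, 0 = non-exudate

    def __len__(self) -> int:
        return len(self.patches)


def assemble_svm_dataset(
    positive_patches: Sequence[Patch],
    negative_pool_dr: Sequence[Patch],
    negative_pool_healthy: Sequence[Patch],
    black_threshold: int = DEFAULT_BLACK_THRESHOLD,
    rng=None,
) -> SVMDataset:
    """Assemble the gate training set: all positives, 2:1 sampled negatives.

    Negatives are drawn without replacement from two pools — retinopathy
    background and healthy-retina patches — stratified half-and-half when
    both pools suffice, with the remainder taken from the larger pool.
    Candidates with more than a third of background pixels are ineligible.
    Four synthetic pure-black patches are appended so heavily padded
    patches classify correctly.
    """
    if len(positive_patches) == 0:
        raise ValueError("cannot assemble an SVM dataset with zero positive patches")
    rng = as_rng(rng)
    n_neg = 2 * len(positive_patches)

    def eligible(pool):
        return [p for p in pool if black_fraction(p, black_threshold) <= 1.0 / 3.0]

    pool_dr = eligible(negative_pool_dr)
    pool_healthy = eligible(negative_pool_healthy)
    total = len(pool_dr) + len(pool_healthy)
    if total < n_neg:
        raise ValueError(
            f"insufficient eligible negative patches: need {n_neg}, "
            f"have {len(pool_dr)} retinopathy + {len(pool_healthy)} healthy = {total}"
        )
    half = n_neg // 2
    take_dr = min(half, len(pool_dr))
    take_healthy = min(n_neg - take_dr, len(pool_healthy))
    take_dr = n_neg - take_healthy  # remainder falls back to the larger pool
    chosen: List[Patch] = []
    for pool, take in ((pool_dr, take_dr), (pool_healthy, take_healthy)):
        idx = rng.choice(len(pool), size=take, replace=False) if take else []
        chosen.extend(pool[i] for i in sorted(int(j) for j in np.atleast_1d(idx)))

    black = [
        Patch(
            pixels=np.zeros((TILE, TILE, 3), dtype=np.uint8),
            origin=(0, 0),
            source_id=f"pure_black_{i}",
            provenance="original",
        )
        for i in range(4)
    ]
    patches = list(positive_patches) + chosen + black
    labels = np.array([1] * len(positive_patches) + [0] * (len(chosen) + 4))
    return SVMDataset(patches=patches, labels=labels)


def make_folds(
    positive_ids: Sequence[str],
    negative_ids: Sequence[str],
    k: int = 5,
    rng=None,
) -> FoldSplit:
    """Randomly partition image ids into k near-equal folds per class.

    Within each label class fold sizes differ by at most one (larger
    folds first), e.g. 47 positives over 5 folds gives sizes
    {10, 10, 9, 9, 9} and 35 negatives gives five folds of 7.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = as_rng(rng)
    assignment: Dict[str, int] = {}
    for ids in (list(positive_ids), list(negative_ids)):
        if not ids:
            continue
        if k > len(ids):
            raise ValueError(f"k={k} exceeds the class size {len(ids)}")
        order = rng.permutation(len(ids))
        for fold, chunk in enumerate(np.array_split(order, k)):
            for j in chunk:
                assignment[ids[int(j)]] = fold
    return FoldSplit(k=k, assignment=assignment)
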