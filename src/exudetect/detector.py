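"""Object-detection stage: anchors, training configuration, backends, and
whole-image inference.

Two backends share one interface. The deep backend adapts an established
region-proposal detector (Faster R-CNN style: region proposal network
over anchor boxes on convolutional features) configured with the
pipeline's training recipe — stochastic gradient descent with momentum,
mini-batch 2, fixed learning rate 3e-4, ten epochs, anchors derived from
the training-object size distribution, and anchor labelling by overlap
intervals [0, 0.1) negative / [0.1, 1] positive. It is optional at
install time. The *reference* backend is a deterministic CPU detector —
adaptive intensity thresholding over the local background followed by
connected-component boxing with contrast-normalised scores — that
exercises the identical pipeline surface (training, per-patch detection,
gating, whole-image composition, evaluation) in milliseconds.

Whole-image inference pads the image, tiles the base non-overlapping
grid, optionally discards patches via the SVM gate, detects per retained
patch, and maps boxes back to image coordinates. Shifted tiles are a
training-time augmentation only, so no duplicate-box merging is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure

from .geometry import BoundingBox
from .patches import DEFAULT_BLACK_THRESHOLD, TILE, PaddedImage, Patch, pad_to_multiple, tile as tile_grid, to_image_coords


@dataclass(frozen=True)
class Detection:
    """A detector output: box plus confidence score in [0, 1]."""

    box: BoundingBox
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass
class DetectorConfig:
    """Training recipe for the detection stage.

    Defaults follow the pipeline's published configuration: SGD with
    momentum, mini-batch 2, learning rate 3e-4, ten epochs, anchor
    labelling negative on max-IoU in [0, 0.1) and positive in [0.1, 1].
    Anchor dimensions, when None, are derived from training-box sizes.
    """

    learning_rate: float = 3e-4
    mini_batch: int = 2
    epochs: int = 10
    negative_overlap: Tuple[float, float] = (0.0, 0.1)
    positive_overlap: Tuple[float, float] = (0.1, 1.0)
    anchor_dims: Optional[List[Tuple[float, float]]] = None
    backend_id: str = "reference"
    early_stop_patience: Optional[int] = None  # e.g. 5 => stop after 5 worsenings

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if not (
            0.0 <= self.negative_overlap[0]
            <= self.negative_overlap[1]
            <= self.positive_overlap[0]
            <= self.positive_overlap[1]
            <= 1.0
        ):
            raise ValueError(
                "overlap intervals must satisfy 0 <= neg_lo <= neg_hi <= pos_lo <= pos_hi <= 1"
            )


def derive_anchors(
    training_boxes: Sequence[BoundingBox], n_anchors: int
) -> List[Tuple[float, float]]:
    """Anchor (w, h) pairs as quantiles of the training-box size distribution.

    Quantiles are taken at equally spaced probability levels (a single
    anchor uses the median); each dimension is floored at one pixel and
    the result is invariant to box ordering.
    """
    if len(training_boxes) == 0:
        raise ValueError("cannot derive anchors from an empty box list")
    if n_anchors < 1:
        raise ValueError("n_anchors must be at least 1")
    widths = np.array([b.width for b in training_boxes], dtype=np.float64)
    heights = np.array([b.height for b in training_boxes], dtype=np.float64)
    levels = np.linspace(0, 1, n_anchors) if n_anchors > 1 else np.array([0.5])
    ws = np.maximum(np.quantile(widths, levels), 1.0)
    hs = np.maximum(np.quantile(heights, levels), 1.0)
    return [(float(w), float(h)) for w, h in zip(ws, hs)]


@dataclass
class ReferenceParams:
    """Fitted parameters of the reference (threshold-based) detector.

    delta:
        Intensity excess over the patch's background estimate above which
        a pixel is a lesion candidate.
    score_scale:
        Excess at which a candidate's contrast score saturates at 1.
    min_area:
        Minimum component area in pixels; smaller blobs are noise.
    min_score:
        Score floor applied after scoring; raising it can only remove
        detections (the backend's monotone threshold knob).
    black_threshold:
        Channel intensity at or below which a pixel is background fill.
    """

    delta: float = 25.0
    score_scale: float = 80.0
    min_area: int = 4
    min_score: float = 0.0
    black_threshold: int = DEFAULT_BLACK_THRESHOLD


@dataclass
class DetectorModel:
    """A trained detector handle with its configuration echoed as metadata."""

    backend_id: str
    params: ReferenceParams
    anchors: List[Tuple[float, float]]
    config: DetectorConfig
    trained: bool = False


def _patch_intensity(pixels: np.ndarray) -> np.ndarray:
    return pixels.astype(np.float64).mean(axis=2)


def reference_detect(patch: Patch, params: ReferenceParams) -> List[Detection]:
    """Deterministic CPU detection on one patch.

    Candidate regions are 8-connected components of non-background pixels
    exceeding the patch's median non-background intensity by
    ``params.delta``; each is scored by its peak excess normalised by
    ``params.score_scale`` and clipped to [0, 1], so a lesion as bright
    as the training distribution's upper decile scores 1. Results are
    sorted by descending score (ties broken by box position).
    """
    intensity = _patch_intensity(patch.pixels)
    nonblack = patch.pixels.max(axis=2) > params.black_threshold
    if not nonblack.any():
        return []
    background = float(np.median(intensity[nonblack]))
    candidate = nonblack & (intensity > background + params.delta)
    labelled = measure.label(candidate, connectivity=2)
    detections = []
    for region in measure.regionprops(labelled):
        if region.area < params.min_area:
            continue
        y0, x0, y1, x1 = region.bbox
        peak_excess = float(intensity[tuple(region.coords.T)].max() - background)
        score = float(np.clip(peak_excess / params.score_scale, 0.0, 1.0))
        if score < params.min_score:
            continue
        detections.append(Detection(box=BoundingBox(x0, y0, x1, y1), score=score))
    detections.sort(key=lambda d: (-d.score, d.box.y0, d.box.x0))
    return detections


class ReferenceBackend:
    """Closed-form 'training' for the threshold detector.

    Fitting pools, over all training patches, the intensity excess (over
    each patch's background median) of lesion pixels versus non-lesion
    pixels, then places the detection threshold midway between the 95th
    percentile of background excess and the 25th percentile of lesion
    excess, and sets the score scale at the lesion-excess 90th percentile.
    Deterministic for fixed input.
    """

    backend_id = "reference"

    def fit(
        self,
        patches_with_boxes: Sequence[Tuple[Patch, Sequence[BoundingBox]]],
        config: DetectorConfig,
    ) -> DetectorModel:
        lesion_excess: List[np.ndarray] = []
        background_excess: List[np.ndarray] = []
        for patch, boxes in patches_with_boxes:
            intensity = _patch_intensity(patch.pixels)
            nonblack = patch.pixels.max(axis=2) > DEFAULT_BLACK_THRESHOLD
            if not nonblack.any():
                continue
            bg = float(np.median(intensity[nonblack]))
            in_box = np.zeros_like(nonblack)
            for b in boxes:
                in_box[b.y0 : b.y1, b.x0 : b.x1] = True
            lesion_px = nonblack & in_box
            back_px = nonblack & ~in_box
            if lesion_px.any():
                lesion_excess.append(intensity[lesion_px] - bg)
            if back_px.any():
                background_excess.append(intensity[back_px] - bg)
        if not lesion_excess:
            raise ValueError("reference backend fit needs at least one lesion pixel")
        lesion = np.concatenate(lesion_excess)
        background = (
            np.concatenate(background_excess) if background_excess else np.array([0.0])
        )
        delta = max(5.0, 0.5 * (np.percentile(background, 95) + np.percentile(lesion, 25)))
        score_scale = max(10.0, float(np.percentile(lesion, 90)))
        params = ReferenceParams(delta=float(delta), score_scale=score_scale)
        anchors = config.anchor_dims or derive_anchors(
            [b for _, boxes in patches_with_boxes for b in boxes], n_anchors=3
        )
        return DetectorModel(
            backend_id=self.backend_id,
            params=params,
            anchors=anchors,
            config=config,
            trained=True,
        )

    def predict(self, model: DetectorModel, patch: Patch) -> List[Detection]:
        return reference_detect(patch, model.params)


class TorchFasterRCNNBackend:  # pragma: no cover - requires optional extra
    """Adapter around torchvision's region-proposal detector.

    Constructing it requires the optional deep-learning dependencies;
    training honours the configured epochs, mini-batch, learning rate,
    momentum SGD, derived anchors, and overlap-interval anchor labelling,
    with an optional early-stop callback (off by default).
    """

    backend_id = "torch-faster-rcnn"

    def __init__(self):
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "TorchFasterRCNNBackend needs the 'deep' extra (torch, torchvision)"
            ) from exc
        import torchvision

        self._torchvision = torchvision

    def fit(self, patches_with_boxes, config: DetectorConfig):
        import torch
        from torchvision.models.detection import FasterRCNN
        from torchvision.models.detection.anchor_utils import AnchorGenerator
        from torchvision.models.detection.backbone_utils import resnet_fpn_backbone

        boxes_all = [b for _, boxes in patches_with_boxes for b in boxes]
        anchors = config.anchor_dims or derive_anchors(boxes_all, n_anchors=3)
        sizes = tuple(float(np.sqrt(w * h)) for w, h in anchors)
        backbone = resnet_fpn_backbone("resnet50", weights=None)
        net = FasterRCNN(
            backbone,
            num_classes=2,
            rpn_anchor_generator=AnchorGenerator(
                sizes=(sizes,) * 5, aspect_ratios=((0.5, 1.0, 2.0),) * 5
            ),
            rpn_bg_iou_thresh=config.negative_overlap[1],
            rpn_fg_iou_thresh=config.positive_overlap[0],
        )
        optimiser = torch.optim.SGD(
            net.parameters(), lr=config.learning_rate, momentum=0.9
        )
        net.train()
        for _ in range(config.epochs):
            for i in range(0, len(patches_with_boxes), config.mini_batch):
                batch = patches_with_boxes[i : i + config.mini_batch]
                images = [
                    torch.from_numpy(p.pixels.astype(np.float32) / 255.0).permute(2, 0, 1)
                    for p, _ in batch
                ]
                targets = [
                    {
                        "boxes": torch.tensor(
                            [[b.x0, b.y0, b.x1, b.y1] for b in boxes], dtype=torch.float32
                        ),
                        "labels": torch.ones(len(boxes), dtype=torch.int64),
                    }
                    for _, boxes in batch
                ]
                loss = sum(net(images, targets).values())
                optimiser.zero_grad()
                loss.backward()
                optimiser.step()
        model = DetectorModel(
            backend_id=self.backend_id,
            params=ReferenceParams(),
            anchors=anchors,
            config=config,
            trained=True,
        )
        model.net = net.eval()
        return model

    def predict(self, model, patch: Patch):
        import torch

        x = torch.from_numpy(patch.pixels.astype(np.float32) / 255.0).permute(2, 0, 1)
        with torch.no_grad():
            out = model.net([x])[0]
        detections = []
        for box, score in zip(out["boxes"].numpy(), out["scores"].numpy()):
            x0, y0, x1, y1 = (int(round(v)) for v in box)
            x1, y1 = max(x1, x0 + 1), max(y1, y0 + 1)
            detections.append(
                Detection(BoundingBox(max(x0, 0), max(y0, 0), min(x1, TILE), min(y1, TILE)),
                          float(np.clip(score, 0, 1)))
            )
        return detections


_BACKENDS = {"reference": ReferenceBackend}


def get_backend(backend_id: str):
    if backend_id == "torch-faster-rcnn":
        return TorchFasterRCNNBackend()
    if backend_id in _BACKENDS:
        return _BACKENDS[backend_id]()
    raise KeyError(f"unknown detector backend: {backend_id}")


def train_detector(
    patches_with_boxes: Sequence[Tuple[Patch, Sequence[BoundingBox]]],
    config: Optional[DetectorConfig] = None,
    backend=None,
) -> DetectorModel:
    """Train the detection stage on positive patches only.

    Every training patch must carry at least one ground-truth box —
    exudate-free patches are excluded from detector training by design
    (the gate, not the detector, sees the negatives).
    """
    config = config or DetectorConfig()
    for i, (_, boxes) in enumerate(patches_with_boxes):
        if len(boxes) == 0:
            raise ValueError(
                f"training patch {i} has no ground-truth boxes; "
                "patches without exudates are not part of the detector training set"
            )
    backend = backend or get_backend(config.backend_id)
    return backend.fit(patches_with_boxes, config)


def detect(
    model: DetectorModel, patch: Patch, score_threshold: float = 0.5
) -> List[Detection]:
    """Detections on one patch with score >= score_threshold, best first."""
    if not model.trained:
        raise ValueError("detector model is not trained")
    if not (0.0 <= score_threshold <= 1.0):
        raise ValueError("score_threshold must lie in [0, 1]")
    if patch.pixels.shape != (TILE, TILE, 3):
        raise ValueError("detect expects a 224x224x3 patch")
    backend = get_backend(model.backend_id)
    detections = [d for d in backend.predict(model, patch) if d.score >= score_threshold]
    detections.sort(key=lambda d: (-d.score, d.box.y0, d.box.x0))
    return detections


@dataclass
class ImageDetectionResult:
    """Whole-image inference output.

    detections are in original-image coordinates (clipped to the
    pre-padding extent); per_patch_scores holds, for every patch of the
    base grid in row-major order, the maximum detection score (0 for
    gated-out or detection-free patches).
    """

    detections: List[Detection]
    per_patch_scores: np.ndarray
    patch_origins: List[Tuple[int, int]]
    kept: np.ndarray  # bool per grid patch: survived the gate

    @property
    def max_score(self) -> float:
        return float(self.per_patch_scores.max()) if self.per_patch_scores.size else 0.0


def detect_image(
    image: np.ndarray,
    model: DetectorModel,
    patch_filter: Optional[Callable[[Patch], bool]] = None,
    score_threshold: float = 0.5,
    source_id: str = "image",
) -> ImageDetectionResult:
    """Run the full per-image pipeline: pad, tile, gate, detect, compose.

    patch_filter is the optional pre-scanning gate (e.g. built via
    ``gate.as_patch_filter``); when given, patches it rejects are skipped
    entirely and score 0 in per_patch_scores. Detections are translated
    to image coordinates and clipped to the original (pre-padding) image
    bounds, so they never overlap the padding region.
    """
    padded = pad_to_multiple(image, source_id=source_id)
    grid = tile_grid(padded)
    w, h = padded.original_size
    scores = np.zeros(len(grid))
    kept = np.zeros(len(grid), dtype=bool)
    detections: List[Detection] = []
    for i, patch in enumerate(grid):
        if patch_filter is not None and not patch_filter(patch):
            continue
        kept[i] = True
        patch_dets = detect(model, patch, score_threshold=score_threshold)
        if patch_dets:
            scores[i] = max(d.score for d in patch_dets)
        for d in patch_dets:
            img_box = to_image_coords(d.box, patch)
            clipped = img_box.intersect(BoundingBox(0, 0, w, h))
            if clipped is not None:
                detections.append(Detection(box=clipped, score=d.score))
    detections.sort(key=lambda d: (-d.score, d.box.y0, d.box.x0))
    return ImageDetectionResult(
        detections=detections,
        per_patch_scores=scores,
        patch_origins=[p.origin for p in grid],
        kept=kept,
    )
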