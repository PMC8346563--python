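"""Linear SVM pre-scanning of patches before the object detector runs.

The gate exists for throughput and false-positive control: a linear
support-vector classifier over a fixed-length feature vector decides, per
224x224 patch, whether it plausibly contains exudates; only positive
patches are forwarded to the (much slower) detector. Features come from a
pluggable extractor. Two extractors ship:

* ``ResNet50AvgPoolExtractor`` — the production contract: 2048 activations
  from the final average-pool of a 50-layer residual network. It is an
  optional adapter; constructing it requires the deep-learning extra.
* ``ToyFeatureExtractor`` — a deterministic, CPU-only extractor
  (per-channel histograms plus gradient-magnitude statistics) used by all
  tests and the reference pipeline.

The decision boundary is the classical hard/soft maximum-margin
hyperplane with hinge loss; a margin of exactly zero is classified
positive so that borderline patches err toward reaching the detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from skimage.measure import label
from sklearn.svm import SVC

from .patches import Patch

RESNET50_FEATURE_DIM = 2048


class FeatureExtractor:
    """Contract: a callable mapping a 224x224x3 patch to a fixed vector."""

    extractor_id: str = "abstract"
    dim: int = 0

    def __call__(self, patch: Patch) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ToyFeatureExtractor(FeatureExtractor):
    """Deterministic hand-crafted features for CPU-only pipelines.

    Three feature groups per patch:

    * per channel, a ``bins``-bin normalised intensity histogram over
      [0, 256);
    * four gradient-magnitude statistics of the channel-mean image
      (mean, std, max, 95th percentile), scaled to [0, 1];
    * contrast-tail statistics aimed at small bright lesions: with b the
      median channel-mean intensity of non-background pixels, the
      fraction of non-background pixels whose excess over b exceeds each
      of eight margins (10..120), plus the maximum and 99th-percentile
      excess scaled to [0, 1];
    * bright-blob morphology, separating small compact deposits from
      single large bright structures such as the optic disc: number of
      connected bright components (excess > 40), the largest and
      second-largest component areas as patch fractions, and the bright
      area lying outside the largest component.

    On an all-zero patch the histograms put all mass in the first bin
    and every other statistic is zero.
    """

    _TAIL_MARGINS = (10.0, 20.0, 30.0, 40.0, 60.0, 80.0, 100.0, 120.0)
    _BLOB_EXCESS = 40.0

    def __init__(self, bins: int = 16, black_threshold: int = 10):
        self.bins = bins
        self.black_threshold = black_threshold
        self.extractor_id = f"toy-hist{bins}-grad-tail-blob"
        self.dim = 3 * bins + 4 + len(self._TAIL_MARGINS) + 2 + 4

    def __call__(self, patch: Patch) -> np.ndarray:
        px = patch.pixels.astype(np.float64)
        feats = []
        for c in range(3):
            hist, _ = np.histogram(px[..., c], bins=self.bins, range=(0, 256))
            feats.append(hist / px[..., c].size)
        gray = px.mean(axis=2)
        gy, gx = np.gradient(gray)
        mag = np.hypot(gx, gy)
        feats.append(
            np.array([mag.mean(), mag.std(), mag.max(), np.percentile(mag, 95)]) / 255.0
        )
        nonblack = px.max(axis=2) > self.black_threshold
        blob = [0.0, 0.0, 0.0, 0.0]
        if nonblack.any():
            base = np.median(gray[nonblack])
            excess = gray[nonblack] - base
            tails = [float((excess > m).mean()) for m in self._TAIL_MARGINS]
            extremes = [float(excess.max()) / 255.0, float(np.percentile(excess, 99)) / 255.0]
            bright = nonblack & (gray > base + self._BLOB_EXCESS)
            if bright.any():
                labelled = label(bright, connectivity=2)
                areas = np.sort(np.bincount(labelled.ravel())[1:])[::-1]
                total = gray.size
                blob = [
                    len(areas) / 10.0,
                    float(areas[0]) / total,
                    float(areas[1]) / total if len(areas) > 1 else 0.0,
                    float(areas[1:].sum()) / total,
                ]
        else:
            tails = [0.0] * len(self._TAIL_MARGINS)
            extremes = [0.0, 0.0]
        feats.append(np.array(tails + extremes + blob))
        vec = np.concatenate(feats)
        assert vec.shape == (self.dim,)
        return vec


class ResNet50AvgPoolExtractor(FeatureExtractor):
    """Adapter to a pretrained 50-layer residual backbone, truncated at
    the final average-pool (2048 activations per patch).

    Requires the optional deep-learning dependencies; the class-level
    ``dim`` contract is importable without them.
    """

    extractor_id = "resnet50-avgpool"
    dim = RESNET50_FEATURE_DIM

    def __init__(self):
        try:  # deferred so the contract is usable without the extra
            import torch  # noqa: F401
            import torchvision
        except ImportError as exc:  # pragma: no cover - env without torch
            raise ImportError(
                "ResNet50AvgPoolExtractor needs the 'deep' extra (torch, torchvision)"
            ) from exc
        weights = torchvision.models.ResNet50_Weights.IMAGENET1K_V1  # pragma: no cover
        net = torchvision.models.resnet50(weights=weights)  # pragma: no cover
        self._net = torch.nn.Sequential(*list(net.children())[:-1]).eval()  # pragma: no cover

    def __call__(self, patch: Patch) -> np.ndarray:  # pragma: no cover
        import torch

        x = torch.from_numpy(patch.pixels.astype(np.float32) / 255.0)
        x = x.permute(2, 0, 1).unsqueeze(0)
        with torch.no_grad():
            out = self._net(x)
        return out.numpy().reshape(-1)


@dataclass
class GateModel:
    """A trained linear gate: label positive iff weights . x + bias >= 0."""

    weights: np.ndarray
    bias: float
    extractor_id: str
    training_meta: Dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": [float(w) for w in self.weights],
                "bias": float(self.bias),
                "extractor_id": self.extractor_id,
                "training_meta": self.training_meta,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GateModel":
        d = json.loads(text)
        return cls(
            weights=np.asarray(d["weights"], dtype=np.float64),
            bias=float(d["bias"]),
            extractor_id=d["extractor_id"],
            training_meta=d.get("training_meta", {}),
        )


def extract_features(patch: Patch, extractor: FeatureExtractor) -> np.ndarray:
    """Run the extractor on a patch, validating the declared dimension."""
    vec = np.asarray(extractor(patch), dtype=np.float64)
    if vec.shape != (extractor.dim,):
        raise ValueError(
            f"extractor {extractor.extractor_id} returned shape {vec.shape}, "
            f"declared dim {extractor.dim}"
        )
    if not np.all(np.isfinite(vec)):
        raise ValueError("feature vector contains non-finite values")
    return vec


def extract_features_batch(
    patches: Sequence[Patch], extractor: FeatureExtractor
) -> np.ndarray:
    return np.stack([extract_features(p, extractor) for p in patches]) if patches else np.empty((0, extractor.dim))


def train_gate(
    features: np.ndarray,
    labels: Sequence[int],
    C: float = 1.0,
    extractor_id: str = "unknown",
) -> GateModel:
    """Fit the maximum-margin linear separator (hinge loss, penalty C).

    labels are binary with 1 = exudate. Deterministic for fixed inputs.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array (n_samples, dim)")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels length mismatch")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need both classes present, got classes {classes}")
    svc = SVC(kernel="linear", C=C)
    svc.fit(X, (y == classes.max()).astype(int))
    return GateModel(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        extractor_id=extractor_id,
        training_meta={"C": C, "n_train": int(X.shape[0])},
    )


def gate_classify(model: GateModel, feature: np.ndarray) -> Tuple[bool, float]:
    """Classify one feature vector. Returns (is_positive, margin).

    margin = weights . x + bias; zero margin is positive by design so
    ties are forwarded to the detector.
    """
    x = np.asarray(feature, dtype=np.float64)
    if x.shape != model.weights.shape:
        raise ValueError(
            f"feature length {x.shape} does not match model weights {model.weights.shape}"
        )
    margin = float(model.weights @ x + model.bias)
    return margin >= 0.0, margin


def gate_filter(
    patches: Sequence[Patch], model: GateModel, extractor: FeatureExtractor
) -> List[Patch]:
    """Keep, in order, the patches the gate classifies as positive."""
    kept = []
    for p in patches:
        positive, _ = gate_classify(model, extract_features(p, extractor))
        if positive:
            kept.append(p)
    return kept


def as_patch_filter(model: GateModel, extractor: FeatureExtractor):
    """Wrap a gate model as a per-patch predicate for detector pipelines."""

    def keep(patch: Patch) -> bool:
        positive, _ = gate_classify(model, extract_features(patch, extractor))
        return positive

    return keep


def gate_cv_accuracy(
    fold_datasets: Sequence[Tuple[np.ndarray, np.ndarray]], C: float = 1.0
) -> Tuple[List[float], float]:
    """Cross-validated gate accuracy: train on k-1 folds, score the held-out one.

    fold_datasets is a sequence of (features, labels) pairs, one per fold.
    Returns (per-fold accuracies, their mean). A training union containing
    a single class is flagged as an error.
    """
    k = len(fold_datasets)
    if k < 2:
        raise ValueError("need at least 2 folds")
    accuracies = []
    for i in range(k):
        X_tr = np.concatenate([fold_datasets[j][0] for j in range(k) if j != i])
        y_tr = np.concatenate([np.asarray(fold_datasets[j][1]) for j in range(k) if j != i])
        if np.unique(y_tr).size < 2:
            raise ValueError(f"training folds excluding fold {i} contain a single class")
        model = train_gate(X_tr, y_tr, C=C)
        X_va, y_va = fold_datasets[i]
        y_va = np.asarray(y_va)
        preds = np.array(
            [gate_classify(model, x)[0] for x in np.asarray(X_va, dtype=np.float64)]
        )
        accuracies.append(float((preds == (y_va == y_tr.max())).mean()))
    return accuracies, float(np.mean(accuracies))
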