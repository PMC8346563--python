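"""Stage orchestration: chain the synthetic data, patch, gate, detector
and evaluation modules into a reproducible on-disk pipeline.

Each stage reads the artifacts of its predecessors from a working
directory and writes its own (CSV/JSON/PNG only), so every command is
rerunnable and deterministic for a fixed seed. A machine-readable
``run_log.json`` accumulates the seed, a config hash, and the headline
counts of every stage.

The four method variants — gate on/off x contrast-jitter augmentation
on/off — are plain config switches; :func:`run_experiment` executes all
four over shared data and folds so their error rates are directly
comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from ._utils import as_rng, derive_seed
from . import annotations as ann
from . import detector as det
from . import evaluation as ev
from . import gate as gt
from . import patches as pt
from . import synth
from .geometry import BoundingBox


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults give a fast desk-scale study."""

    out_dir: str = "run"
    seed: int = 0
    # synthetic data
    n_images: int = 20
    positive_fraction: float = 0.6
    width: int = 672
    height: int = 672
    n_lesions: Tuple[int, int] = (1, 4)
    lesion_gain: Tuple[float, float] = (60.0, 120.0)
    noise_sigma: float = 4.0
    # folds / patches
    k_folds: int = 5
    stride: int = 112
    jitter_max_frac: float = 0.2
    black_threshold: int = pt.DEFAULT_BLACK_THRESHOLD
    # gate
    gate_C: float = 1.0
    use_gate: bool = True
    # detector
    use_jitter: bool = False
    score_threshold: float = 0.5
    # evaluation
    overlap_min: float = 0.2
    tau: float = 0.9
    mode: str = "strict"

    def synth_config(self) -> synth.SynthConfig:
        return synth.SynthConfig(
            width=self.width,
            height=self.height,
            n_lesions=self.n_lesions,
            lesion_gain=self.lesion_gain,
            noise_sigma=self.noise_sigma,
            seed=derive_seed(self.seed, "synth"),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for name in ("n_lesions", "lesion_gain"):
            if name in raw:
                raw[name] = tuple(raw[name])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["n_lesions"] = list(d["n_lesions"])
        d["lesion_gain"] = list(d["lesion_gain"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _log(config: RunConfig, stage: str, payload: Dict) -> None:
    path = os.path.join(config.out_dir, "run_log.json")
    log = {}
    if os.path.exists(path):
        with open(path) as fh:
            log = json.load(fh)
    log.setdefault("seed", config.seed)
    log.setdefault("config_hash", config.config_hash())
    log[stage] = payload
    os.makedirs(config.out_dir, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2)


def _require(path: str, stage: str) -> None:
    if not os.path.exists(path):
        raise FileNotFoundError(f"stage '{stage}' needs missing artifact: {path}")


# ---------------------------------------------------------------- synth

def run_synth(config: RunConfig) -> pd.DataFrame:
    """Generate the synthetic dataset and its manifest."""
    data_dir = os.path.join(config.out_dir, "data")
    manifest = synth.generate_dataset(
        config.synth_config(), config.n_images, config.positive_fraction, data_dir
    )
    _log(config, "synth", {"n_images": len(manifest), "n_positive": int(manifest.label.sum())})
    return manifest


def _load_manifest(config: RunConfig) -> pd.DataFrame:
    path = os.path.join(config.out_dir, "data", "manifest.csv")
    _require(path, "prepare")
    m = pd.read_csv(path)
    m["image_id"] = [os.path.splitext(os.path.basename(p))[0] for p in m.image_path]
    return m


def _image_objects(mask: np.ndarray) -> List[ann.ExudateObject]:
    return ann.mask_to_objects(mask, connectivity=8)


# -------------------------------------------------------------- prepare

def run_prepare(config: RunConfig) -> None:
    """Extract objects, assign folds, and label the base patch grid."""
    manifest = _load_manifest(config)
    prep_dir = os.path.join(config.out_dir, "prepared")
    os.makedirs(prep_dir, exist_ok=True)

    obj_rows, patch_rows = [], []
    for _, row in manifest.iterrows():
        sample = synth.load_sample(row.image_path, row.mask_path)
        objects = _image_objects(sample.mask)
        for obj in objects:
            obj_rows.append(
                {
                    "image_id": row.image_id,
                    "component_id": obj.component_id,
                    "x0": obj.box.x0, "y0": obj.box.y0,
                    "x1": obj.box.x1, "y1": obj.box.y1,
                    "pixel_count": obj.pixel_count,
                }
            )
        padded = pt.pad_to_multiple(sample.image, source_id=row.image_id)
        for patch in pt.tile(padded):
            positive, _ = ann.label_patch(objects, patch)
            patch_rows.append(
                {
                    "source_id": row.image_id,
                    "origin_x": patch.origin[0],
                    "origin_y": patch.origin[1],
                    "provenance": patch.provenance,
                    "label": int(positive),
                }
            )
    pd.DataFrame(
        obj_rows,
        columns=["image_id", "component_id", "x0", "y0", "x1", "y1", "pixel_count"],
    ).to_csv(os.path.join(prep_dir, "objects.csv"), index=False)
    pd.DataFrame(patch_rows).to_csv(os.path.join(prep_dir, "patches.csv"), index=False)

    pos_ids = list(manifest[manifest.label == 1].image_id)
    neg_ids = list(manifest[manifest.label == 0].image_id)
    folds = ann.make_folds(pos_ids, neg_ids, k=config.k_folds,
                           rng=derive_seed(config.seed, "folds"))
    fold_rows = [
        {"image_id": i, "label": int(i in pos_ids), "fold": f}
        for i, f in sorted(folds.assignment.items())
    ]
    pd.DataFrame(fold_rows).to_csv(os.path.join(prep_dir, "folds.csv"), index=False)
    _log(config, "prepare", {
        "n_objects": len(obj_rows),
        "n_patches": len(patch_rows),
        "n_positive_patches": int(sum(r["label"] for r in patch_rows)),
    })


def _load_prepared(config: RunConfig):
    prep_dir = os.path.join(config.out_dir, "prepared")
    for name in ("objects.csv", "folds.csv", "patches.csv"):
        _require(os.path.join(prep_dir, name), "downstream")
    objects = pd.read_csv(os.path.join(prep_dir, "objects.csv"))
    folds = pd.read_csv(os.path.join(prep_dir, "folds.csv"))
    patches = pd.read_csv(os.path.join(prep_dir, "patches.csv"))
    return objects, folds, patches


def _objects_for(objects_df: pd.DataFrame, image_id: str) -> List[ann.ExudateObject]:
    rows = objects_df[objects_df.image_id == image_id]
    return [
        ann.ExudateObject(
            box=BoundingBox(int(r.x0), int(r.y0), int(r.x1), int(r.y1)),
            component_id=int(r.component_id),
            pixel_count=int(r.pixel_count),
        )
        for r in rows.itertuples()
    ]


def _gate_patches(config: RunConfig, manifest: pd.DataFrame, image_id: str) -> List[pt.Patch]:
    """Base-grid plus shifted patches of one image — the same patch
    methodology the detector trains on, reused for the gate dataset."""
    row = manifest[manifest.image_id == image_id].iloc[0]
    sample = synth.load_sample(row.image_path, row.mask_path)
    padded = pt.pad_to_multiple(sample.image, source_id=image_id)
    return pt.tile(padded) + pt.shifted_tiles(padded, stride=config.stride)


# -------------------------------------------------------- SVM set / gate

def run_build_svm_set(config: RunConfig) -> pd.DataFrame:
    """Assemble per-fold SVM training sets (2:1 negatives, 4 black patches)."""
    manifest = _load_manifest(config)
    objects_df, folds_df, _ = _load_prepared(config)
    rng = as_rng(derive_seed(config.seed, "svm_set"))
    rows = []
    for fold in range(config.k_folds):
        # each fold's dataset comes from its own images, so the CV folds
        # in train-gate stay disjoint at the image level
        fold_imgs = folds_df[folds_df.fold == fold]
        positives, pool_dr, pool_healthy = [], [], []
        for r in fold_imgs.itertuples():
            objects = _objects_for(objects_df, r.image_id)
            for patch in _gate_patches(config, manifest, r.image_id):
                positive, _ = ann.label_patch(objects, patch)
                if positive:
                    positives.append(patch)
                elif r.label == 1:
                    pool_dr.append(patch)
                else:
                    pool_healthy.append(patch)
        dataset = ann.assemble_svm_dataset(
            positives, pool_dr, pool_healthy,
            black_threshold=config.black_threshold, rng=rng,
        )
        for patch, label in zip(dataset.patches, dataset.labels):
            rows.append(
                {
                    "fold": fold,
                    "source_id": patch.source_id,
                    "origin_x": patch.origin[0],
                    "origin_y": patch.origin[1],
                    "label": int(label),
                }
            )
    out = pd.DataFrame(rows)
    svm_dir = os.path.join(config.out_dir, "svm")
    os.makedirs(svm_dir, exist_ok=True)
    out.to_csv(os.path.join(svm_dir, "svm_set.csv"), index=False)
    _log(config, "build-svm-set", {
        "n_rows": len(out),
        "n_positive": int(out.label.sum()),
        "n_negative": int((1 - out.label).sum()),
    })
    return out


def _materialise_svm_patch(
    config, manifest, source_id: str, ox: int, oy: int, cache: Optional[Dict] = None
) -> pt.Patch:
    if source_id.startswith("pure_black_"):
        return pt.Patch(
            pixels=np.zeros((pt.TILE, pt.TILE, 3), dtype=np.uint8),
            origin=(0, 0), source_id=source_id,
        )
    if cache is not None and source_id in cache:
        pixels = cache[source_id]
    else:
        row = manifest[manifest.image_id == source_id].iloc[0]
        sample = synth.load_sample(row.image_path, row.mask_path)
        pixels = pt.pad_to_multiple(sample.image, source_id=source_id).pixels
        if cache is not None:
            cache[source_id] = pixels
    return pt.Patch(
        pixels=pixels[oy : oy + pt.TILE, ox : ox + pt.TILE].copy(),
        origin=(ox, oy), source_id=source_id,
    )


def run_train_gate(config: RunConfig) -> Dict:
    """Train one linear gate per fold; report cross-validated accuracy."""
    manifest = _load_manifest(config)
    svm_path = os.path.join(config.out_dir, "svm", "svm_set.csv")
    _require(svm_path, "train-gate")
    svm_set = pd.read_csv(svm_path)
    extractor = gt.ToyFeatureExtractor()
    gate_dir = os.path.join(config.out_dir, "gate")
    os.makedirs(gate_dir, exist_ok=True)

    fold_data = []
    cache: Dict[str, np.ndarray] = {}
    for fold in range(config.k_folds):
        rows = svm_set[svm_set.fold == fold]
        patches = [
            _materialise_svm_patch(config, manifest, r.source_id,
                                   int(r.origin_x), int(r.origin_y), cache)
            for r in rows.itertuples()
        ]
        X = gt.extract_features_batch(patches, extractor)
        y = rows.label.to_numpy()
        fold_data.append((X, y))

    accuracies = []
    for fold in range(config.k_folds):
        X_tr = np.concatenate([fold_data[j][0] for j in range(config.k_folds) if j != fold])
        y_tr = np.concatenate([fold_data[j][1] for j in range(config.k_folds) if j != fold])
        model = gt.train_gate(X_tr, y_tr, C=config.gate_C, extractor_id=extractor.extractor_id)
        model.training_meta["fold"] = fold
        with open(os.path.join(gate_dir, f"gate_fold{fold}.json"), "w") as fh:
            fh.write(model.to_json())
        X_va, y_va = fold_data[fold]
        preds = np.array([gt.gate_classify(model, x)[0] for x in X_va])
        accuracies.append(float((preds == (y_va == 1)).mean()))
    summary = {"per_fold_accuracy": accuracies, "mean_accuracy": float(np.mean(accuracies))}
    with open(os.path.join(gate_dir, "cv.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    _log(config, "train-gate", summary)
    return summary


# ------------------------------------------------------------- detector

def _mirror_box(box: BoundingBox, flip_x: bool, flip_y: bool) -> BoundingBox:
    x0, x1 = (pt.TILE - box.x1, pt.TILE - box.x0) if flip_x else (box.x0, box.x1)
    y0, y1 = (pt.TILE - box.y1, pt.TILE - box.y0) if flip_y else (box.y0, box.y1)
    return BoundingBox(x0, y0, x1, y1)


def build_detector_training_set(
    padded_images: Sequence[pt.PaddedImage],
    objects_per_image: Sequence[Sequence[ann.ExudateObject]],
    stride: int = 112,
    use_jitter: bool = False,
    jitter_max_frac: float = 0.2,
    black_threshold: int = pt.DEFAULT_BLACK_THRESHOLD,
    rng=None,
) -> List[Tuple[pt.Patch, List[BoundingBox]]]:
    """Positive patches with local boxes: originals + shifted, each with
    its three mirrored variants (boxes flipped alongside the pixels), and
    optionally one contrast-jittered copy per patch."""
    rng = as_rng(rng)
    out: List[Tuple[pt.Patch, List[BoundingBox]]] = []
    for padded, objects in zip(padded_images, objects_per_image):
        base = pt.tile(padded) + pt.shifted_tiles(padded, stride=stride)
        for patch in base:
            positive, boxes = ann.label_patch(objects, patch)
            if not positive:
                continue
            out.append((patch, boxes))
            flips = ((True, False), (False, True), (True, True))
            for mirrored, (fx, fy) in zip(pt.mirror(patch), flips):
                out.append((mirrored, [_mirror_box(b, fx, fy) for b in boxes]))
    if use_jitter:
        jittered = [
            (pt.jitter(p, max_frac=jitter_max_frac, black_threshold=black_threshold, rng=rng),
             list(boxes))
            for p, boxes in out
        ]
        out.extend(jittered)
    return out


def _model_to_json(model: det.DetectorModel) -> Dict:
    return {
        "backend_id": model.backend_id,
        "params": dataclasses.asdict(model.params),
        "anchors": [list(a) for a in model.anchors],
        "config": {
            "learning_rate": model.config.learning_rate,
            "mini_batch": model.config.mini_batch,
            "epochs": model.config.epochs,
            "negative_overlap": list(model.config.negative_overlap),
            "positive_overlap": list(model.config.positive_overlap),
        },
    }


def _model_from_json(d: Dict) -> det.DetectorModel:
    cfg = det.DetectorConfig(
        learning_rate=d["config"]["learning_rate"],
        mini_batch=d["config"]["mini_batch"],
        epochs=d["config"]["epochs"],
        negative_overlap=tuple(d["config"]["negative_overlap"]),
        positive_overlap=tuple(d["config"]["positive_overlap"]),
        backend_id=d["backend_id"],
    )
    return det.DetectorModel(
        backend_id=d["backend_id"],
        params=det.ReferenceParams(**d["params"]),
        anchors=[tuple(a) for a in d["anchors"]],
        config=cfg,
        trained=True,
    )


def run_train_detector(config: RunConfig) -> None:
    """Train one reference detector per fold on that fold's training images."""
    manifest = _load_manifest(config)
    objects_df, folds_df, _ = _load_prepared(config)
    det_dir = os.path.join(config.out_dir, "detector")
    os.makedirs(det_dir, exist_ok=True)
    rng = as_rng(derive_seed(config.seed, "detector"))
    n_patches = 0
    for fold in range(config.k_folds):
        train_imgs = folds_df[(folds_df.fold != fold) & (folds_df.label == 1)]
        padded_images, objects_per_image = [], []
        for r in train_imgs.itertuples():
            row = manifest[manifest.image_id == r.image_id].iloc[0]
            sample = synth.load_sample(row.image_path, row.mask_path)
            padded_images.append(pt.pad_to_multiple(sample.image, source_id=r.image_id))
            objects_per_image.append(_objects_for(objects_df, r.image_id))
        training_set = build_detector_training_set(
            padded_images, objects_per_image,
            stride=config.stride, use_jitter=config.use_jitter,
            jitter_max_frac=config.jitter_max_frac,
            black_threshold=config.black_threshold, rng=rng,
        )
        n_patches += len(training_set)
        model = det.train_detector(training_set, det.DetectorConfig())
        with open(os.path.join(det_dir, f"model_fold{fold}.json"), "w") as fh:
            json.dump(_model_to_json(model), fh, indent=2)
    _log(config, "train-detector", {
        "n_training_patches": n_patches, "use_jitter": config.use_jitter,
    })


# --------------------------------------------------------------- detect

def run_detect(config: RunConfig) -> None:
    """Detect on every image with its fold's model (and optionally gate)."""
    manifest = _load_manifest(config)
    _, folds_df, _ = _load_prepared(config)
    det_dir = os.path.join(config.out_dir, "detector")
    gate_dir = os.path.join(config.out_dir, "gate")
    out_dir = os.path.join(config.out_dir, "detections")
    os.makedirs(out_dir, exist_ok=True)

    models = {}
    for fold in range(config.k_folds):
        path = os.path.join(det_dir, f"model_fold{fold}.json")
        _require(path, "detect")
        with open(path) as fh:
            models[fold] = _model_from_json(json.load(fh))
    gates = {}
    if config.use_gate:
        extractor = gt.ToyFeatureExtractor()
        for fold in range(config.k_folds):
            path = os.path.join(gate_dir, f"gate_fold{fold}.json")
            _require(path, "detect")
            with open(path) as fh:
                gates[fold] = gt.GateModel.from_json(fh.read())

    det_rows, score_rows = [], []
    n_gated_out = 0
    fold_of = dict(zip(folds_df.image_id, folds_df.fold))
    for _, row in manifest.iterrows():
        fold = fold_of[row.image_id]
        sample = synth.load_sample(row.image_path, row.mask_path)
        patch_filter = (
            gt.as_patch_filter(gates[fold], gt.ToyFeatureExtractor())
            if config.use_gate else None
        )
        result = det.detect_image(
            sample.image, models[fold],
            patch_filter=patch_filter,
            score_threshold=config.score_threshold,
            source_id=row.image_id,
        )
        n_gated_out += int((~result.kept).sum())
        for d in result.detections:
            det_rows.append(
                {"image_id": row.image_id, "x0": d.box.x0, "y0": d.box.y0,
                 "x1": d.box.x1, "y1": d.box.y1, "score": d.score}
            )
        for i, (origin, score) in enumerate(zip(result.patch_origins, result.per_patch_scores)):
            score_rows.append(
                {"image_id": row.image_id, "patch_index": i,
                 "origin_x": origin[0], "origin_y": origin[1],
                 "score": float(score), "kept": bool(result.kept[i])}
            )
    pd.DataFrame(det_rows, columns=["image_id", "x0", "y0", "x1", "y1", "score"]).to_csv(
        os.path.join(out_dir, "detections.csv"), index=False
    )
    pd.DataFrame(score_rows).to_csv(os.path.join(out_dir, "patch_scores.csv"), index=False)
    _log(config, "detect", {
        "n_detections": len(det_rows),
        "n_patches": len(score_rows),
        "n_gated_out": n_gated_out,
        "use_gate": config.use_gate,
    })


# ------------------------------------------------------------- evaluate

def run_evaluate(config: RunConfig) -> Dict:
    """Fold-aggregated exudate-level and image-level evaluation."""
    manifest = _load_manifest(config)
    objects_df, folds_df, _ = _load_prepared(config)
    det_path = os.path.join(config.out_dir, "detections", "detections.csv")
    score_path = os.path.join(config.out_dir, "detections", "patch_scores.csv")
    _require(det_path, "evaluate")
    _require(score_path, "evaluate")
    det_df = pd.read_csv(det_path)
    score_df = pd.read_csv(score_path)
    fold_of = dict(zip(folds_df.image_id, folds_df.fold))

    per_image_rows = []
    fold_counts: Dict[int, List[int]] = {f: [0, 0, 0, 0] for f in range(config.k_folds)}
    decisions, labels, max_scores = [], [], []
    for _, row in manifest.iterrows():
        sample = synth.load_sample(row.image_path, row.mask_path)
        objects = _objects_for(objects_df, row.image_id)
        rows = det_df[det_df.image_id == row.image_id]
        detections = [
            det.Detection(BoundingBox(int(r.x0), int(r.y0), int(r.x1), int(r.y1)),
                          float(r.score))
            for r in rows.itertuples()
        ]
        counts, _status = ev.match_exudate_level(
            objects, detections, sample.mask.shape,
            overlap_min=config.overlap_min, mode=config.mode,
        )
        fold = fold_of[row.image_id]
        for i, v in enumerate((counts.tp, counts.fp, counts.fn, counts.tn)):
            fold_counts[fold][i] += v
        per_image_rows.append(
            {"image_id": row.image_id, "fold": fold, "tp": counts.tp,
             "fp": counts.fp, "fn": counts.fn, "tn": counts.tn}
        )
        patch_scores = score_df[score_df.image_id == row.image_id].score.to_numpy()
        decisions.append(ev.image_level_decision(patch_scores, tau=config.tau))
        labels.append(bool(row.label))
        max_scores.append(float(patch_scores.max()) if patch_scores.size else 0.0)

    exudate_fold_metrics = []
    image_fold_metrics = []
    for fold in range(config.k_folds):
        tp, fp, fn, tn = fold_counts[fold]
        exudate_fold_metrics.append(ev.compute_metrics(ev.PixelCounts(tp, fp, fn, tn)))
        in_fold = [i for i, (_, r) in enumerate(manifest.iterrows())
                   if fold_of[r.image_id] == fold]
        _, m = ev.image_level_metrics(
            [decisions[i] for i in in_fold], [labels[i] for i in in_fold]
        )
        image_fold_metrics.append(m)

    summary = {
        "exudate_level": {
            "per_fold": [m.as_dict() for m in exudate_fold_metrics],
            "aggregate": {k: list(v) for k, v in ev.aggregate_folds(exudate_fold_metrics).items()},
        },
        "image_level": {
            "per_fold": [m.as_dict() for m in image_fold_metrics],
            "aggregate": {k: list(v) for k, v in ev.aggregate_folds(image_fold_metrics).items()},
        },
        "auc": ev.roc_auc(max_scores, labels) if len(set(labels)) > 1 else None,
    }
    eval_dir = os.path.join(config.out_dir, "evaluation")
    os.makedirs(eval_dir, exist_ok=True)
    pd.DataFrame(per_image_rows).to_csv(
        os.path.join(eval_dir, "exudate_per_image.csv"), index=False
    )
    if len(set(labels)) > 1:
        fpr, tpr, thr = ev.roc_points(max_scores, labels)
        pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
            os.path.join(eval_dir, "roc.csv"), index=False
        )
    with open(os.path.join(eval_dir, "evaluation.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    _log(config, "evaluate", {
        "auc": summary["auc"],
        "exudate_mean": summary["exudate_level"]["aggregate"],
    })
    return summary


# --------------------------------------------------------------- report

VARIANTS = {
    "frcnn": {"use_gate": False, "use_jitter": False},
    "frcnn_svm": {"use_gate": True, "use_jitter": False},
    "frcnn_ca": {"use_gate": False, "use_jitter": True},
    "frcnn_ca_svm": {"use_gate": True, "use_jitter": True},
}


def run_experiment(config: RunConfig) -> Dict[str, Dict]:
    """Run all four variants over shared data, folds, and gate models."""
    run_synth(config)
    run_prepare(config)
    run_build_svm_set(config)
    run_train_gate(config)
    summaries = {}
    for name, switches in VARIANTS.items():
        vcfg = replace(config, **switches)
        vcfg.out_dir = os.path.join(config.out_dir, "variants", name)
        os.makedirs(vcfg.out_dir, exist_ok=True)
        # share upstream artifacts via symlink-free copy of paths: stages
        # below read from the parent run directory
        for sub in ("data", "prepared", "svm", "gate"):
            src = os.path.join(config.out_dir, sub)
            dst = os.path.join(vcfg.out_dir, sub)
            if not os.path.exists(dst):
                os.symlink(os.path.abspath(src), dst)
        run_train_detector(vcfg)
        run_detect(vcfg)
        summaries[name] = run_evaluate(vcfg)
    return summaries


def report(config: RunConfig) -> str:
    """Table of variant metrics (mean +/- sd) plus the gate's FPR/FNR deltas."""
    summaries = {}
    for name in VARIANTS:
        path = os.path.join(config.out_dir, "variants", name, "evaluation", "evaluation.json")
        if os.path.exists(path):
            with open(path) as fh:
                summaries[name] = json.load(fh)
    if not summaries:
        raise FileNotFoundError(
            f"no variant evaluations under {config.out_dir}/variants; run the pipeline first"
        )
    lines = []
    for level in ("exudate_level", "image_level"):
        lines.append(f"== {level.replace('_', ' ')} ==")
        header = ["variant"] + list(ev.METRIC_NAMES)
        lines.append("  ".join(f"{h:>12}" for h in header))
        for name, summary in summaries.items():
            agg = summary[level]["aggregate"]
            cells = [f"{name:>12}"]
            for metric in ev.METRIC_NAMES:
                if metric in agg:
                    mu, sd = agg[metric]
                    cells.append(f"{mu:.4f}±{sd:.4f}")
                else:
                    cells.append("     —      ")
            lines.append("  ".join(cells))
    for base, gated in (("frcnn", "frcnn_svm"), ("frcnn_ca", "frcnn_ca_svm")):
        if base in summaries and gated in summaries:
            for level in ("exudate_level", "image_level"):
                for metric in ("fpr", "fnr"):
                    b = summaries[base][level]["aggregate"].get(metric)
                    g = summaries[gated][level]["aggregate"].get(metric)
                    if b and g and b[0] > 0:
                        delta = ev.relative_change(b[0], g[0])
                        lines.append(
                            f"gate effect on {level} {metric} ({base} -> {gated}): "
                            f"{delta:+.1f}%"
                        )
    text = "\n".join(lines)
    with open(os.path.join(config.out_dir, "report.txt"), "w") as fh:
        fh.write(text + "\n")
    return text


def oracle_patch_filter(objects: Sequence[ann.ExudateObject]):
    """A ground-truth gate: keep exactly the patches intersecting a lesion box.

    Used to measure the best case of pre-scanning — what a perfect gate
    would do to the false-positive pixel count — independently of any
    trained classifier.
    """

    def keep(patch: pt.Patch) -> bool:
        positive, _ = ann.label_patch(objects, patch)
        return positive

    return keep
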