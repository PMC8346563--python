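"""Train and cross-validate the SVM pre-scanning gate.

Patches from exudate and healthy images are labelled by ground-truth box
intersection; each fold's training set holds twice as many negatives as
positives (drawn from retinopathy background and healthy images, skipping
patches that are more than a third black) plus four pure-black patches.
A linear SVM over deterministic hand-crafted features then separates
exudate from exudate-free patches.
"""

import numpy as np

from exudetect import (
    SynthConfig, ToyFeatureExtractor, assemble_svm_dataset, gate_cv_accuracy,
    label_patch, mask_to_objects, pad_to_multiple, sample_dataset,
    shifted_tiles, tile,
)
from exudetect.gate import extract_features_batch

samples = sample_dataset(
    SynthConfig(width=672, height=672, n_lesions=(1, 3), seed=11), 12, positive_fraction=2 / 3
)
extractor = ToyFeatureExtractor()
folds = []
for start in range(3):  # interleave images into 3 folds with both classes
    positives, pool_dr, pool_healthy = [], [], []
    for idx in range(start, 12, 3):
        s = samples[idx]
        objects = mask_to_objects(s.mask)
        padded = pad_to_multiple(s.image, source_id=f"img{idx}")
        for patch in tile(padded) + shifted_tiles(padded):
            has_exudate, _ = label_patch(objects, patch)
            if has_exudate:
                positives.append(patch)
            elif s.label:
                pool_dr.append(patch)
            else:
                pool_healthy.append(patch)
    ds = assemble_svm_dataset(positives, pool_dr, pool_healthy, rng=start)
    folds.append((extract_features_batch(ds.patches, extractor), ds.labels))
    print(f"fold {start}: {int(ds.labels.sum())} positive / "
          f"{int((1 - ds.labels).sum())} negative patches")

per_fold, mean = gate_cv_accuracy(folds)
print(f"per-fold validation accuracy: {[round(a, 3) for a in per_fold]}")
print(f"mean cross-validated accuracy: {mean:.3f}")
majority = max(np.concatenate([y for _, y in folds]).mean(),
               1 - np.concatenate([y for _, y in folds]).mean())
print(f"majority-class baseline: {majority:.3f}")
# The gate is useful exactly when its accuracy clears the majority baseline:
# every rejected patch skips the (much slower) object detector.
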