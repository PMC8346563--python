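"""Feature extraction and the linear SVM pre-scanning gate."""

import numpy as np
import pytest

from exudetect import (
    GateModel,
    ResNet50AvgPoolExtractor,
    SynthConfig,
    ToyFeatureExtractor,
    assemble_svm_dataset,
    extract_features,
    gate_classify,
    gate_cv_accuracy,
    gate_filter,
    label_patch,
    mask_to_objects,
    pad_to_multiple,
    sample_dataset,
    tile,
    train_gate,
)
from exudetect.gate import extract_features_batch

from conftest import make_patch
from helpers_oracles import hard_margin_oracle


class TestFeatureExtraction:
    def test_toy_extractor_closed_form_on_all_zero_patch(self):
        ex = ToyFeatureExtractor(bins=16)
        vec = extract_features(make_patch(0), ex)
        assert vec.shape == (ex.dim,)
        # all histogram mass in the first bin of each channel
        for c in range(3):
            hist = vec[c * 16 : (c + 1) * 16]
            assert hist[0] == 1.0 and (hist[1:] == 0).all()
        # zero gradients and zero contrast tails
        assert (vec[48:] == 0).all()

    def test_toy_extractor_deterministic(self, rng):
        patch = make_patch(pixels=rng.integers(0, 255, (224, 224, 3), dtype=np.uint8))
        ex = ToyFeatureExtractor()
        assert np.array_equal(extract_features(patch, ex), extract_features(patch, ex))

    def test_residual_backbone_contract_is_2048(self):
        assert ResNet50AvgPoolExtractor.dim == 2048

    def test_declared_dim_enforced(self):
        class Broken(ToyFeatureExtractor):
            def __call__(self, patch):
                return np.zeros(3)

        with pytest.raises(ValueError):
            extract_features(make_patch(0), Broken())


class TestTrainGate:
    def test_symmetric_pair_boundary_at_zero(self):
        model = train_gate(np.array([[-1.0], [1.0]]), [0, 1])
        # boundary at the origin, both points on the right side
        assert gate_classify(model, np.array([0.0]))[0]  # tie -> positive
        assert gate_classify(model, np.array([1.0])) == (True, pytest.approx(1.0, abs=1e-6))
        assert gate_classify(model, np.array([-1.0]))[0] is False

    def test_separable_set_trains_to_perfect_accuracy(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        model = train_gate(X, y)
        preds = [gate_classify(model, x)[0] for x in X]
        assert (np.array(preds) == (y == 1)).all()

    def test_matches_hard_margin_qp_oracle(self):
        """On a tiny separable 2-D set the fitted separator agrees with a
        direct quadratic-programme solve of the max-margin problem."""
        X = np.array([[0.0, 1.0], [1.0, 2.0], [-1.0, 1.5], [0.0, -1.0], [1.0, -2.0], [-0.5, -1.2]])
        y = np.array([1, 1, 1, -1, -1, -1])
        w_ref, b_ref = hard_margin_oracle(X, y)
        model = train_gate(X, (y > 0).astype(int), C=100.0)
        assert np.allclose(model.weights, w_ref, atol=1e-3)
        assert model.bias == pytest.approx(b_ref, abs=1e-3)
        for x in X:
            _, margin = gate_classify(model, x)
            assert margin == pytest.approx(float(w_ref @ x + b_ref), abs=5e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_gate(np.zeros((3, 2)), [1, 1, 1])

    def test_scaling_features_preserves_separability(self, rng):
        X = np.vstack([rng.normal(-2, 0.2, (15, 3)), rng.normal(2, 0.2, (15, 3))])
        y = np.array([0] * 15 + [1] * 15)
        model = train_gate(X * 50.0, y)
        preds = [gate_classify(model, x)[0] for x in X * 50.0]
        assert (np.array(preds) == (y == 1)).all()


class TestGateClassifyAndFilter:
    def test_zero_margin_is_positive(self):
        model = GateModel(weights=np.array([1.0, -1.0]), bias=0.0, extractor_id="x")
        positive, margin = gate_classify(model, np.array([2.0, 2.0]))
        assert positive and margin == 0.0

    def test_negating_model_flips_every_label(self, rng):
        model = GateModel(weights=rng.normal(size=4), bias=0.3, extractor_id="x")
        negated = GateModel(weights=-model.weights, bias=-model.bias, extractor_id="x")
        for _ in range(20):
            x = rng.normal(size=4)
            a, ma = gate_classify(model, x)
            b, mb = gate_classify(negated, x)
            assert mb == pytest.approx(-ma)
            if ma != 0:
                assert a != b

    def test_margin_is_plain_dot_product(self, rng):
        model = GateModel(weights=rng.normal(size=6), bias=-0.7, extractor_id="x")
        x = rng.normal(size=6)
        _, margin = gate_classify(model, x)
        assert margin == pytest.approx(float(np.dot(model.weights, x) + model.bias))

    def test_length_mismatch_rejected(self):
        model = GateModel(weights=np.ones(3), bias=0.0, extractor_id="x")
        with pytest.raises(ValueError):
            gate_classify(model, np.ones(4))

    def _extractor_and_patches(self, rng, n=6):
        ex = ToyFeatureExtractor()
        patches = [
            make_patch(pixels=rng.integers(0, 255, (224, 224, 3), dtype=np.uint8),
                       source_id=f"p{i}")
            for i in range(n)
        ]
        return ex, patches

    def test_accept_all_and_reject_all_models(self, rng):
        ex, patches = self._extractor_and_patches(rng)
        accept = GateModel(weights=np.zeros(ex.dim), bias=1.0, extractor_id=ex.extractor_id)
        reject = GateModel(weights=np.zeros(ex.dim), bias=-1.0, extractor_id=ex.extractor_id)
        assert gate_filter(patches, accept, ex) == patches
        assert gate_filter(patches, reject, ex) == []

    def test_filter_matches_per_patch_classification_and_is_idempotent(self, rng):
        ex, patches = self._extractor_and_patches(rng, n=10)
        weights = rng.normal(size=ex.dim)
        model = GateModel(weights=weights, bias=-float(np.median(
            [weights @ extract_features(p, ex) for p in patches])), extractor_id=ex.extractor_id)
        kept = gate_filter(patches, model, ex)
        expected = [p for p in patches if gate_classify(model, extract_features(p, ex))[0]]
        assert kept == expected
        assert gate_filter(kept, model, ex) == kept  # idempotent


class TestCrossValidation:
    def test_identical_separable_folds_score_one(self, rng):
        X = np.vstack([rng.normal(-3, 0.2, (10, 2)), rng.normal(3, 0.2, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        folds = [(X, y)] * 4
        per_fold, mean = gate_cv_accuracy(folds)
        assert per_fold == [1.0] * 4 and mean == 1.0

    def test_random_labels_score_near_majority_rate(self):
        rng = np.random.default_rng(7)
        folds = []
        for _ in range(4):
            X = rng.normal(size=(120, 5))
            y = rng.integers(0, 2, size=120)
            folds.append((X, y))
        _, mean = gate_cv_accuracy(folds)
        assert abs(mean - 0.5) < 0.12

    def test_single_class_training_union_flagged(self):
        X = np.zeros((4, 2))
        folds = [(X, np.zeros(4)), (X, np.zeros(4)), (X, np.ones(4))]
        with pytest.raises(ValueError):
            gate_cv_accuracy(folds)

    def test_synthetic_gate_beats_majority_baseline(self):
        """With lesion gain far above noise, cross-validated gate accuracy
        exceeds the majority-class rate by at least 10 points."""
        cfg = SynthConfig(width=672, height=672, n_lesions=(1, 2), seed=31)
        samples = sample_dataset(cfg, 12, positive_fraction=2 / 3)
        extractor = ToyFeatureExtractor()
        folds = []
        for start in range(3):  # interleave so every fold has both classes
            positives, pool_dr, pool_healthy = [], [], []
            for s_idx in range(start, 12, 3):
                s = samples[s_idx]
                objects = mask_to_objects(s.mask)
                for patch in tile(pad_to_multiple(s.image, source_id=f"i{s_idx}")):
                    pos, _ = label_patch(objects, patch)
                    if pos:
                        positives.append(patch)
                    elif s.label:
                        pool_dr.append(patch)
                    else:
                        pool_healthy.append(patch)
            ds = assemble_svm_dataset(positives, pool_dr, pool_healthy, rng=start)
            folds.append((extract_features_batch(ds.patches, extractor), ds.labels))
        _, mean = gate_cv_accuracy(folds)
        labels_all = np.concatenate([y for _, y in folds])
        majority = max(labels_all.mean(), 1 - labels_all.mean())
        assert mean >= majority + 0.10
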