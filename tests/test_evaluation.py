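"""Filled-box overlap matching, metrics, image-level rules, AUC, aggregation."""

import numpy as np
import pytest

from exudetect import (
    BoundingBox,
    Detection,
    ExudateObject,
    MetricSet,
    PixelCounts,
    aggregate_folds,
    compute_metrics,
    fill_boxes,
    image_level_decision,
    image_level_metrics,
    match_exudate_level,
    relative_change,
    roc_auc,
)

from helpers_oracles import auc_oracle, match_oracle


def obj(x0, y0, x1, y1):
    box = BoundingBox(x0, y0, x1, y1)
    return ExudateObject(box=box, component_id=1, pixel_count=box.area)


def det(x0, y0, x1, y1, score=0.9):
    return Detection(box=BoundingBox(x0, y0, x1, y1), score=score)


class TestFillBoxes:
    def test_single_box_pixel_count(self):
        assert fill_boxes([BoundingBox(3, 4, 13, 14)], (30, 30)).sum() == 100

    def test_overlapping_union_matches_rasterisation_oracle(self, rng):
        shape = (40, 50)
        boxes = []
        for _ in range(4):
            x0, y0 = rng.integers(0, 30), rng.integers(0, 25)
            boxes.append(BoundingBox(int(x0), int(y0), int(x0 + rng.integers(1, 15)),
                                     int(y0 + rng.integers(1, 12))))
        got = fill_boxes(boxes, shape)
        oracle = set()
        for b in boxes:
            oracle |= {(y, x) for y in range(b.y0, b.y1) for x in range(b.x0, b.x1)}
        assert int(got.sum()) == len(oracle)
        assert {(y, x) for y, x in zip(*np.nonzero(got))} == oracle

    def test_empty_list_gives_all_zero(self):
        assert not fill_boxes([], (10, 10)).any()

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            fill_boxes([BoundingBox(5, 5, 15, 15)], (10, 10))


class TestMatchExudateLevel:
    def test_quarter_overlap_counts_as_found(self):
        counts, status = match_exudate_level(
            [obj(0, 0, 10, 10)], [det(5, 0, 10, 5)], (20, 20)  # 25 of 100 px
        )
        assert status.found == [True]
        assert counts.tp == 100 and counts.fn == 0

    def test_exactly_twenty_percent_is_not_found(self):
        counts, status = match_exudate_level(
            [obj(0, 0, 10, 10)], [det(0, 0, 4, 5)], (20, 20)  # 20 of 100 px
        )
        assert status.found == [False]
        assert counts.fn == 100 and counts.tp == 0
        assert status.best_overlap == [pytest.approx(0.2)]

    def test_any_overlap_mode_accepts_one_pixel(self):
        counts, status = match_exudate_level(
            [obj(0, 0, 10, 10)], [det(9, 9, 30, 30)], (40, 40), mode="any_overlap"
        )
        assert status.found == [True] and status.matched == [True]

    def test_zero_detections_all_ground_truth_is_missed(self):
        counts, _ = match_exudate_level([obj(2, 2, 7, 7)], [], (10, 10))
        assert counts.tp == 0 and counts.fp == 0 and counts.fn == 25
        assert counts.tn == 75

    def test_unmatched_detection_contributes_false_positives(self):
        counts, status = match_exudate_level(
            [obj(0, 0, 10, 10)], [det(20, 20, 30, 30)], (40, 40)
        )
        assert status.matched == [False]
        assert counts.fp == 100 and counts.fn == 100

    def test_min_denominator_flag(self):
        # detection of 25 px covering 25 of a 200-px object: 12.5% of gt
        # but 100% of the smaller detection
        gt, d = [obj(0, 0, 20, 10)], [det(0, 0, 5, 5)]
        _, strict_gt = match_exudate_level(gt, d, (30, 30), denominator="gt")
        _, strict_min = match_exudate_level(gt, d, (30, 30), denominator="min")
        assert strict_gt.found == [False]
        assert strict_min.found == [True]

    def test_invalid_overlap_min_rejected(self):
        with pytest.raises(ValueError):
            match_exudate_level([], [], (5, 5), overlap_min=1.0)

    @pytest.mark.parametrize("mode", ["strict", "any_overlap"])
    def test_random_scenes_match_set_based_oracle(self, mode, rng):
        for _ in range(40):
            shape = (int(rng.integers(16, 64)), int(rng.integers(16, 64)))
            h, w = shape

            def rand_boxes(n):
                out = []
                for _ in range(n):
                    x0, y0 = int(rng.integers(0, w - 2)), int(rng.integers(0, h - 2))
                    out.append((x0, y0, int(rng.integers(x0 + 1, w)), int(rng.integers(y0 + 1, h))))
                return out

            gt = rand_boxes(int(rng.integers(0, 4)))
            dd = rand_boxes(int(rng.integers(0, 4)))
            counts, status = match_exudate_level(
                [obj(*b) for b in gt], [det(*b) for b in dd], shape, mode=mode
            )
            oracle = match_oracle(gt, dd, shape, mode=mode)
            assert (counts.tp, counts.fp, counts.fn, counts.tn) == (
                oracle["tp"], oracle["fp"], oracle["fn"], oracle["tn"]
            )
            assert status.found == oracle["found"]
            assert status.matched == oracle["matched"]
            assert counts.total == shape[0] * shape[1]

    def test_lowering_overlap_threshold_never_loses_objects(self, rng):
        gt = [obj(0, 0, 10, 10), obj(20, 20, 35, 30), obj(40, 5, 50, 18)]
        dd = [det(5, 0, 12, 8), det(22, 21, 28, 26), det(41, 6, 44, 9)]
        found_counts = []
        for om in (0.8, 0.6, 0.4, 0.2, 0.05, 0.0):
            _, status = match_exudate_level(gt, dd, (60, 60), overlap_min=om)
            found_counts.append(sum(status.found))
        assert found_counts == sorted(found_counts)


class TestComputeMetrics:
    def test_direct_substitution(self):
        m = compute_metrics(PixelCounts(tp=9, fn=1, fp=0, tn=90))
        assert m.sensitivity == pytest.approx(0.9)
        assert m.fnr == pytest.approx(0.1)
        assert m.ppv == 1.0

    def test_perfect_scores_give_unit_f1(self):
        m = compute_metrics(PixelCounts(tp=10, fn=0, fp=0, tn=10))
        assert m.sensitivity == 1.0 and m.ppv == 1.0 and m.f1 == 1.0

    def test_random_counts_match_long_hand_fractions(self, rng):
        for _ in range(25):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 50, 4))
            m = compute_metrics(PixelCounts(tp, fp, fn, tn))
            if tp + fn:
                assert m.sensitivity == pytest.approx(tp / (tp + fn))
                assert m.fnr == pytest.approx(fn / (fn + tp))
                assert m.sensitivity + m.fnr == pytest.approx(1.0)
            else:
                assert m.sensitivity is None and m.fnr is None
            if tn + fp:
                assert m.specificity == pytest.approx(tn / (tn + fp))
                assert m.fpr == pytest.approx(fp / (fp + tn))
                assert m.specificity + m.fpr == pytest.approx(1.0)
            if tp + fp:
                assert m.ppv == pytest.approx(tp / (tp + fp))
            if (tp + fn) and (tp + fp) and (m.sensitivity + m.ppv):
                assert m.f1 == pytest.approx(
                    2 * m.sensitivity * m.ppv / (m.sensitivity + m.ppv)
                )

    def test_all_zero_counts_are_undefined(self):
        m = compute_metrics(PixelCounts(0, 0, 0, 0))
        assert all(v is None for v in m.as_dict().values())


class TestImageLevel:
    def test_decision_threshold_rule(self):
        assert image_level_decision([0.3, 0.95]) is True
        assert image_level_decision([0.89]) is False
        assert image_level_decision([0.9]) is True  # equal-or-higher
        assert image_level_decision([]) is False

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            image_level_decision([1.2])

    def test_all_correct_gives_unit_accuracy(self):
        _, m = image_level_metrics([True, False, True], [True, False, True])
        assert m.accuracy == 1.0

    def test_all_positive_on_all_negative(self):
        counts, m = image_level_metrics([True, True], [False, False])
        assert m.fpr == 1.0 and m.specificity == 0.0
        assert counts.total == 2

    def test_constructed_confusion_table(self):
        decisions = [True] * 6 + [False] * 4 + [True] * 3 + [False] * 7
        labels = [True] * 10 + [False] * 10
        counts, m = image_level_metrics(decisions, labels)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (6, 4, 3, 7)
        assert m.accuracy == pytest.approx(13 / 20)
        assert m.ppv == pytest.approx(6 / 9)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_reversed_scores(self):
        assert roc_auc([0.1, 0.2, 0.9, 0.8], [1, 1, 0, 0]) == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        scores = rng.random(400)
        labels = rng.integers(0, 2, 400)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.08

    def test_matches_pairwise_probability_oracle_with_ties(self, rng):
        scores = rng.integers(0, 5, 60) / 4.0  # coarse grid forces ties
        labels = rng.integers(0, 2, 60).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert roc_auc(scores, labels) == pytest.approx(auc_oracle(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestRelativeChange:
    def test_headline_reduction_arithmetic(self):
        assert relative_change(0.0037, 0.0026) == pytest.approx(-29.73, abs=0.01)
        assert relative_change(0.5143, 0.2571) == pytest.approx(-50.01, abs=0.01)

    def test_no_change_is_zero(self):
        assert relative_change(0.4, 0.4) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            relative_change(0.0, 0.1)


class TestAggregateFolds:
    def _metric(self, **kw):
        base = dict(sensitivity=None, specificity=None, accuracy=None,
                    f1=None, ppv=None, fpr=None, fnr=None)
        base.update(kw)
        return MetricSet(**base)

    def test_identical_folds_have_zero_spread(self):
        m = self._metric(sensitivity=0.8, f1=0.6)
        agg = aggregate_folds([m, m, m])
        assert agg["sensitivity"] == (pytest.approx(0.8), pytest.approx(0.0))

    def test_two_fold_mean(self):
        agg = aggregate_folds([self._metric(sensitivity=0.8), self._metric(sensitivity=1.0)])
        assert agg["sensitivity"][0] == pytest.approx(0.9)

    def test_matches_long_hand_mean_and_sd(self, rng):
        vals = rng.random(5)
        folds = [self._metric(ppv=float(v)) for v in vals]
        mu, sd = aggregate_folds(folds)["ppv"]
        assert mu == pytest.approx(vals.mean())
        assert sd == pytest.approx(vals.std(ddof=1))

    def test_f1_is_averaged_not_recomputed(self):
        """Mean F1 over folds differs from the F1 of mean sensitivity and
        mean PPV; the aggregator must report the former."""
        folds = []
        for sens, ppv in ((0.99, 0.45), (0.80, 0.75)):
            f1 = 2 * sens * ppv / (sens + ppv)
            folds.append(self._metric(sensitivity=sens, ppv=ppv, f1=f1))
        agg = aggregate_folds(folds)
        mean_f1 = agg["f1"][0]
        recomputed = 2 * agg["sensitivity"][0] * agg["ppv"][0] / (
            agg["sensitivity"][0] + agg["ppv"][0]
        )
        expected = np.mean([2 * s * p / (s + p) for s, p in ((0.99, 0.45), (0.80, 0.75))])
        assert mean_f1 == pytest.approx(expected)
        assert abs(mean_f1 - recomputed) > 0.005

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([])
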