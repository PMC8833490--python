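"""Detector-evaluation metrics against closed forms and brute-force oracles."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import ap_11point_oracle, iou_raster_oracle, random_outcome_instance
from foxwatch import (
    BoundingBox,
    GroundTruthBox,
    LabelSet,
    Prediction,
    evaluate,
    interpolated_ap,
    iou,
    match_detections,
    precision_recall,
)
from foxwatch.evaluation import EvalCounts


def _box(cx, cy, w, h):
    return BoundingBox(cx, cy, w, h)


class TestIoU:
    def test_identity(self):
        a = _box(0.3, 0.7, 0.25, 0.1)
        assert iou(a, a) == pytest.approx(1.0)

    def test_disjoint(self):
        assert iou(_box(0.2, 0.2, 0.1, 0.1), _box(0.8, 0.8, 0.1, 0.1)) == 0.0

    def test_offset_squares(self):
        """Two 0.2-squares offset by 0.05 in x: inter 0.03, union 0.05 -> 0.6."""
        a = _box(0.5, 0.5, 0.2, 0.2)
        b = _box(0.55, 0.5, 0.2, 0.2)
        assert iou(a, b) == pytest.approx(0.6)
        assert iou(a, b) == pytest.approx(iou_raster_oracle(a, b), abs=1e-3)

    def test_zero_area_box_scores_zero(self):
        assert iou(_box(0.5, 0.5, 0.0, 0.2), _box(0.5, 0.5, 0.2, 0.2)) == 0.0

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_range(self, data):
        def rand_box():
            w = data.draw(st.floats(0.02, 0.6))
            h = data.draw(st.floats(0.02, 0.6))
            cx = data.draw(st.floats(w / 2, 1 - w / 2))
            cy = data.draw(st.floats(h / 2, 1 - h / 2))
            return _box(cx, cy, w, h)

        a, b = rand_box(), rand_box()
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0


class TestMatching:
    def _truths(self, boxes):
        images = {}
        for img, posture, box in boxes:
            images.setdefault(img, []).append(GroundTruthBox(img, posture, box))
        return LabelSet(class_names=("lying", "sitting", "standing"), images=images)

    def test_exact_match_is_tp(self):
        b = _box(0.5, 0.5, 0.2, 0.2)
        truths = self._truths([("i", "sitting", b)])
        m = match_detections([Prediction("i", "sitting", 0.9, b)], truths)
        c = m.counts["sitting"]
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)
        assert m.matched_ious["sitting"] == [pytest.approx(1.0)]

    def test_labeled_image_with_no_predictions_is_fn(self):
        truths = self._truths(
            [("i", "sitting", _box(0.5, 0.5, 0.2, 0.2)), ("i", "lying", _box(0.2, 0.2, 0.2, 0.2))]
        )
        m = match_detections([], truths)
        assert m.counts["sitting"].fn == 1 and m.counts["lying"].fn == 1

    def test_low_iou_is_fp_plus_fn(self):
        truths = self._truths([("i", "sitting", _box(0.5, 0.5, 0.2, 0.2))])
        # IoU 0.4 < 0.5: shifted square overlapping 4/7... use offset giving < 0.5
        pred = Prediction("i", "sitting", 0.9, _box(0.62, 0.5, 0.2, 0.2))
        assert iou(pred.box, _box(0.5, 0.5, 0.2, 0.2)) < 0.5
        c = match_detections([pred], truths).counts["sitting"]
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_iou_exactly_half_is_tp(self):
        gt = _box(0.5, 0.5, 0.2, 0.3)
        pred_box = _box(0.5, 0.5 - 0.075, 0.2, 0.15)  # nested half-height box: IoU 0.5
        assert iou(pred_box, gt) == pytest.approx(0.5)
        truths = self._truths([("i", "sitting", gt)])
        c = match_detections([Prediction("i", "sitting", 0.9, pred_box)], truths).counts["sitting"]
        assert (c.tp, c.fp) == (1, 0)

    def test_class_mismatch_is_fp(self):
        b = _box(0.5, 0.5, 0.2, 0.2)
        truths = self._truths([("i", "sitting", b)])
        m = match_detections([Prediction("i", "standing", 0.9, b)], truths)
        assert m.counts["standing"].fp == 1
        assert m.counts["sitting"].fn == 1

    def test_each_truth_matched_once(self):
        b = _box(0.5, 0.5, 0.2, 0.2)
        truths = self._truths([("i", "sitting", b)])
        preds = [Prediction("i", "sitting", 0.9, b), Prediction("i", "sitting", 0.8, b)]
        c = match_detections(preds, truths).counts["sitting"]
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_unknown_image_rejected(self):
        truths = self._truths([("i", "sitting", _box(0.5, 0.5, 0.2, 0.2))])
        with pytest.raises(ValueError, match="unknown image"):
            match_detections([Prediction("j", "sitting", 0.9, _box(0.5, 0.5, 0.2, 0.2))], truths)

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_tp_plus_fn_conservation(self, data):
        """TP + FN equals the number of ground-truth boxes per class on
        random instances."""
        postures = ("lying", "sitting", "standing")
        n_img = data.draw(st.integers(1, 4))
        images = {f"img{i}": [] for i in range(n_img)}
        preds = []
        for i in range(n_img):
            img = f"img{i}"
            for _ in range(data.draw(st.integers(0, 3))):
                images[img].append(
                    GroundTruthBox(img, data.draw(st.sampled_from(postures)), _rand_box(data))
                )
            for _ in range(data.draw(st.integers(0, 3))):
                preds.append(
                    Prediction(
                        img,
                        data.draw(st.sampled_from(postures)),
                        data.draw(st.floats(0.05, 1.0)),
                        _rand_box(data),
                    )
                )
        truths = LabelSet(postures, images)
        m = match_detections(preds, truths)
        per_class_truth = truths.boxes_per_class()
        for c, counts in m.counts.items():
            assert counts.tp + counts.fn == per_class_truth.get(c, 0)
            assert min(counts.tp, counts.fp, counts.fn) >= 0


def _rand_box(data):
    w = data.draw(st.floats(0.05, 0.5))
    h = data.draw(st.floats(0.05, 0.5))
    cx = data.draw(st.floats(w / 2, 1 - w / 2))
    cy = data.draw(st.floats(h / 2, 1 - h / 2))
    return BoundingBox(cx, cy, w, h)


@pytest.mark.parametrize(
    "counts, expected",
    [
        (EvalCounts(2, 1, 0), (2 / 3, 1.0)),
        (EvalCounts(0, 0, 5), (None, 0.0)),
        (EvalCounts(3, 0, 0), (1.0, 1.0)),
        (EvalCounts(0, 0, 0), (None, None)),
    ],
)
def test_precision_recall(counts, expected):
    p, r = precision_recall(counts)
    ep, er = expected
    assert (p is None) == (ep is None)
    if ep is not None:
        assert p == pytest.approx(ep)
    assert (r is None) == (er is None)
    if er is not None:
        assert r == pytest.approx(er)


class TestInterpolatedAP:
    def test_perfect_detector(self):
        assert interpolated_ap([(0.9, True), (0.8, True)], 2) == pytest.approx(1.0)

    def test_no_tp(self):
        assert interpolated_ap([(0.9, False), (0.8, False)], 3) == 0.0

    def test_worked_example(self):
        """TP, FP, TP over 2 truths: six grid points at precision 1.0 and
        five at 2/3, so AP = (6 + 10/3)/11 = 28/33."""
        ap = interpolated_ap([(0.9, True), (0.8, False), (0.7, True)], 2)
        assert ap == pytest.approx(28 / 33, abs=1e-12)

    def test_zero_truths_rejected(self):
        with pytest.raises(ValueError):
            interpolated_ap([(0.9, True)], 0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(300):
            outcomes, n_truths = random_outcome_instance(rng)
            assert interpolated_ap(outcomes, n_truths) == pytest.approx(
                ap_11point_oracle(outcomes, n_truths), abs=1e-12
            )

    def test_monotone_in_extra_tp_and_fp(self, rng):
        for _ in range(100):
            outcomes, n_truths = random_outcome_instance(rng)
            base = interpolated_ap(outcomes, n_truths)
            covered = sum(f for _, f in outcomes)
            if covered < n_truths:
                more = interpolated_ap(outcomes + [(0.01, True)], n_truths)
                assert more >= base - 1e-12
            worse = interpolated_ap(outcomes + [(0.001, False)], n_truths)
            assert worse <= base + 1e-12


class TestEvaluate:
    def _three_class_fixture(self):
        postures = ("lying", "sitting", "standing")
        images, preds = {}, []
        for i, p in enumerate(postures):
            for j in range(3):
                img = f"{p}{j}"
                box = BoundingBox(0.3 + 0.05 * j, 0.4 + 0.05 * i, 0.2, 0.2)
                images[img] = [GroundTruthBox(img, p, box)]
                preds.append(Prediction(img, p, 0.9 - 0.01 * j, box))
        return preds, LabelSet(postures, images)

    def test_perfect_predictions(self):
        preds, truths = self._three_class_fixture()
        r = evaluate(preds, truths)
        assert r.map_ == pytest.approx(1.0)
        assert r.precision == pytest.approx(1.0)
        assert r.recall == pytest.approx(1.0)
        assert r.mean_iou == pytest.approx(1.0)
        assert r.n_classes == 3

    def test_map_is_mean_of_class_aps(self):
        b = BoundingBox(0.5, 0.5, 0.2, 0.2)
        far = BoundingBox(0.1, 0.1, 0.1, 0.1)
        images = {
            "a": [GroundTruthBox("a", "lying", b)],
            "b": [GroundTruthBox("b", "sitting", b)],
        }
        truths = LabelSet(("lying", "sitting"), images)
        preds = [
            Prediction("a", "lying", 0.9, b),  # perfect class: AP 1
            Prediction("b", "sitting", 0.9, far),  # no-TP class: AP 0
        ]
        r = evaluate(preds, truths)
        assert r.per_class["lying"].ap == pytest.approx(1.0)
        assert r.per_class["sitting"].ap == pytest.approx(0.0)
        assert r.map_ == pytest.approx(0.5)

    def test_corrupted_fixture_matches_oracle(self, rng):
        """50-image synthetic set with ~10% of predictions displaced into
        FPs: per-class AP must equal the rational-arithmetic enumeration
        oracle applied to the same matching outcomes."""
        postures = ("lying", "sitting", "standing")
        images, preds = {}, []
        for i in range(50):
            img = f"img{i}"
            p = postures[int(rng.integers(3))]
            w, h = 0.2, 0.2
            cx = float(rng.uniform(0.2, 0.8))
            cy = float(rng.uniform(0.2, 0.8))
            images[img] = [GroundTruthBox(img, p, BoundingBox(cx, cy, w, h))]
            if rng.random() < 0.1:
                cx = min(1 - w / 2, cx + 0.25)  # displaced: IoU < 0.5 -> FP
            preds.append(Prediction(img, p, float(rng.uniform(0.3, 1.0)), BoundingBox(cx, cy, w, h)))
        truths = LabelSet(postures, images)
        result = evaluate(preds, truths)
        match = match_detections(preds, truths)
        n_per_class = truths.boxes_per_class()
        for c in postures:
            expected = ap_11point_oracle(match.outcomes[c], n_per_class[c])
            assert result.per_class[c].ap == pytest.approx(expected, abs=1e-12)
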