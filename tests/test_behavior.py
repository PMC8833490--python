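"""Fusion, smoothing, posture-change counting, behavior map, overviews."""

import pytest

from foxwatch import (
    ActivityConfig,
    BehaviorMap,
    BoundingBox,
    CameraSecond,
    Detection,
    DetectionSeries,
    aggregate_overview,
    behavior_timeline,
    classify_behavior,
    count_posture_changes,
    fuse_cameras,
    smooth_posture,
)
from foxwatch.activity import ActivitySample
from foxwatch.behavior import PostureSample, TimelinePoint, build_timeline


def _cs(t, posture, conf, norm, cam="cam1"):
    return CameraSecond(t=t, posture=posture, confidence=conf, mean_norm=norm, camera_id=cam)


class TestFusion:
    def test_blind_spot_mismatch_resolved_by_confidence(self):
        """Camera 1 sees the fox partially (lying, 0.80); camera 2 sees it
        fully (standing, 0.95): the fused posture is standing."""
        (f,) = fuse_cameras([_cs(0, "lying", 0.80, 0.002)], [_cs(0, "standing", 0.95, 0.003, "cam2")])
        assert f.posture == "standing" and f.source_camera == "cam2"

    def test_larger_norm_wins(self):
        (f,) = fuse_cameras([_cs(0, "lying", 0.9, 0.002)], [_cs(0, "lying", 0.9, 0.011, "cam2")])
        assert f.mean_norm == pytest.approx(0.011)

    def test_idempotent_on_identical_inputs(self):
        a = [_cs(t, "sitting", 0.8, 0.004) for t in range(3)]
        fused = fuse_cameras(a, a)
        assert [(f.t, f.posture, f.confidence, f.mean_norm) for f in fused] == [
            (s.t, s.posture, s.confidence, s.mean_norm) for s in a
        ]

    def test_commutative(self):
        a = [_cs(0, "lying", 0.8, 0.002), _cs(1, "sitting", 0.7, None), _cs(2, None, None, 0.003)]
        b = [_cs(0, "standing", 0.9, 0.001, "cam2"), _cs(1, "standing", 0.7, 0.004, "cam2")]
        ab, ba = fuse_cameras(a, b), fuse_cameras(b, a)
        assert [(f.t, f.posture, f.confidence, f.mean_norm) for f in ab] == [
            (f.t, f.posture, f.confidence, f.mean_norm) for f in ba
        ]

    def test_single_source_wins(self):
        (f,) = fuse_cameras([_cs(0, None, None, None)], [_cs(0, "sitting", 0.6, 0.001, "cam2")])
        assert f.posture == "sitting" and f.mean_norm == 0.001

    def test_both_missing_is_no_data(self):
        (f,) = fuse_cameras([_cs(0, None, None, None)], [_cs(0, None, None, None, "cam2")])
        assert f.posture is None and f.mean_norm is None

    def test_confidence_tie_broken_by_norm(self):
        (f,) = fuse_cameras(
            [_cs(0, "lying", 0.8, 0.010)], [_cs(0, "standing", 0.8, 0.002, "cam2")]
        )
        assert f.posture == "lying"


def _frame_series(postures_confs, fps=5.0):
    records = []
    for f, pc in enumerate(postures_confs):
        if pc is None:
            records.append(Detection.gap("c", f, f / fps))
        else:
            p, conf = pc
            records.append(
                Detection("c", f, f / fps, p, conf, BoundingBox(0.5, 0.5, 0.2, 0.2))
            )
    return DetectionSeries(camera_id="c", fps=fps, records=records)


class TestSmoothing:
    def test_isolated_flip_removed(self):
        frames = [("sitting", 0.9)] * 12 + [("standing", 0.9)] + [("sitting", 0.9)] * 13
        out = smooth_posture(_frame_series(frames))
        assert all(s.posture == "sitting" for s in out)

    def test_constant_input_identity(self):
        out = smooth_posture(_frame_series([("lying", 0.8)] * 30))
        assert out and all(s.posture == "lying" for s in out)

    def test_tie_broken_by_summed_confidence(self):
        # 26 frames at 5 fps; the first full window (frames 1..25) holds 12
        # sitting votes at 0.9 and 12 standing votes at 0.6 around one gap
        frames = (
            [("standing", 0.6)]
            + [("sitting", 0.9)] * 12
            + [None]
            + [("standing", 0.6)] * 12
        )
        out = smooth_posture(_frame_series(frames))
        assert out[0].posture == "sitting"
        assert out[0].confidence == pytest.approx(0.9)

    def test_empty_window_is_no_data(self):
        frames = [("sitting", 0.9)] + [None] * 30 + [("sitting", 0.9)]
        out = smooth_posture(_frame_series(frames))
        assert any(s.posture is None for s in out)

    def test_output_label_always_in_window(self):
        frames = [("lying", 0.9)] * 10 + [("standing", 0.9)] * 30
        for s in smooth_posture(_frame_series(frames)):
            assert s.posture in {"lying", "standing"}


class TestPostureChanges:
    def _samples(self, labels, t0=0.0):
        return [PostureSample(t=t0 + i, posture=p, confidence=0.9) for i, p in enumerate(labels)]

    def test_constant_has_no_changes(self):
        assert count_posture_changes(self._samples(["lying"] * 1800)) == {}

    def test_three_changes(self):
        counts = count_posture_changes(self._samples(["lying", "sitting", "standing", "sitting"]))
        assert counts == {0.0: 3}

    def test_gap_suppresses_change(self):
        counts = count_posture_changes(self._samples(["sitting", None, "standing"]))
        assert counts == {}

    def test_change_lands_in_later_samples_bin(self):
        samples = self._samples(["lying"] * 2 + ["sitting"] * 2, t0=1798.0)
        # change occurs at t=1800, the first second of the second bin
        assert count_posture_changes(samples) == {1800.0: 1}

    def test_time_shift_invariance(self):
        labels = ["lying", "sitting", "sitting", "standing", "lying"] * 10
        a = count_posture_changes(self._samples(labels), bin_width_s=1e9)
        b = count_posture_changes(self._samples(labels, t0=12345.0), bin_width_s=1e9)
        assert sum(a.values()) == sum(b.values())


class TestBehaviorMap:
    def test_default_has_seven_labels(self):
        assert len(BehaviorMap.default().labels) == 7

    def test_strict_nine_has_nine(self):
        assert len(BehaviorMap.strict_nine().labels) == 9

    @pytest.mark.parametrize(
        "posture, activity, behavior",
        [
            ("standing", "active", "active standing"),
            ("standing", "highly_active", "highly active standing"),
            ("standing", "inactive", "standing still"),
            ("lying", "inactive", "lying motionless"),
            ("lying", "highly_active", "active lying"),  # 7-label collapse
            ("sitting", "highly_active", "active sitting"),
            ("sitting", "inactive", "sitting still"),
        ],
    )
    def test_default_assignments(self, posture, activity, behavior):
        assert classify_behavior(posture, activity) == behavior

    def test_strict_nine_keeps_highly_active_variants(self):
        m = BehaviorMap.strict_nine()
        assert classify_behavior("lying", "highly_active", m) == "highly active lying"
        assert classify_behavior("sitting", "highly_active", m) == "highly active sitting"

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            classify_behavior("crouching", "active")
        with pytest.raises(ValueError):
            classify_behavior("lying", "sleepy")

    def test_map_must_be_total(self):
        with pytest.raises(ValueError, match="not total"):
            BehaviorMap({("lying", "inactive"): "lying motionless"})


class TestTimelineAndOverview:
    def test_behavior_timeline_joins_on_seconds(self):
        posts = [PostureSample(t=float(t), posture="lying", confidence=0.9) for t in range(5)]
        acts = [ActivitySample(t=float(t), mean_norm=0.001, level="inactive") for t in range(4)]
        out = behavior_timeline(posts, acts)
        assert [b.behavior for b in out] == ["lying motionless"] * 4 + [None]

    def test_empty_inputs_empty_timeline(self):
        assert behavior_timeline([], []) == []

    def test_one_sample_per_second(self):
        posts = [PostureSample(t=float(t), posture="sitting", confidence=0.9) for t in range(100)]
        acts = [ActivitySample(t=float(t), mean_norm=0.02, level="highly_active") for t in range(100)]
        out = behavior_timeline(posts, acts)
        assert len(out) == 100 and len({b.t for b in out}) == 100

    def test_uniform_hour_overview(self):
        """A uniform 'sitting still' hour fills two half-hour bins with
        1800 s of sitting and inactive each and zero changes."""
        timeline = [
            TimelinePoint(t=float(t), posture="sitting", activity="inactive", behavior="sitting still")
            for t in range(3600)
        ]
        bins = aggregate_overview(timeline)
        assert len(bins) == 2
        for b in bins:
            assert b.posture_seconds == {"sitting": 1800}
            assert b.activity_seconds == {"inactive": 1800}
            assert b.behavior_seconds == {"sitting still": 1800}
            assert b.posture_changes == 0

    def test_bin_totals_conserve_covered_seconds(self, short_fixture):
        from foxwatch import analyze

        timeline = analyze(short_fixture.streams).timeline
        bins = aggregate_overview(timeline)
        covered = sum(1 for p in timeline if p.behavior is not None)
        assert sum(b.covered_seconds for b in bins) == covered
        for b in bins:
            assert sum(b.behavior_seconds.values()) == b.covered_seconds

    def test_build_timeline_rederives_level_from_fused_norm(self):
        from foxwatch.behavior import FusedSample

        fused = [FusedSample(t=0.0, posture="standing", confidence=0.9, mean_norm=0.02)]
        (p,) = build_timeline(fused, ActivityConfig(), BehaviorMap.default())
        assert p.activity == "highly_active" and p.behavior == "highly active standing"
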