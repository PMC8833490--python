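"""Posture smoothing, dual-camera fusion, behavior classification, overviews.

The two enclosure cameras face each other, so each has a blind spot in
which the animal is only partially visible and systematically
misclassified (legs hidden: standing looks like lying). The pipeline
therefore smooths each camera's posture stream with a trailing 5 s mode
filter (suppressing single-frame misclassifications), then fuses the two
cameras per second: the larger displacement norm wins, and on posture
disagreement the label with the higher confidence wins.

Behavior is the cross of posture with activity level through a fixed
decision tree. The default ethogram has seven labels — highly active
standing, active standing, standing still, active sitting, sitting still,
active lying, lying motionless — with the highly-active sitting/lying
combinations collapsed onto their active variants; ``BehaviorMap.strict_nine``
keeps all nine combinations distinct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .activity import ActivitySample
from .core import ACTIVITY_LEVELS, POSTURE_RANK, POSTURES, Detection, DetectionSeries


@dataclass(frozen=True)
class PostureSample:
    """One second of smoothed posture; ``posture`` None means no data."""

    t: float
    posture: str | None
    confidence: float | None


@dataclass(frozen=True)
class CameraSecond:
    """One camera's per-second posture + activity statistic, pre-fusion."""

    t: float
    posture: str | None
    confidence: float | None
    mean_norm: float | None
    camera_id: str = ""


@dataclass(frozen=True)
class FusedSample:
    t: float
    posture: str | None
    confidence: float | None
    mean_norm: float | None
    source_camera: str = ""


@dataclass(frozen=True)
class BehaviorSample:
    t: float
    behavior: str | None


@dataclass(frozen=True)
class TimelinePoint:
    """One second of the final 1 Hz timeline (posture x activity x behavior)."""

    t: float
    posture: str | None
    activity: str | None
    behavior: str | None
    mean_norm: float | None = None
    confidence: float | None = None


@dataclass
class OverviewBin:
    """Seconds per label for each family, plus posture changes, in one bin."""

    start: float
    end: float
    posture_seconds: dict[str, int] = field(default_factory=dict)
    activity_seconds: dict[str, int] = field(default_factory=dict)
    behavior_seconds: dict[str, int] = field(default_factory=dict)
    posture_changes: int = 0
    covered_seconds: int = 0


# --------------------------------------------------------------------------
# behavior decision tree


@dataclass(frozen=True)
class BehaviorMap:
    """Total mapping (posture, activity level) -> behavior label."""

    mapping: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        domain = {(p, a) for p in POSTURES for a in ACTIVITY_LEVELS}
        missing = domain - set(self.mapping)
        if missing:
            raise ValueError(f"behavior map not total; missing {sorted(missing)}")

    def __call__(self, posture: str, activity: str) -> str:
        return classify_behavior(posture, activity, self)

    @property
    def labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for p in POSTURES:
            for a in ACTIVITY_LEVELS:
                lab = self.mapping[(p, a)]
                if lab not in seen:
                    seen.append(lab)
        return tuple(seen)

    @classmethod
    def default(cls) -> "BehaviorMap":
        """Seven-label ethogram; highly-active sitting/lying collapse onto
        the active variants."""
        return cls(
            {
                ("standing", "highly_active"): "highly active standing",
                ("standing", "active"): "active standing",
                ("standing", "inactive"): "standing still",
                ("sitting", "highly_active"): "active sitting",
                ("sitting", "active"): "active sitting",
                ("sitting", "inactive"): "sitting still",
                ("lying", "highly_active"): "active lying",
                ("lying", "active"): "active lying",
                ("lying", "inactive"): "lying motionless",
            }
        )

    @classmethod
    def strict_nine(cls) -> "BehaviorMap":
        """Nine-label variant keeping highly-active sitting/lying distinct."""
        m = dict(cls.default().mapping)
        m[("sitting", "highly_active")] = "highly active sitting"
        m[("lying", "highly_active")] = "highly active lying"
        return cls(m)


def classify_behavior(
    posture: str, activity: str, bmap: BehaviorMap | None = None
) -> str:
    """Decision tree: behavior = map(posture, activity level)."""
    if posture not in POSTURES:
        raise ValueError(f"unknown posture {posture!r}")
    if activity not in ACTIVITY_LEVELS:
        raise ValueError(f"unknown activity level {activity!r}")
    bmap = bmap or BehaviorMap.default()
    return bmap.mapping[(posture, activity)]


# --------------------------------------------------------------------------
# smoothing


def smooth_posture(
    series: DetectionSeries | Iterable[Detection],
    window_s: float = 5.0,
    step_s: float = 1.0,
) -> list[PostureSample]:
    """Trailing-window mode filter over per-frame posture labels.

    The output sample at time t is the most frequent posture among frames
    with timestamp in (t - window_s, t]; ties are broken by larger summed
    confidence, then by the fixed order lying < sitting < standing. The
    reported confidence is the maximum among the winning label's votes.
    Emission is aligned with the activity windows (first sample one full
    window after the first frame). An all-gap window yields a no-data
    sample.
    """
    records = list(series.records if isinstance(series, DetectionSeries) else series)
    if not records:
        return []
    ts = [r.timestamp for r in records]
    t0, t_last = ts[0], ts[-1]
    out: list[PostureSample] = []
    eps = 1e-9
    t = t0 + window_s
    i_lo = 0
    while t <= t_last + window_s + eps:
        # frames with timestamp in (t - window_s, t]
        while i_lo < len(records) and ts[i_lo] <= t - window_s + eps:
            i_lo += 1
        votes: dict[str, list[float]] = {}
        for r in records[i_lo:]:
            if r.timestamp > t + eps:
                break
            if not r.is_gap:
                votes.setdefault(r.posture, []).append(r.confidence)  # type: ignore[arg-type]
        if not votes:
            out.append(PostureSample(t=t, posture=None, confidence=None))
        else:
            winner = max(
                votes,
                key=lambda p: (len(votes[p]), sum(votes[p]), -POSTURE_RANK[p]),
            )
            out.append(
                PostureSample(t=t, posture=winner, confidence=max(votes[winner]))
            )
        if t >= t_last:
            break
        t += step_s
    # trim trailing sample beyond last frame time (loop guard emits at most
    # one sample past t_last when step does not divide the span)
    return [s for s in out if s.t <= t_last + eps]


# --------------------------------------------------------------------------
# fusion


def _merge_camera_second(
    posts: Sequence[PostureSample], acts: Sequence[ActivitySample], camera_id: str
) -> list[CameraSecond]:
    """Zip a camera's smoothed postures and activity samples on the 1 Hz grid."""
    act_by_t = {round(a.t): a for a in acts}
    out = []
    for p in posts:
        a = act_by_t.get(round(p.t))
        out.append(
            CameraSecond(
                t=p.t,
                posture=p.posture,
                confidence=p.confidence,
                mean_norm=a.mean_norm if a else None,
                camera_id=camera_id,
            )
        )
    return out


def fuse_cameras(
    a: Sequence[CameraSecond],
    b: Sequence[CameraSecond],
    tolerance_s: float = 0.5,
) -> list[FusedSample]:
    """Per-second fusion of two cameras observing the same animal.

    Seconds are aligned by nearest timestamp within ``tolerance_s``
    (implemented as rounding to the shared integer-second grid). Per
    second: the fused displacement norm is the max over cameras; on
    posture disagreement the higher-confidence label wins, confidence ties
    going to the camera with the larger norm, then to the fixed posture
    order. A camera with no data at a second concedes it; both absent
    yields a fused no-data sample. The operation is commutative and
    idempotent on identical inputs.
    """
    if tolerance_s <= 0:
        raise ValueError("tolerance_s must be positive")

    # nearest-neighbor join: snap to a grid of pitch 2*tolerance so that two
    # timestamps within the tolerance share a key (integer seconds for the
    # default 0.5 s tolerance on 1 Hz grids)
    def grid(t: float) -> int:
        return round(t / (2.0 * tolerance_s))

    index_a = {grid(s.t): s for s in a}
    index_b = {grid(s.t): s for s in b}
    out: list[FusedSample] = []
    for k in sorted(set(index_a) | set(index_b)):
        sa, sb = index_a.get(k), index_b.get(k)
        out.append(_fuse_pair(sa, sb))
    return out


def _norm_or_neginf(s: CameraSecond | None) -> float:
    if s is None or s.mean_norm is None:
        return -math.inf
    return s.mean_norm


def _fuse_pair(sa: CameraSecond | None, sb: CameraSecond | None) -> FusedSample:
    assert sa is not None or sb is not None
    t = sa.t if sa is not None else sb.t  # type: ignore[union-attr]
    norms = [s.mean_norm for s in (sa, sb) if s is not None and s.mean_norm is not None]
    fused_norm = max(norms) if norms else None

    with_posture = [s for s in (sa, sb) if s is not None and s.posture is not None]
    if not with_posture:
        return FusedSample(t=t, posture=None, confidence=None, mean_norm=fused_norm)
    if len(with_posture) == 1 or with_posture[0].posture == with_posture[1].posture:
        # agreement (or single source): keep label, max confidence
        best = max(
            with_posture,
            key=lambda s: (s.confidence, _norm_or_neginf(s), s.camera_id),
        )
        return FusedSample(
            t=t,
            posture=best.posture,
            confidence=max(s.confidence for s in with_posture),  # type: ignore[type-var]
            mean_norm=fused_norm,
            source_camera=best.camera_id,
        )
    best = max(
        with_posture,
        key=lambda s: (
            s.confidence,
            _norm_or_neginf(s),
            -POSTURE_RANK[s.posture],  # type: ignore[index]
            s.camera_id,
        ),
    )
    return FusedSample(
        t=t,
        posture=best.posture,
        confidence=best.confidence,
        mean_norm=fused_norm,
        source_camera=best.camera_id,
    )


def passthrough_camera(cam: Sequence[CameraSecond]) -> list[FusedSample]:
    """Single-camera degradation of fusion (identity)."""
    return [
        FusedSample(
            t=s.t,
            posture=s.posture,
            confidence=s.confidence,
            mean_norm=s.mean_norm,
            source_camera=s.camera_id,
        )
        for s in cam
    ]


# --------------------------------------------------------------------------
# posture changes, timeline, overview


def count_posture_changes(
    timeline: Sequence[PostureSample | FusedSample | TimelinePoint],
    bin_width_s: float = 1800.0,
    origin: float = 0.0,
) -> dict[float, int]:
    """Posture changes per bin (default half-hour bins aligned to origin).

    A change is two *adjacent* samples with different non-missing posture
    labels; it is counted into the bin of the later sample. A no-data
    sample between two postures suppresses the change (the transition
    cannot be located in time).
    """
    counts: dict[float, int] = {}
    prev = None
    for s in timeline:
        cur = s.posture
        if cur is not None and prev is not None and cur != prev:
            b = origin + math.floor((s.t - origin) / bin_width_s) * bin_width_s
            counts[b] = counts.get(b, 0) + 1
        prev = cur
    return counts


def behavior_timeline(
    postures: Sequence[PostureSample | FusedSample],
    activities: Sequence[ActivitySample],
    bmap: BehaviorMap | None = None,
) -> list[BehaviorSample]:
    """1 Hz behavior labels; no-data whenever either input is missing."""
    bmap = bmap or BehaviorMap.default()
    act_by_t = {round(a.t): a for a in activities}
    out: list[BehaviorSample] = []
    for p in postures:
        a = act_by_t.get(round(p.t))
        if p.posture is None or a is None or a.level is None:
            out.append(BehaviorSample(t=p.t, behavior=None))
        else:
            out.append(BehaviorSample(t=p.t, behavior=bmap.mapping[(p.posture, a.level)]))
    return out


def build_timeline(
    fused: Sequence[FusedSample],
    cfg=None,
    bmap: BehaviorMap | None = None,
) -> list[TimelinePoint]:
    """Assemble the final per-second record from fused samples.

    The activity level is re-derived from the fused (max-over-cameras)
    mean norm, then crossed with the fused posture through the behavior
    map.
    """
    from .activity import ActivityConfig, classify_activity

    cfg = cfg or ActivityConfig()
    bmap = bmap or BehaviorMap.default()
    out: list[TimelinePoint] = []
    for s in fused:
        level = classify_activity(s.mean_norm, cfg) if s.mean_norm is not None else None
        behavior = (
            bmap.mapping[(s.posture, level)]
            if s.posture is not None and level is not None
            else None
        )
        out.append(
            TimelinePoint(
                t=s.t,
                posture=s.posture,
                activity=level,
                behavior=behavior,
                mean_norm=s.mean_norm,
                confidence=s.confidence,
            )
        )
    return out


def aggregate_overview(
    timeline: Sequence[TimelinePoint],
    bin_width_s: float = 1800.0,
    origin: float = 0.0,
) -> list[OverviewBin]:
    """Per-bin time budgets (seconds per posture/activity/behavior label)
    plus posture-change counts; bins aligned to the origin clock grid."""
    bins: dict[float, OverviewBin] = {}
    for p in timeline:
        b = origin + math.floor((p.t - origin) / bin_width_s) * bin_width_s
        ob = bins.get(b)
        if ob is None:
            ob = bins[b] = OverviewBin(start=b, end=b + bin_width_s)
        if p.posture is not None:
            ob.posture_seconds[p.posture] = ob.posture_seconds.get(p.posture, 0) + 1
        if p.activity is not None:
            ob.activity_seconds[p.activity] = ob.activity_seconds.get(p.activity, 0) + 1
        if p.behavior is not None:
            ob.behavior_seconds[p.behavior] = ob.behavior_seconds.get(p.behavior, 0) + 1
            ob.covered_seconds += 1
    changes = count_posture_changes(timeline, bin_width_s, origin)
    for b, n in changes.items():
        if b in bins:
            bins[b].posture_changes = n
    return [bins[k] for k in sorted(bins)]


def timeline_to_dataframe(timeline: Sequence[TimelinePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "t": p.t,
                "posture": p.posture,
                "activity": p.activity,
                "behavior": p.behavior,
                "mean_norm": p.mean_norm,
                "confidence": p.confidence,
            }
            for p in timeline
        ],
        columns=["t", "posture", "activity", "behavior", "mean_norm", "confidence"],
    )


def overview_to_dataframe(bins: Sequence[OverviewBin]) -> pd.DataFrame:
    rows = []
    for b in bins:
        row: dict[str, object] = {
            "start": b.start,
            "end": b.end,
            "covered_seconds": b.covered_seconds,
            "posture_changes": b.posture_changes,
        }
        for fam, d in (
            ("posture", b.posture_seconds),
            ("activity", b.activity_seconds),
            ("behavior", b.behavior_seconds),
        ):
            for label, secs in sorted(d.items()):
                row[f"{fam}:{label}"] = secs
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)
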