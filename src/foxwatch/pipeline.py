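"""End-to-end orchestration: streams in, timelines and overviews out.

Workflow per camera: windowed activity statistic from box-center
displacements, trailing-mode posture smoothing; then per-second fusion
across cameras (max norm, higher-confidence posture), activity-level
classification on the fused norm, behavior classification, and binned
overview aggregation. A manifest records the configuration and package
version so any report can be regenerated bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from .activity import ActivityConfig, activity_series
from .behavior import (
    BehaviorMap,
    CameraSecond,
    FusedSample,
    OverviewBin,
    TimelinePoint,
    _merge_camera_second,
    aggregate_overview,
    build_timeline,
    count_posture_changes,
    fuse_cameras,
    overview_to_dataframe,
    passthrough_camera,
    smooth_posture,
    timeline_to_dataframe,
)
from .core import DetectionSeries, ValidationError


@dataclass
class PipelineConfig:
    """Defaults are the published operating point: 5 fps streams, 5 s/1 s
    activity windows with thresholds 0.0054/0.0094, 5 s posture smoothing,
    0.5 s camera alignment tolerance, half-hour overview bins, 7-label
    behavior map."""

    fps: float = 5.0
    activity: ActivityConfig = field(default_factory=ActivityConfig)
    smoothing_window_s: float = 5.0
    strict_nine: bool = False
    bin_width_s: float = 1800.0
    camera_tolerance_s: float = 0.5

    @property
    def behavior_map(self) -> BehaviorMap:
        return BehaviorMap.strict_nine() if self.strict_nine else BehaviorMap.default()


@dataclass
class PipelineResult:
    timeline: list[TimelinePoint]
    overview: list[OverviewBin]
    summary: dict
    config: PipelineConfig
    fused: list[FusedSample]

    def write(self, out_dir: str | Path, manifest_extra: dict | None = None) -> None:
        """Write timeline.csv, overview.csv, summary.json and manifest.json."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        timeline_to_dataframe(self.timeline).to_csv(out_dir / "timeline.csv", index=False)
        overview_to_dataframe(self.overview).to_csv(out_dir / "overview.csv", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
        manifest = {
            "config": asdict(self.config),
            "package": "foxwatch",
            "version": _package_version(),
        }
        manifest.update(manifest_extra or {})
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("foxwatch")
    except PackageNotFoundError:
        return "unknown"


def analyze(
    streams: Sequence[DetectionSeries], cfg: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full pipeline on one or two (or more) camera streams.

    With a single stream, fusion degrades to a pass-through; with more
    than two, cameras are folded pairwise in order. Streams must share a
    frame rate. Empty input produces empty reports with a warning.
    """
    cfg = cfg or PipelineConfig()
    if not streams:
        warnings.warn("no detection streams supplied; reports will be empty")
        return PipelineResult([], [], _summarize([], [], {}), cfg, [])
    rates = {s.fps for s in streams}
    if len(rates) > 1:
        raise ValidationError(f"inconsistent fps between streams: {sorted(rates)}")
    if all(len(s) == 0 for s in streams):
        warnings.warn("all detection streams are empty; reports will be empty")
        return PipelineResult([], [], _summarize([], [], {}), cfg, [])

    cam_seconds: list[list[CameraSecond]] = []
    for s in streams:
        acts = activity_series(s, cfg.activity)
        posts = smooth_posture(s, cfg.smoothing_window_s, cfg.activity.step_s)
        cam_seconds.append(_merge_camera_second(posts, acts, s.camera_id))

    if len(cam_seconds) == 1:
        fused = passthrough_camera(cam_seconds[0])
    else:
        fused_cs = cam_seconds[0]
        for other in cam_seconds[1:]:
            fused = fuse_cameras(fused_cs, other, cfg.camera_tolerance_s)
            fused_cs = [
                CameraSecond(
                    t=f.t,
                    posture=f.posture,
                    confidence=f.confidence,
                    mean_norm=f.mean_norm,
                    camera_id=f.source_camera,
                )
                for f in fused
            ]
        fused = passthrough_camera(fused_cs)

    timeline = build_timeline(fused, cfg.activity, cfg.behavior_map)
    overview = aggregate_overview(timeline, cfg.bin_width_s)
    changes = count_posture_changes(timeline, cfg.bin_width_s)
    summary = _summarize(timeline, overview, changes)
    return PipelineResult(timeline, overview, summary, cfg, fused)


def _summarize(timeline, overview, changes) -> dict:
    behavior_seconds: dict[str, int] = {}
    activity_seconds: dict[str, int] = {}
    posture_seconds: dict[str, int] = {}
    covered = 0
    for p in timeline:
        if p.behavior is not None:
            behavior_seconds[p.behavior] = behavior_seconds.get(p.behavior, 0) + 1
            covered += 1
        if p.activity is not None:
            activity_seconds[p.activity] = activity_seconds.get(p.activity, 0) + 1
        if p.posture is not None:
            posture_seconds[p.posture] = posture_seconds.get(p.posture, 0) + 1
    return {
        "seconds_total": len(timeline),
        "seconds_covered": covered,
        "behavior_seconds": dict(sorted(behavior_seconds.items())),
        "activity_seconds": dict(sorted(activity_seconds.items())),
        "posture_seconds": dict(sorted(posture_seconds.items())),
        "posture_changes_total": int(sum(changes.values())),
        "posture_changes_per_bin": {str(k): v for k, v in sorted(changes.items())},
    }


def run_pipeline(
    inputs: Sequence[str | Path],
    out_dir: str | Path,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Read detection stream files, analyze, and write the report bundle."""
    from .io import read_detections

    cfg = cfg or PipelineConfig()
    streams: list[DetectionSeries] = []
    for path in inputs:
        streams.extend(read_detections(path, fps=cfg.fps).values())
    result = analyze(streams, cfg)
    result.write(out_dir, manifest_extra={"inputs": [str(p) for p in inputs]})
    return result
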