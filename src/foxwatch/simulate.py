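"""Synthetic single-animal enclosure scenes with ground truth.

The generator emulates the study setting the pipeline was designed for:
one fox in an enclosure watched by two opposing cameras whose streams are
sampled at 5 fps. Behavior follows a continuous-time Markov chain over the
ethogram states (exponential dwell times, tens of seconds by default); the
animal's position is a reflected Gaussian random walk whose per-frame step
scale is set by the current state's activity level, calibrated so that
trailing-window mean norms land well inside the corresponding threshold
band (see docs/methods.md). Each camera renders the truth with its own
noise: missed detections, isotropic center jitter, and systematic posture
flips modeling a blind spot (e.g. standing reported as lying when the legs
are hidden), with flipped labels drawing lower confidences.

Everything is deterministic given the seed: child streams for truth and
each camera are spawned from one :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .activity import ActivityConfig, activity_series
from .behavior import BehaviorMap, smooth_posture
from .core import POSTURES, BoundingBox, Detection, DetectionSeries, GroundTruthBox, LabelSet
from .evaluation import Prediction
from .io import write_detections

#: Typical box extents (w, h) per posture: lying is wide and low, standing
#: tall, sitting compact. Only the center feeds the activity statistic;
#: sizes exercise the IoU/evaluation paths.
POSTURE_BOX: dict[str, tuple[float, float]] = {
    "lying": (0.30, 0.12),
    "sitting": (0.16, 0.22),
    "standing": (0.24, 0.20),
}

#: Ethogram states and the (posture, activity level) pair each generates.
SEVEN_STATES: dict[str, tuple[str, str]] = {
    "lying motionless": ("lying", "inactive"),
    "active lying": ("lying", "active"),
    "sitting still": ("sitting", "inactive"),
    "active sitting": ("sitting", "active"),
    "standing still": ("standing", "inactive"),
    "active standing": ("standing", "active"),
    "highly active standing": ("standing", "highly_active"),
}

NINE_STATES: dict[str, tuple[str, str]] = {
    **SEVEN_STATES,
    "highly active sitting": ("sitting", "highly_active"),
    "highly active lying": ("lying", "highly_active"),
}

DEFAULT_DWELL_MEANS: dict[str, float] = {
    "lying motionless": 60.0,
    "active lying": 25.0,
    "sitting still": 40.0,
    "active sitting": 20.0,
    "standing still": 30.0,
    "active standing": 20.0,
    "highly active standing": 25.0,
    "highly active sitting": 20.0,
    "highly active lying": 20.0,
}


@dataclass
class CameraModel:
    """Noise model for one camera rendering the truth.

    ``flip_table`` maps a true posture to the label the camera reports
    with probability ``flip_prob`` (the blind-spot misclassification).
    Confidences are Gaussian draws, clipped into (0, 1], with a lower mean
    for flipped labels.
    """

    camera_id: str = "cam1"
    miss_prob: float = 0.0
    jitter_sigma: float = 0.0
    flip_prob: float = 0.0
    flip_table: dict[str, str] = field(default_factory=dict)
    conf_correct: tuple[float, float] = (0.90, 0.05)
    conf_flipped: tuple[float, float] = (0.60, 0.10)
    size_jitter: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.miss_prob < 1 and 0 <= self.flip_prob < 1):
            raise ValueError("probabilities must be in [0, 1)")
        for src, dst in self.flip_table.items():
            if src not in POSTURES or dst not in POSTURES:
                raise ValueError(f"flip table uses unknown posture {src!r}->{dst!r}")


def default_cameras() -> list[CameraModel]:
    """The study-like two-camera setup: moderate misses and jitter on both,
    with a standing->lying blind-spot flip on camera 1 only."""
    return [
        CameraModel(
            camera_id="cam1",
            miss_prob=0.05,
            jitter_sigma=0.002,
            flip_prob=0.05,
            flip_table={"standing": "lying"},
        ),
        CameraModel(camera_id="cam2", miss_prob=0.05, jitter_sigma=0.002),
    ]


@dataclass
class SimConfig:
    """Scene and noise configuration for one simulated observation bout.

    Step scales are normalized units per frame at 5 fps; defaults
    (0.0005, 0.006, 0.012) put noiseless windowed mean norms near 0.0006,
    0.0072 and 0.0144 — firmly inside the inactive / active / highly
    active bands delimited by the 0.0054 and 0.0094 thresholds.
    """

    duration_s: float = 7200.0
    fps: float = 5.0
    seed: int = 0
    sigma_inactive: float = 0.0005
    sigma_active: float = 0.006
    sigma_high: float = 0.012
    dwell_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DWELL_MEANS))
    strict_nine: bool = False
    cameras: list[CameraModel] = field(default_factory=default_cameras)
    arena_margin: float = 0.08

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if not (0 < self.sigma_inactive < self.sigma_active < self.sigma_high):
            raise ValueError("need 0 < sigma_inactive < sigma_active < sigma_high")
        for state, mean in self.dwell_means.items():
            if state not in NINE_STATES:
                raise ValueError(f"unknown behavior state {state!r}")
            if mean <= 0:
                raise ValueError(f"non-positive dwell mean for {state!r}")

    @property
    def states(self) -> dict[str, tuple[str, str]]:
        """Reachable chain states: the ethogram restricted to the behaviors
        listed in ``dwell_means`` (so a one-entry table pins the animal to a
        single behavior)."""
        table = NINE_STATES if self.strict_nine else SEVEN_STATES
        out = {k: v for k, v in table.items() if k in self.dwell_means}
        if not out:
            raise ValueError("dwell_means leaves no reachable state")
        return out

    def sigma_for(self, level: str) -> float:
        return {
            "inactive": self.sigma_inactive,
            "active": self.sigma_active,
            "highly_active": self.sigma_high,
        }[level]


@dataclass(frozen=True)
class ExpectedSecond:
    """Known-answer 1 Hz labels under the pipeline's windowing conventions."""

    t: float
    posture: str | None
    activity: str | None
    behavior: str | None


@dataclass
class TruthTrace:
    """Ground truth of one simulated bout.

    Frame-level: timestamps, positions in the unit square, posture and
    generating state. Second-level: the instantaneous state's posture,
    activity level and behavior at each integer second.
    """

    fps: float
    frame_t: np.ndarray
    pos: np.ndarray  # (n, 2)
    frame_posture: list[str]
    frame_state: list[str]
    sec_t: np.ndarray
    sec_posture: list[str]
    sec_activity: list[str]
    sec_behavior: list[str]

    @property
    def n_frames(self) -> int:
        return len(self.frame_t)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold an unbounded walk into [lo, hi] (reflecting boundaries)."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    return lo + width - np.abs(y - width)


def simulate_truth(cfg: SimConfig, rng: np.random.Generator | None = None) -> TruthTrace:
    """Draw one behavior/trajectory trace.

    States follow a Markov chain with exponential dwell times and uniform
    jumps to any other state; within a state, per-frame steps are isotropic
    Gaussian with the state's activity scale, and the path reflects off the
    arena walls (an inset of ``arena_margin`` keeps boxes on screen).
    Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    states = list(cfg.states)
    # state segments covering [0, duration]
    seg_start: list[float] = []
    seg_state: list[str] = []
    t = 0.0
    cur = int(rng.integers(len(states)))
    while t < cfg.duration_s:
        seg_start.append(t)
        seg_state.append(states[cur])
        t += float(rng.exponential(cfg.dwell_means[states[cur]]))
        if len(states) > 1:
            step = int(rng.integers(1, len(states)))
            cur = (cur + step) % len(states)

    n = int(round(cfg.duration_s * cfg.fps)) + 1
    frame_t = np.arange(n) / cfg.fps
    seg_idx = np.searchsorted(np.asarray(seg_start), frame_t, side="right") - 1
    frame_state = [seg_state[i] for i in seg_idx]
    frame_posture = [cfg.states[s][0] for s in frame_state]
    sigmas = np.array([cfg.sigma_for(cfg.states[s][1]) for s in frame_state])

    steps = rng.normal(0.0, 1.0, (n, 2)) * sigmas[:, None]
    steps[0] = 0.0
    start = rng.uniform(0.25, 0.75, 2)
    lo, hi = cfg.arena_margin, 1.0 - cfg.arena_margin
    pos = _reflect(start + np.cumsum(steps, axis=0), lo, hi)

    sec_t = np.arange(int(cfg.duration_s) + 1, dtype=float)
    sec_idx = np.searchsorted(np.asarray(seg_start), sec_t, side="right") - 1
    sec_state = [seg_state[i] for i in sec_idx]
    sec_posture = [cfg.states[s][0] for s in sec_state]
    sec_activity = [cfg.states[s][1] for s in sec_state]
    return TruthTrace(
        fps=cfg.fps,
        frame_t=frame_t,
        pos=pos,
        frame_posture=frame_posture,
        frame_state=frame_state,
        sec_t=sec_t,
        sec_posture=sec_posture,
        sec_activity=sec_activity,
        sec_behavior=list(sec_state),
    )


def render_camera(
    truth: TruthTrace,
    cam: CameraModel,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> DetectionSeries:
    """Render the truth through one camera's noise model.

    Per frame: with ``miss_prob`` a gap; otherwise a detection with
    jittered center (clipped to the unit square, so clipping never moves a
    center by more than the jitter overshoot), posture flipped per the
    flip table with ``flip_prob``, and confidence drawn from the correct
    or flipped confidence model. Zero-noise settings reproduce the truth
    exactly (confidence 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = truth.n_frames
    miss = rng.random(n) < cam.miss_prob
    jitter = (
        rng.normal(0.0, cam.jitter_sigma, (n, 2))
        if cam.jitter_sigma > 0
        else np.zeros((n, 2))
    )
    flip_u = rng.random(n)
    conf_u = rng.normal(0.0, 1.0, n)
    size_u = rng.normal(0.0, 1.0, (n, 2))

    noiseless = (
        cam.miss_prob == 0 and cam.jitter_sigma == 0 and cam.flip_prob == 0
    )
    records: list[Detection] = []
    for i in range(n):
        t = float(truth.frame_t[i])
        if miss[i]:
            records.append(Detection.gap(cam.camera_id, i, t))
            continue
        true_posture = truth.frame_posture[i]
        flipped = (
            true_posture in cam.flip_table and flip_u[i] < cam.flip_prob
        )
        posture = cam.flip_table[true_posture] if flipped else true_posture
        if noiseless:
            conf = 1.0
        else:
            mean, spread = cam.conf_flipped if flipped else cam.conf_correct
            conf = float(np.clip(mean + spread * conf_u[i], 0.05, 1.0))
        cx = float(np.clip(truth.pos[i, 0] + jitter[i, 0], 0.0, 1.0))
        cy = float(np.clip(truth.pos[i, 1] + jitter[i, 1], 0.0, 1.0))
        w0, h0 = POSTURE_BOX[posture]
        if noiseless or cam.size_jitter == 0:
            w, h = w0, h0
        else:
            w = float(np.clip(w0 * (1.0 + cam.size_jitter * size_u[i, 0]), 0.02, 1.0))
            h = float(np.clip(h0 * (1.0 + cam.size_jitter * size_u[i, 1]), 0.02, 1.0))
        records.append(
            Detection(cam.camera_id, i, t, posture, conf, BoundingBox(cx, cy, w, h))
        )
    return DetectionSeries(camera_id=cam.camera_id, fps=truth.fps, records=records)


def truth_series(truth: TruthTrace, camera_id: str = "truth") -> DetectionSeries:
    """The truth as a noiseless detection stream (confidence 1)."""
    return render_camera(truth, CameraModel(camera_id=camera_id), seed=0)


def expected_labels(
    truth: TruthTrace,
    activity_cfg: ActivityConfig | None = None,
    bmap: BehaviorMap | None = None,
) -> list[ExpectedSecond]:
    """Known-answer per-second labels for pipeline recovery tests.

    Computed by applying the pipeline's own trailing-window conventions to
    the *noiseless* truth: 5 s mode of true postures, 5 s mean norm of
    true center displacements. Away from state transitions these coincide
    with the instantaneous truth; at transitions they define what an ideal
    noise-free pipeline would output.
    """
    activity_cfg = activity_cfg or ActivityConfig()
    bmap = bmap or BehaviorMap.default()
    series = truth_series(truth)
    acts = {round(a.t): a for a in activity_series(series, activity_cfg)}
    posts = smooth_posture(series, activity_cfg.window_s, activity_cfg.step_s)
    out: list[ExpectedSecond] = []
    for p in posts:
        a = acts.get(round(p.t))
        level = a.level if a else None
        behavior = (
            bmap.mapping[(p.posture, level)]
            if p.posture is not None and level is not None
            else None
        )
        out.append(ExpectedSecond(t=p.t, posture=p.posture, activity=level, behavior=behavior))
    return out


@dataclass
class Fixture:
    """A complete simulated test case: truth, camera streams, expectations."""

    config: SimConfig
    truth: TruthTrace
    streams: list[DetectionSeries]
    expected: list[ExpectedSecond]


def make_fixture(cfg: SimConfig, out_dir: str | Path | None = None) -> Fixture:
    """Simulate truth, render every configured camera, derive expected
    labels, and (optionally) write everything to plain-text files.

    Written files: one ``detections_<camera>.jsonl`` stream per camera,
    ``truth_frames.csv``, ``expected_seconds.csv`` and a ``config.yaml``
    echo. Byte-identical across reruns with the same config.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(1 + len(cfg.cameras))
    truth = simulate_truth(cfg, np.random.default_rng(children[0]))
    streams = [
        render_camera(truth, cam, np.random.default_rng(children[1 + i]))
        for i, cam in enumerate(cfg.cameras)
    ]
    bmap = BehaviorMap.strict_nine() if cfg.strict_nine else BehaviorMap.default()
    expected = expected_labels(truth, bmap=bmap)
    fixture = Fixture(config=cfg, truth=truth, streams=streams, expected=expected)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in streams:
            write_detections(s, out_dir / f"detections_{s.camera_id}.jsonl")
        _write_truth_csv(truth, out_dir / "truth_frames.csv")
        _write_expected_csv(expected, out_dir / "expected_seconds.csv")
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    return fixture


def _write_truth_csv(truth: TruthTrace, path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "timestamp", "x", "y", "posture", "state"])
        for i in range(truth.n_frames):
            w.writerow(
                [
                    i,
                    float(truth.frame_t[i]),
                    float(truth.pos[i, 0]),
                    float(truth.pos[i, 1]),
                    truth.frame_posture[i],
                    truth.frame_state[i],
                ]
            )


def _write_expected_csv(expected: Sequence[ExpectedSecond], path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "posture", "activity", "behavior"])
        for e in expected:
            w.writerow([e.t, e.posture or "", e.activity or "", e.behavior or ""])


def scripted_series(
    schedule: Sequence[tuple[float, str]],
    fps: float = 5.0,
    camera_id: str = "cam1",
    center: tuple[float, float] = (0.5, 0.5),
    confidence: float = 0.95,
) -> DetectionSeries:
    """A stationary animal switching postures on a script.

    ``schedule`` is a list of (duration_s, posture) segments. Useful for
    exact known-answer tests of smoothing and posture-change counting:
    the box center never moves, so all activity is 'inactive'.
    """
    records: list[Detection] = []
    f = 0
    for duration, posture in schedule:
        w, h = POSTURE_BOX[posture]
        n = int(round(duration * fps))
        for _ in range(n):
            records.append(
                Detection(
                    camera_id,
                    f,
                    f / fps,
                    posture,
                    confidence,
                    BoundingBox(center[0], center[1], w, h),
                )
            )
            f += 1
    return DetectionSeries(camera_id=camera_id, fps=fps, records=records)


def make_eval_set(
    truth: TruthTrace,
    cam: CameraModel,
    n_images: int,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[Prediction], LabelSet]:
    """Sample frames as an annotated evaluation set with noisy predictions.

    Ground truth comes straight from the trace (true center, posture-typical
    box); predictions pass through the camera noise model, so misses become
    false negatives and flips/large jitter become false positives.
    """
    rng = np.random.default_rng(seed)
    idx = np.unique(np.linspace(0, truth.n_frames - 1, n_images).astype(int))
    images: dict[str, list[GroundTruthBox]] = {}
    preds: list[Prediction] = []
    for f in idx:
        image_id = f"frame{int(f):06d}"
        posture = truth.frame_posture[int(f)]
        w0, h0 = POSTURE_BOX[posture]
        gt_box = BoundingBox(float(truth.pos[f, 0]), float(truth.pos[f, 1]), w0, h0)
        images[image_id] = [GroundTruthBox(image_id, posture, gt_box)]
        if rng.random() < cam.miss_prob:
            continue
        flipped = posture in cam.flip_table and rng.random() < cam.flip_prob
        out_posture = cam.flip_table[posture] if flipped else posture
        mean, spread = cam.conf_flipped if flipped else cam.conf_correct
        conf = float(np.clip(rng.normal(mean, spread), 0.05, 1.0))
        cx = float(np.clip(truth.pos[f, 0] + rng.normal(0, cam.jitter_sigma), 0, 1)) if cam.jitter_sigma else float(truth.pos[f, 0])
        cy = float(np.clip(truth.pos[f, 1] + rng.normal(0, cam.jitter_sigma), 0, 1)) if cam.jitter_sigma else float(truth.pos[f, 1])
        pw, ph = POSTURE_BOX[out_posture]
        if cam.size_jitter:
            pw = float(np.clip(pw * (1 + cam.size_jitter * rng.normal()), 0.02, 1))
            ph = float(np.clip(ph * (1 + cam.size_jitter * rng.normal()), 0.02, 1))
        preds.append(Prediction(image_id, out_posture, conf, BoundingBox(cx, cy, pw, ph)))
    class_names = tuple(sorted({b.posture for bs in images.values() for b in bs} | set(POSTURES)))
    return preds, LabelSet(class_names=class_names, images=images)
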