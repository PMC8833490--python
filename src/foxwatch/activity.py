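"""Activity quantification from bounding-box center trajectories.

The activity statistic is the windowed mean of per-frame-pair center
displacements in normalized image coordinates:

    m_{f,f+1} = sqrt((x_{f+1} - x_f)^2 + (y_{f+1} - y_f)^2)
    mean norm over a trailing 5 s window, stepped by 1 s.

The per-window normalization divides the sum of the F-1 pair displacements
by F, the number of frames in the window (25 frames -> divide by 25). That
is the published convention and the one the activity thresholds were
calibrated in; the conventional mean over pairs is available via
``ActivityConfig.mean_over_pairs``.

Three activity levels are assigned by fixed thresholds on the mean norm:
>= 0.0094 highly active; >= 0.0054 active; below, inactive. A value exactly
on a threshold takes the more active label. Distances are left in raw
normalized units (no aspect-ratio correction): the thresholds were derived
in that same uncorrected space, so correcting for the 16:9 frame would
invalidate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ACTIVITY_LEVELS, DetectionSeries


@dataclass
class ActivityConfig:
    """Windowing and threshold parameters for activity classification.

    Defaults are the published operating point: trailing 5 s windows
    stepped by 1 s on a 5 fps stream, thresholds 0.0054/0.0094 in
    normalized units per frame pair. ``min_valid_fraction`` is the fraction
    of the window's expected frame pairs that must be observed (no gap on
    either side) before a mean norm is reported; sparser windows yield a
    no-data sample.
    """

    window_s: float = 5.0
    step_s: float = 1.0
    tau_active: float = 0.0054
    tau_high: float = 0.0094
    min_valid_fraction: float = 0.5
    mean_over_pairs: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.tau_active < self.tau_high):
            raise ValueError("need 0 < tau_active < tau_high")
        if not (self.window_s >= self.step_s > 0):
            raise ValueError("need window_s >= step_s > 0")
        if not (0 < self.min_valid_fraction <= 1):
            raise ValueError("min_valid_fraction must be in (0, 1]")


@dataclass
class DisplacementSeries:
    """Per consecutive-frame-pair center displacements.

    One entry per frame-index pair (f, f+1) in the covered range;
    ``valid`` is False (and ``value`` NaN) where either frame lacks a
    detection. ``t_start``/``t_end`` are the timestamps of the earlier and
    later frame of each pair.
    """

    t_start: np.ndarray
    t_end: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    fps: float

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ActivitySample:
    """Mean norm and activity level for one trailing window.

    ``mean_norm`` and ``level`` are None for no-data windows (insufficient
    valid frame pairs).
    """

    t: float
    mean_norm: float | None
    level: str | None


def displacements(series: DetectionSeries) -> DisplacementSeries:
    """Center displacement for every consecutive frame-index pair.

    Pairs where either frame is a gap (or absent from the series) are
    flagged invalid and excluded from windowed means. A series with fewer
    than two frames yields an empty result. Frame index is authoritative
    for consecutiveness; slot timestamps are reconstructed on the
    ``frame_index / fps`` grid anchored at the first record, so explicit
    timestamps may carry a clock offset.
    """
    fps = series.fps
    if len(series.records) < 2:
        empty = np.array([])
        return DisplacementSeries(empty, empty, empty, np.array([], dtype=bool), fps)
    first = series.records[0]
    base_t = first.timestamp - first.frame_index / fps
    centers: dict[int, tuple[float, float]] = {}
    for r in series.records:
        if not r.is_gap:
            assert r.box is not None
            centers[r.frame_index] = (r.box.cx, r.box.cy)
    lo = series.records[0].frame_index
    hi = series.records[-1].frame_index
    frames = np.arange(lo, hi)
    t_start = base_t + frames / fps
    t_end = base_t + (frames + 1) / fps
    values = np.full(len(frames), np.nan)
    valid = np.zeros(len(frames), dtype=bool)
    for i, f in enumerate(frames):
        a = centers.get(int(f))
        b = centers.get(int(f) + 1)
        if a is not None and b is not None:
            values[i] = float(np.hypot(b[0] - a[0], b[1] - a[1]))
            valid[i] = True
    return DisplacementSeries(t_start, t_end, values, valid, fps)


def classify_activity(mean_norm: float, cfg: ActivityConfig | None = None) -> str:
    """Map a mean displacement norm to an activity level.

    >= tau_high -> highly_active; >= tau_active -> active; else inactive.
    Values exactly on a threshold take the more active label.
    """
    cfg = cfg or ActivityConfig()
    if mean_norm < 0:
        raise ValueError(f"mean norm must be non-negative, got {mean_norm}")
    if mean_norm >= cfg.tau_high:
        return ACTIVITY_LEVELS[2]
    if mean_norm >= cfg.tau_active:
        return ACTIVITY_LEVELS[1]
    return ACTIVITY_LEVELS[0]


def windowed_mean_norm(
    d: DisplacementSeries, cfg: ActivityConfig | None = None
) -> list[ActivitySample]:
    """Trailing-window mean norms with activity levels, one per step.

    Windows are causal: the sample at time t covers (t - window_s, t], a
    pair counting iff both its frames fall inside. Emission starts one full
    window after the first frame and steps by ``cfg.step_s``. The mean
    divides the sum of valid pair values by F = (#valid pairs + 1), the
    frame-count normalization the thresholds were calibrated with (or by
    the pair count when ``mean_over_pairs``). Windows with fewer valid
    pairs than ``min_valid_fraction`` of the expected count are emitted as
    no-data samples.
    """
    cfg = cfg or ActivityConfig()
    if len(d) == 0:
        return []
    expected_pairs = max(1, int(round(d.fps * cfg.window_s)) - 1)
    t0 = float(d.t_start[0])
    t_last = float(d.t_end[-1])
    out: list[ActivitySample] = []
    t = t0 + cfg.window_s
    eps = 1e-9
    while t <= t_last + eps:
        in_win = (d.t_start - (t - cfg.window_s) > eps) & (d.t_end <= t + eps)
        sel = in_win & d.valid
        n_valid = int(sel.sum())
        if n_valid == 0 or n_valid < cfg.min_valid_fraction * expected_pairs:
            out.append(ActivitySample(t=t, mean_norm=None, level=None))
        else:
            denom = n_valid if cfg.mean_over_pairs else n_valid + 1
            m = float(d.values[sel].sum()) / denom
            out.append(ActivitySample(t=t, mean_norm=m, level=classify_activity(m, cfg)))
        t += cfg.step_s
    return out


def activity_series(
    series: DetectionSeries, cfg: ActivityConfig | None = None
) -> list[ActivitySample]:
    """Convenience composition: displacements then windowed mean norms."""
    return windowed_mean_norm(displacements(series), cfg)
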