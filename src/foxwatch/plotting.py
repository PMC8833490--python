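"""Optional timeline/overview figures (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .behavior import OverviewBin, TimelinePoint

_BEHAVIOR_COLORS = {
    "lying motionless": "#2c4d8e",
    "active lying": "#6b8ed6",
    "sitting still": "#356e35",
    "active sitting": "#7dbf7d",
    "highly active sitting": "#b7e4b7",
    "standing still": "#8a5a19",
    "active standing": "#d99a3d",
    "highly active standing": "#f2c94c",
}


def plot_timeline(
    timeline: Sequence[TimelinePoint], path: str | Path, title: str = "Behavior timeline"
) -> None:
    """One horizontal band per behavior label, one colored tick per second."""
    labels = sorted({p.behavior for p in timeline if p.behavior is not None})
    fig, ax = plt.subplots(figsize=(10, 0.6 * max(3, len(labels))))
    for row, lab in enumerate(labels):
        ts = [p.t for p in timeline if p.behavior == lab]
        color = _BEHAVIOR_COLORS.get(lab, "#777777")
        ax.broken_barh([(t, 1.0) for t in ts], (row - 0.4, 0.8), color=color)
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels)
    ax.set_xlabel("time (s)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_overview(
    bins: Sequence[OverviewBin], path: str | Path, family: str = "behavior"
) -> None:
    """Stacked per-bin time budgets for one label family."""
    key = f"{family}_seconds"
    labels = sorted({lab for b in bins for lab in getattr(b, key)})
    fig, ax = plt.subplots(figsize=(10, 4))
    bottoms = [0.0] * len(bins)
    width = bins[0].end - bins[0].start if bins else 1800.0
    xs = [b.start for b in bins]
    for lab in labels:
        heights = [getattr(b, key).get(lab, 0) for b in bins]
        ax.bar(
            xs,
            heights,
            width=width * 0.9,
            bottom=bottoms,
            align="edge",
            label=lab,
            color=_BEHAVIOR_COLORS.get(lab),
        )
        bottoms = [b + h for b, h in zip(bottoms, heights)]
    ax.set_xlabel("bin start (s)")
    ax.set_ylabel("seconds")
    ax.set_title(f"{family} time budget per bin")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
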