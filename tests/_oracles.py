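"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the vectorized code paths of the package: the AP
oracle works in exact rational arithmetic over explicitly enumerated PR
points, and the IoU oracle accumulates per-cell covered area on a fixed
2000x2000 raster grid.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import numpy as np


def ap_11point_oracle(outcomes: Sequence[tuple[float, bool]], n_truths: int) -> float:
    """11-point interpolated AP by explicit PR-point enumeration.

    Exact rational arithmetic: recall/precision at every rank are
    Fractions, and the interpolated precision at each grid recall is the
    max over qualifying points, scanned one by one.
    """
    ranked = sorted(outcomes, key=lambda o: -o[0])
    points: list[tuple[Fraction, Fraction]] = []
    tp = 0
    for rank, (_conf, is_tp) in enumerate(ranked, start=1):
        if is_tp:
            tp += 1
        points.append((Fraction(tp, n_truths), Fraction(tp, rank)))
    total = Fraction(0)
    for k in range(11):
        r = Fraction(k, 10)
        best = Fraction(0)
        found = False
        for rec, prec in points:
            if rec >= r and prec > best:
                best, found = prec, True
            elif rec >= r:
                found = True
        total += best if found else Fraction(0)
    return float(total / 11)


def iou_raster_oracle(a, b, n: int = 2000) -> float:
    """IoU by rasterizing both boxes on an n x n grid of cells.

    Each cell contributes its exactly covered area (anti-aliased cells),
    accumulated per axis and combined by separability of axis-aligned
    rectangles; accurate to float rounding.
    """

    def axis_cover(lo: float, hi: float) -> np.ndarray:
        edges = np.arange(n + 1) / n
        left = np.maximum(edges[:-1], lo)
        right = np.minimum(edges[1:], hi)
        return np.maximum(right - left, 0.0) * n  # fraction of each cell covered

    ax = axis_cover(a.cx - a.w / 2, a.cx + a.w / 2)
    ay = axis_cover(a.cy - a.h / 2, a.cy + a.h / 2)
    bx = axis_cover(b.cx - b.w / 2, b.cx + b.w / 2)
    by = axis_cover(b.cy - b.h / 2, b.cy + b.h / 2)
    cell = 1.0 / (n * n)
    area_a = ax.sum() * ay.sum() * cell
    area_b = bx.sum() * by.sum() * cell
    ix = axis_cover(max(a.cx - a.w / 2, b.cx - b.w / 2), min(a.cx + a.w / 2, b.cx + b.w / 2))
    iy = axis_cover(max(a.cy - a.h / 2, b.cy - b.h / 2), min(a.cy + a.h / 2, b.cy + b.h / 2))
    inter = ix.sum() * iy.sum() * cell
    union = area_a + area_b - inter
    if union <= 0:
        return 0.0
    return inter / union


def random_outcome_instance(rng: np.random.Generator) -> tuple[list[tuple[float, bool]], int]:
    """Random ranked-outcome instance with <= 8 detections, <= 5 truths."""
    n_truths = int(rng.integers(1, 6))
    n_det = int(rng.integers(0, 9))
    confs = np.round(rng.random(n_det), 2)  # coarse grid to force ties
    max_tp = min(n_det, n_truths)
    n_tp = int(rng.integers(0, max_tp + 1))
    flags = np.zeros(n_det, dtype=bool)
    if n_tp:
        flags[rng.choice(n_det, size=n_tp, replace=False)] = True
    return [(float(c), bool(f)) for c, f in zip(confs, flags)], n_truths
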