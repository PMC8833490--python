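"""Detector evaluation: IoU, TP/FP/FN matching, precision/recall, 11-point AP.

Matching follows the classic Pascal-VOC contract. Within each image,
predictions are processed in decreasing confidence; a prediction is a true
positive iff a not-yet-matched ground-truth box of the *same class* overlaps
it with IoU >= threshold (0.5 by default, the >= boundary counting as TP),
taking the best-IoU candidate first. Everything else is a false positive,
and ground truths left unmatched — including every box of a labeled image
the detector missed entirely — are false negatives.

Average precision per class uses the 11-point interpolation: the mean over
recall grid r in {0, 0.1, ..., 1.0} of the interpolated precision
``p_interp(r) = max over PR points with recall >= r of precision``, 0 where
no such point exists. mAP is the plain mean of per-class APs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import BoundingBox, LabelSet

#: Slack used when comparing exact-fraction recalls against the binary
#: representation of the 0.1-spaced recall grid.
_GRID_EPS = 1e-9


@dataclass(frozen=True)
class Prediction:
    """A detector output attributed to an evaluation image."""

    image_id: str
    posture: str
    confidence: float
    box: BoundingBox


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class MatchResult:
    """Per-class counts, ranked TP/FP outcomes and matched-pair IoUs."""

    counts: dict[str, EvalCounts] = field(default_factory=dict)
    outcomes: dict[str, list[tuple[float, bool]]] = field(default_factory=dict)
    matched_ious: dict[str, list[float]] = field(default_factory=dict)

    def pooled(self) -> EvalCounts:
        out = EvalCounts()
        for c in self.counts.values():
            out.tp += c.tp
            out.fp += c.fp
            out.fn += c.fn
        return out


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two normalized boxes; 0 when disjoint
    or when either box has zero area."""
    ax0, ay0, ax1, ay1 = a.cx - a.w / 2, a.cy - a.h / 2, a.cx + a.w / 2, a.cy + a.h / 2
    bx0, by0, bx1, by1 = b.cx - b.w / 2, b.cy - b.h / 2, b.cx + b.w / 2, b.cy + b.h / 2
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    if union <= 0:
        return 0.0
    return inter / union


def match_detections(
    preds: Sequence[Prediction] | Mapping[str, Sequence[Prediction]],
    truths: LabelSet,
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy confidence-ordered one-to-one matching of predictions to
    ground truth.

    Every image referenced by a prediction must exist in ``truths``
    (possibly with zero boxes). Each ground truth is matched at most once.
    Confidence ties keep input order (stable sort), making results
    reproducible. Returns per-class counts satisfying
    ``TP + FN == #ground-truth boxes`` per class, plus the globally
    confidence-ranked (confidence, is_tp) outcome list per class that AP
    computation consumes, and the IoUs of matched (TP) pairs.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou_threshold must be in (0, 1)")
    if isinstance(preds, Mapping):
        flat: list[Prediction] = [p for ps in preds.values() for p in ps]
    else:
        flat = list(preds)
    for p in flat:
        if p.image_id not in truths.images:
            raise ValueError(f"prediction references unknown image {p.image_id!r}")

    result = MatchResult()
    classes = set(truths.class_names) | {p.posture for p in flat}
    for c in classes:
        result.counts[c] = EvalCounts()
        result.outcomes[c] = []
        result.matched_ious[c] = []

    by_image: dict[str, list[Prediction]] = {}
    for p in flat:
        by_image.setdefault(p.image_id, []).append(p)

    for image_id, image_preds in by_image.items():
        gts = truths.images[image_id]
        matched = [False] * len(gts)
        ranked = sorted(
            range(len(image_preds)), key=lambda i: -image_preds[i].confidence
        )
        for i in ranked:
            p = image_preds[i]
            best_j, best_iou = -1, 0.0
            for j, g in enumerate(gts):
                if matched[j] or g.posture != p.posture:
                    continue
                v = iou(p.box, g.box)
                if v > best_iou:
                    best_j, best_iou = j, v
            is_tp = best_j >= 0 and best_iou >= iou_threshold
            if is_tp:
                matched[best_j] = True
                result.counts[p.posture].tp += 1
                result.matched_ious[p.posture].append(best_iou)
            else:
                result.counts[p.posture].fp += 1
            result.outcomes[p.posture].append((p.confidence, is_tp))

    n_truth = truths.boxes_per_class()
    for c in classes:
        result.counts[c].fn = n_truth.get(c, 0) - result.counts[c].tp
        # global confidence ranking across images; stable, so confidence
        # ties keep input order
        result.outcomes[c] = sorted(result.outcomes[c], key=lambda o: -o[0])
    return result


def precision_recall(counts: EvalCounts) -> tuple[float | None, float | None]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN); a 0/0 ratio is
    reported as None (undefined), never as 0."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    return precision, recall


def interpolated_ap(
    ranked_outcomes: Sequence[tuple[float, bool]], n_truths: int
) -> float:
    """11-point interpolated average precision for one class.

    ``ranked_outcomes`` is the (confidence, is_tp) list in decreasing
    confidence (re-sorted stably here, so input order only matters within
    exact ties). ``n_truths`` is the number of ground-truth boxes of the
    class and must be >= 1.
    """
    if n_truths < 1:
        raise ValueError("AP undefined without ground-truth boxes")
    outcomes = sorted(ranked_outcomes, key=lambda o: -o[0])
    if not outcomes:
        return 0.0
    flags = np.array([tp for _, tp in outcomes], dtype=float)
    tp_cum = np.cumsum(flags)
    ranks = np.arange(1, len(outcomes) + 1)
    recall = tp_cum / n_truths
    precision = tp_cum / ranks
    total = 0.0
    for r in np.linspace(0.0, 1.0, 11):
        mask = recall >= r - _GRID_EPS
        total += float(precision[mask].max()) if mask.any() else 0.0
    return total / 11.0


@dataclass
class ClassMetrics:
    ap: float | None
    precision: float | None
    recall: float | None
    mean_iou: float | None
    n_truths: int
    counts: EvalCounts


@dataclass
class APResult:
    """Evaluation report: per-class metrics plus pooled overall numbers.

    ``map_`` averages per-class APs over the classes that have at least one
    ground-truth box (AP is undefined otherwise). Overall precision/recall
    pool TP/FP/FN counts over all classes; ``mean_iou`` averages the IoU of
    every TP-matched pair.
    """

    per_class: dict[str, ClassMetrics]
    map_: float | None
    precision: float | None
    recall: float | None
    mean_iou: float | None
    n_classes: int

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: {
                    "ap": m.ap,
                    "precision": m.precision,
                    "recall": m.recall,
                    "mean_iou": m.mean_iou,
                    "n_truths": m.n_truths,
                    "tp": m.counts.tp,
                    "fp": m.counts.fp,
                    "fn": m.counts.fn,
                }
                for c, m in sorted(self.per_class.items())
            },
            "overall": {
                "mAP": self.map_,
                "precision": self.precision,
                "recall": self.recall,
                "mean_iou": self.mean_iou,
                "n_classes": self.n_classes,
            },
        }


def evaluate(
    preds: Sequence[Prediction] | Mapping[str, Sequence[Prediction]],
    truths: LabelSet,
    iou_threshold: float = 0.5,
) -> APResult:
    """Full detector evaluation: match, then per-class AP and pooled
    precision/recall/average-IoU."""
    match = match_detections(preds, truths, iou_threshold)
    n_truth = truths.boxes_per_class()
    per_class: dict[str, ClassMetrics] = {}
    aps: list[float] = []
    for c in sorted(match.counts):
        counts = match.counts[c]
        p, r = precision_recall(counts)
        ious = match.matched_ious[c]
        n_t = n_truth.get(c, 0)
        ap = interpolated_ap(match.outcomes[c], n_t) if n_t > 0 else None
        if ap is not None:
            aps.append(ap)
        per_class[c] = ClassMetrics(
            ap=ap,
            precision=p,
            recall=r,
            mean_iou=float(np.mean(ious)) if ious else None,
            n_truths=n_t,
            counts=counts,
        )
    pooled = match.pooled()
    p_all, r_all = precision_recall(pooled)
    all_ious = [v for vs in match.matched_ious.values() for v in vs]
    return APResult(
        per_class=per_class,
        map_=float(np.mean(aps)) if aps else None,
        precision=p_all,
        recall=r_all,
        mean_iou=float(np.mean(all_ious)) if all_ious else None,
        n_classes=len(aps),
    )
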