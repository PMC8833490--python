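"""Core data model for posture-detection streams.

The monitored animal is a single fox observed by fixed cameras. An upstream
object detector emits, for every sampled video frame, at most one record:
a posture class (``lying``, ``sitting`` or ``standing``), a confidence in
[0, 1] and a bounding box in YOLO center format, normalized to the unit
square (fractions of image width/height). Everything downstream — activity
quantification, posture smoothing, behavior classification — operates on
these records; the detector itself is a pluggable source and no image data
ever enters the pipeline.

Frames where the detector found nothing are kept as explicit *gap* records
(posture, confidence and box all ``None``) so that windowed statistics can
account for missing coverage instead of silently bridging it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

#: The three posture classes, in the fixed tie-breaking order used
#: throughout the package (lying < sitting < standing).
POSTURES: tuple[str, ...] = ("lying", "sitting", "standing")
POSTURE_RANK = {p: i for i, p in enumerate(POSTURES)}

#: Activity levels ordered from least to most active.
ACTIVITY_LEVELS: tuple[str, ...] = ("inactive", "active", "highly_active")
ACTIVITY_RANK = {a: i for i, a in enumerate(ACTIVITY_LEVELS)}


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in normalized center format.

    Parameters
    ----------
    cx, cy:
        Center position as fractions of image width/height, in [0, 1].
    w, h:
        Box width/height as fractions of image width/height, in [0, 1].
        Degenerate zero-area boxes are tolerated (they score IoU 0 and are
        rejected by the annotation readers) so that malformed upstream
        predictions do not abort an evaluation run.
    """

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValidationError(f"box center out of unit square: ({self.cx}, {self.cy})")
        if not (0.0 <= self.w <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValidationError(f"box size out of range: ({self.w}, {self.h})")

    @property
    def area(self) -> float:
        return self.w * self.h

    def corners(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in normalized units, clamped to [0, 1]."""
        return (
            max(0.0, self.cx - self.w / 2),
            max(0.0, self.cy - self.h / 2),
            min(1.0, self.cx + self.w / 2),
            min(1.0, self.cy + self.h / 2),
        )

    def to_pixel_corners(self, width: int, height: int) -> tuple[int, int, int, int]:
        """Convert to integer pixel corners (xmin, ymin, xmax, ymax)."""
        x0, y0, x1, y1 = self.corners()
        return (
            int(round(x0 * width)),
            int(round(y0 * height)),
            int(round(x1 * width)),
            int(round(y1 * height)),
        )

    @classmethod
    def from_pixel_corners(
        cls, xmin: float, ymin: float, xmax: float, ymax: float, width: int, height: int
    ) -> "BoundingBox":
        """Build a normalized center-format box from pixel corners.

        Raises :class:`ValidationError` unless ``xmin < xmax`` and
        ``ymin < ymax``.
        """
        if not (xmin < xmax and ymin < ymax):
            raise ValidationError(
                f"degenerate pixel corners ({xmin}, {ymin}, {xmax}, {ymax})"
            )
        if width <= 0 or height <= 0:
            raise ValidationError("image size must be positive")
        return cls(
            cx=(xmin + xmax) / (2.0 * width),
            cy=(ymin + ymax) / (2.0 * height),
            w=(xmax - xmin) / width,
            h=(ymax - ymin) / height,
        )


@dataclass(frozen=True)
class Detection:
    """One frame's detector output for one camera.

    A *gap* (no detection on this frame) is encoded with ``posture``,
    ``confidence`` and ``box`` all ``None``; partial records are invalid.
    """

    camera_id: str
    frame_index: int
    timestamp: float
    posture: str | None
    confidence: float | None
    box: BoundingBox | None

    def __post_init__(self) -> None:
        fields_none = (self.posture is None, self.confidence is None, self.box is None)
        if any(fields_none) and not all(fields_none):
            raise ValidationError(
                f"frame {self.frame_index}: gap records must have posture, "
                "confidence and box all null"
            )
        if self.posture is not None:
            if self.posture not in POSTURES:
                raise ValidationError(
                    f"frame {self.frame_index}: unknown posture {self.posture!r}"
                )
            assert self.confidence is not None
            if not (0.0 <= self.confidence <= 1.0):
                raise ValidationError(
                    f"frame {self.frame_index}: confidence {self.confidence} "
                    "outside [0, 1]"
                )

    @property
    def is_gap(self) -> bool:
        return self.posture is None

    @classmethod
    def gap(cls, camera_id: str, frame_index: int, timestamp: float) -> "Detection":
        return cls(camera_id, frame_index, timestamp, None, None, None)


@dataclass
class DetectionSeries:
    """Time-ordered detections (one per frame, gaps explicit) for one camera."""

    camera_id: str
    fps: float = 5.0
    records: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        self.records = sorted(self.records, key=lambda r: r.timestamp)
        seen: set[int] = set()
        prev_t = -math.inf
        for r in self.records:
            if r.timestamp <= prev_t:
                raise ValidationError(
                    f"timestamps not strictly increasing at frame {r.frame_index}"
                )
            prev_t = r.timestamp
            if r.frame_index in seen:
                raise ValidationError(f"duplicate frame_index {r.frame_index}")
            seen.add(r.frame_index)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Detection]:
        return iter(self.records)

    def detections(self) -> list[Detection]:
        """Non-gap records only."""
        return [r for r in self.records if not r.is_gap]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "camera_id": r.camera_id,
                    "frame_index": r.frame_index,
                    "timestamp": r.timestamp,
                    "posture": r.posture,
                    "confidence": r.confidence,
                    "cx": r.box.cx if r.box else None,
                    "cy": r.box.cy if r.box else None,
                    "w": r.box.w if r.box else None,
                    "h": r.box.h if r.box else None,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "camera_id",
                "frame_index",
                "timestamp",
                "posture",
                "confidence",
                "cx",
                "cy",
                "w",
                "h",
            ],
        )


@dataclass(frozen=True)
class GroundTruthBox:
    """A manually annotated box: one posture label per box."""

    image_id: str
    posture: str
    box: BoundingBox

    def __post_init__(self) -> None:
        if self.posture not in POSTURES:
            # annotation sets may legitimately use other class vocabularies;
            # only the three-posture pipeline restricts labels, so accept any
            # non-empty label here.
            if not self.posture:
                raise ValidationError("empty class label")


@dataclass
class LabelSet:
    """Annotation set for detector evaluation: image id -> ground-truth boxes."""

    class_names: tuple[str, ...]
    images: dict[str, list[GroundTruthBox]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != len(self.class_names):
            raise ValidationError("duplicate class names")

    @property
    def n_boxes(self) -> int:
        return sum(len(v) for v in self.images.values())

    def boxes_per_class(self) -> dict[str, int]:
        out = {c: 0 for c in self.class_names}
        for boxes in self.images.values():
            for b in boxes:
                out[b.posture] = out.get(b.posture, 0) + 1
        return out
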