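"""Readers and writers for detection streams and annotation sets.

Two stream dialects are supported, carrying identical logical content:

* JSON Lines — one object per frame with keys ``camera_id``,
  ``frame_index``, ``timestamp``, ``posture``, ``confidence``, ``cx``,
  ``cy``, ``w``, ``h``; a null posture/box encodes a no-detection gap.
* CSV — the same columns; empty cells encode the gap fields.

Annotation dialects are the two emitted by LabelImg:

* YOLO/Darknet txt: one file per image, lines ``class cx cy w h`` with
  normalized center-format coordinates; class indices resolve through a
  class-name file (one label per line, index = 0-based line number).
* Pascal-VOC XML: pixel corners ``xmin/ymin/xmax/ymax`` plus the image
  size, converted on read to normalized center format.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.etree import ElementTree

from .core import (
    BoundingBox,
    Detection,
    DetectionSeries,
    GroundTruthBox,
    LabelSet,
    ValidationError,
)

STREAM_FIELDS = (
    "camera_id",
    "frame_index",
    "timestamp",
    "posture",
    "confidence",
    "cx",
    "cy",
    "w",
    "h",
)


class ParseError(ValueError):
    """Malformed input; the message names the offending file/line."""


def _is_null(value: object) -> bool:
    return value is None or value == "" or (isinstance(value, float) and math.isnan(value))


def _record_from_mapping(row: Mapping[str, object], line_no: int, fps: float) -> Detection:
    for key in ("camera_id", "frame_index"):
        if key not in row or _is_null(row[key]):
            raise ParseError(f"line {line_no}: missing mandatory field {key!r}")
    camera_id = str(row["camera_id"])
    try:
        frame_index = int(row["frame_index"])  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise ParseError(f"line {line_no}: bad frame_index {row['frame_index']!r}") from exc
    if _is_null(row.get("timestamp")):
        timestamp = frame_index / fps
    else:
        timestamp = float(row["timestamp"])  # type: ignore[arg-type]

    if _is_null(row.get("posture")):
        return Detection.gap(camera_id, frame_index, timestamp)

    for key in ("confidence", "cx", "cy", "w", "h"):
        if _is_null(row.get(key)):
            raise ParseError(f"line {line_no}: missing mandatory field {key!r}")
    try:
        box = BoundingBox(
            float(row["cx"]), float(row["cy"]), float(row["w"]), float(row["h"])  # type: ignore[arg-type]
        )
        return Detection(
            camera_id,
            frame_index,
            timestamp,
            str(row["posture"]),
            float(row["confidence"]),  # type: ignore[arg-type]
            box,
        )
    except ValidationError as exc:
        raise ParseError(f"line {line_no}: {exc}") from exc


def read_detections(
    path: str | Path, fmt: str | None = None, fps: float = 5.0
) -> dict[str, DetectionSeries]:
    """Read a detection stream, returning one series per camera.

    Records are grouped by ``camera_id`` and sorted by timestamp; a
    missing timestamp is reconstructed as ``frame_index / fps``.
    Malformed rows raise :class:`ParseError` naming the line; duplicate or
    non-monotone timestamps within a camera raise
    :class:`~foxwatch.core.ValidationError`.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    rows: list[tuple[int, Mapping[str, object]]] = []
    if fmt == "jsonl":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"line {i}: invalid JSON ({exc.msg})") from exc
                rows.append((i, obj))
    elif fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for i, obj in enumerate(reader, start=2):  # line 1 is the header
                rows.append((i, obj))
    else:
        raise ValueError(f"unknown dialect {fmt!r}")

    by_camera: dict[str, list[Detection]] = {}
    for line_no, row in rows:
        rec = _record_from_mapping(row, line_no, fps)
        by_camera.setdefault(rec.camera_id, []).append(rec)
    return {
        cam: DetectionSeries(camera_id=cam, fps=fps, records=recs)
        for cam, recs in sorted(by_camera.items())
    }


def _record_to_row(r: Detection) -> dict[str, object]:
    return {
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


def write_detections(
    series: DetectionSeries | Iterable[DetectionSeries],
    path: str | Path,
    fmt: str | None = None,
) -> None:
    """Write one or more camera series to a stream file.

    Gaps become records with null posture/confidence/box, so a read/write
    round trip preserves logical content exactly.
    """
    if isinstance(series, DetectionSeries):
        series = [series]
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    rows = [_record_to_row(r) for s in series for r in s]
    if fmt == "jsonl":
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=STREAM_FIELDS)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
    else:
        raise ValueError(f"unknown dialect {fmt!r}")


def read_class_names(path: str | Path) -> tuple[str, ...]:
    """One label per line; index = 0-based line number."""
    with open(path) as fh:
        return tuple(line.strip() for line in fh if line.strip())


def read_yolo_labels(label_dir: str | Path, class_names: Sequence[str]) -> LabelSet:
    """Read a directory of Darknet txt annotations (one file per image).

    Each non-empty line is ``class cx cy w h`` with normalized
    center-format coordinates. An empty file yields an image with zero
    boxes (a labeled-but-empty frame, counted toward nothing). Coordinate
    or class-index violations raise :class:`ParseError` naming file and
    line.
    """
    label_dir = Path(label_dir)
    images: dict[str, list[GroundTruthBox]] = {}
    for txt in sorted(label_dir.glob("*.txt")):
        image_id = txt.stem
        boxes: list[GroundTruthBox] = []
        with open(txt) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 5:
                    raise ParseError(f"{txt.name} line {i}: expected 5 fields, got {len(parts)}")
                try:
                    cls_idx = int(parts[0])
                    cx, cy, w, h = (float(p) for p in parts[1:])
                except ValueError as exc:
                    raise ParseError(f"{txt.name} line {i}: non-numeric field") from exc
                if not (0 <= cls_idx < len(class_names)):
                    raise ParseError(f"{txt.name} line {i}: unknown class index {cls_idx}")
                if not (0 < w <= 1 and 0 < h <= 1):
                    raise ParseError(f"{txt.name} line {i}: box size ({w}, {h}) out of (0, 1]")
                try:
                    box = BoundingBox(cx, cy, w, h)
                except ValidationError as exc:
                    raise ParseError(f"{txt.name} line {i}: {exc}") from exc
                boxes.append(GroundTruthBox(image_id, class_names[cls_idx], box))
        images[image_id] = boxes
    return LabelSet(class_names=tuple(class_names), images=images)


def write_yolo_labels(labels: LabelSet, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = {name: i for i, name in enumerate(labels.class_names)}
    for image_id, boxes in labels.images.items():
        lines = [
            f"{index[b.posture]} {b.box.cx:.6f} {b.box.cy:.6f} {b.box.w:.6f} {b.box.h:.6f}"
            for b in boxes
        ]
        (out_dir / f"{image_id}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))


def read_voc_labels(xml_files: Iterable[str | Path]) -> LabelSet:
    """Read Pascal-VOC XML annotations, converting pixel corners to
    normalized center format using the ``<size>`` element of each file."""
    images: dict[str, list[GroundTruthBox]] = {}
    names: list[str] = []
    for xml_path in sorted(Path(p) for p in xml_files):
        tree = ElementTree.parse(xml_path)
        root = tree.getroot()
        image_id = xml_path.stem
        size = root.find("size")
        if size is None or size.find("width") is None or size.find("height") is None:
            raise ParseError(f"{xml_path.name}: missing <size> element")
        width = int(size.findtext("width"))  # type: ignore[arg-type]
        height = int(size.findtext("height"))  # type: ignore[arg-type]
        boxes: list[GroundTruthBox] = []
        for obj in root.iter("object"):
            name = obj.findtext("name")
            bnd = obj.find("bndbox")
            if name is None or bnd is None:
                raise ParseError(f"{xml_path.name}: object missing name or bndbox")
            try:
                xmin = float(bnd.findtext("xmin"))  # type: ignore[arg-type]
                ymin = float(bnd.findtext("ymin"))  # type: ignore[arg-type]
                xmax = float(bnd.findtext("xmax"))  # type: ignore[arg-type]
                ymax = float(bnd.findtext("ymax"))  # type: ignore[arg-type]
            except TypeError as exc:
                raise ParseError(f"{xml_path.name}: incomplete bndbox") from exc
            try:
                box = BoundingBox.from_pixel_corners(xmin, ymin, xmax, ymax, width, height)
            except ValidationError as exc:
                raise ParseError(f"{xml_path.name}: {exc}") from exc
            boxes.append(GroundTruthBox(image_id, name, box))
            if name not in names:
                names.append(name)
        images[image_id] = boxes
    return LabelSet(class_names=tuple(names), images=images)


def best_detection_per_frame(
    raw: Iterable[Detection],
    camera_id: str | None = None,
    fps: float = 5.0,
    frame_range: tuple[int, int] | None = None,
) -> DetectionSeries:
    """Reduce a per-frame multiset of detections to at most one per frame.

    The detector may emit several boxes on one frame even with a single
    animal in view; the record with maximal confidence is kept, ties broken
    by larger box area, then by the fixed posture order lying < sitting <
    standing. Frames inside ``frame_range`` (default: the observed
    min..max) with no detection become explicit gap records. The result is
    permutation-invariant in its input.
    """
    from .core import POSTURE_RANK

    by_frame: dict[int, list[Detection]] = {}
    for det in raw:
        if camera_id is None:
            camera_id = det.camera_id
        if det.is_gap:
            by_frame.setdefault(det.frame_index, [])
        else:
            by_frame.setdefault(det.frame_index, []).append(det)
    if camera_id is None:
        camera_id = "cam"
    if frame_range is None:
        if not by_frame:
            return DetectionSeries(camera_id=camera_id, fps=fps, records=[])
        frame_range = (min(by_frame), max(by_frame))
    lo, hi = frame_range
    records: list[Detection] = []
    for f in range(lo, hi + 1):
        cands = by_frame.get(f, [])
        if not cands:
            records.append(Detection.gap(camera_id, f, f / fps))
            continue
        best = max(
            cands,
            key=lambda d: (d.confidence, d.box.area, -POSTURE_RANK[d.posture]),  # type: ignore[union-attr,index]
        )
        records.append(
            Detection(camera_id, f, best.timestamp, best.posture, best.confidence, best.box)
        )
    return DetectionSeries(camera_id=camera_id, fps=fps, records=records)


def sample_frame_indices(native_fps: float, target_fps: float, n_frames: int) -> list[int]:
    """Frame indices for decimating a native-rate stream to ``target_fps``.

    ``i_k = round(k * native_fps / target_fps)``, deduplicated, each below
    ``n_frames``. E.g. 15 fps decimated to 5 fps keeps every third frame.
    """
    if target_fps <= 0 or native_fps <= 0:
        raise ValueError("frame rates must be positive")
    if target_fps > native_fps:
        raise ValueError(f"target_fps {target_fps} exceeds native_fps {native_fps}")
    ratio = native_fps / target_fps
    out: list[int] = []
    k = 0
    while True:
        idx = int(math.floor(k * ratio + 0.5))
        if idx >= n_frames:
            break
        if not out or idx != out[-1]:
            out.append(idx)
        k += 1
    return out
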