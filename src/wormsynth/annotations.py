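"""YOLO-format labels and detections, and box representation conversions.

Three box representations are used throughout the package:

* **normalized center format** (``BBox``): ``(cx, cy, w, h)`` in ``[0, 1]``
  relative to image width/height — the on-disk YOLO txt convention;
* **inclusive pixel box**: integer ``(x0, y0, x1, y1)`` min/max foreground
  indices, with pixel width ``x1 - x0 + 1`` (a 1-px object has width 1);
* **continuous pixel corners**: float ``(x0, y0, x1, y1)`` edges used for
  IoU and geometric transforms.

Label files carry one ``class cx cy w h`` row per object; detection files
append a trailing confidence column.  Coordinates are 0-based, x right /
y down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BBox",
    "Detection",
    "LabelFile",
    "DetectionFile",
    "YoloParseError",
    "mask_to_bbox",
    "mask_to_pixel_box",
    "read_yolo_labels",
    "write_yolo_labels",
    "read_detections",
    "write_detections",
]


class YoloParseError(ValueError):
    """Malformed YOLO txt row; message names the offending line number."""


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box in normalized center format, class 0 = worm."""

    cx: float
    cy: float
    w: float
    h: float
    class_id: int = 0

    def __post_init__(self) -> None:
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"BBox.{name} must be finite, got {v!r}")
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"BBox center outside unit square: ({self.cx}, {self.cy})")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"BBox size outside (0, 1]: ({self.w}, {self.h})")

    # -- conversions -----------------------------------------------------

    def to_corners(self, image_shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """Continuous pixel corners ``(x0, y0, x1, y1)`` for an ``(H, W)`` image."""
        h, w = image_shape[:2]
        return (
            (self.cx - self.w / 2.0) * w,
            (self.cy - self.h / 2.0) * h,
            (self.cx + self.w / 2.0) * w,
            (self.cy + self.h / 2.0) * h,
        )

    def to_pixel_box(self, image_shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """Inclusive integer pixel box ``(x0, y0, x1, y1)``."""
        x0, y0, x1, y1 = self.to_corners(image_shape)
        return (int(round(x0)), int(round(y0)), int(round(x1)) - 1, int(round(y1)) - 1)

    @classmethod
    def from_corners(
        cls,
        corners: tuple[float, float, float, float],
        image_shape: tuple[int, int],
        class_id: int = 0,
    ) -> "BBox":
        h, w = image_shape[:2]
        x0, y0, x1, y1 = corners
        return cls(
            cx=(x0 + x1) / 2.0 / w,
            cy=(y0 + y1) / 2.0 / h,
            w=(x1 - x0) / w,
            h=(y1 - y0) / h,
            class_id=class_id,
        )

    @classmethod
    def from_pixel_box(
        cls,
        pixel_box: tuple[int, int, int, int],
        image_shape: tuple[int, int],
        class_id: int = 0,
    ) -> "BBox":
        """From an inclusive min/max index box; pixel width is ``max - min + 1``."""
        x0, y0, x1, y1 = pixel_box
        if x1 < x0 or y1 < y0:
            raise ValueError(f"degenerate pixel box {pixel_box}")
        return cls.from_corners((x0, y0, x1 + 1, y1 + 1), image_shape, class_id)

    def quantized(self, decimals: int = 6) -> "BBox":
        """The box as it survives a serialize/parse round trip."""
        return BBox(
            round(self.cx, decimals),
            round(self.cy, decimals),
            round(self.w, decimals),
            round(self.h, decimals),
            self.class_id,
        )


@dataclass(frozen=True)
class Detection:
    bbox: BBox
    confidence: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.confidence) and 0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be finite in [0, 1], got {self.confidence!r}")


@dataclass
class LabelFile:
    image_id: str
    boxes: list[BBox] = field(default_factory=list)


@dataclass
class DetectionFile:
    image_id: str
    detections: list[Detection] = field(default_factory=list)
    #: set when the file lacked a confidence column (all confidences assumed 1.0)
    missing_confidence: bool = False


# ---------------------------------------------------------------------------
# mask -> box


def mask_to_pixel_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight inclusive pixel box of a non-empty binary mask."""
    mask = np.asarray(mask)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("mask is empty")
    return (int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max()))


def mask_to_bbox(mask: np.ndarray, image_shape: tuple[int, int] | None = None) -> BBox:
    """Tight normalized box of a non-empty binary mask."""
    mask = np.asarray(mask)
    if image_shape is None:
        image_shape = mask.shape
    return BBox.from_pixel_box(mask_to_pixel_box(mask), image_shape)


# ---------------------------------------------------------------------------
# YOLO txt I/O

_DECIMALS = 6


def _format_row(b: BBox, confidence: float | None = None) -> str:
    row = f"{b.class_id:d} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
    if confidence is not None:
        row += f" {confidence:.6f}"
    return row


def _parse_fields(fields: list[str], lineno: int, path: Path) -> tuple[int, list[float]]:
    try:
        class_id = int(fields[0])
        values = [float(f) for f in fields[1:]]
    except ValueError as exc:
        raise YoloParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
    return class_id, values


def write_yolo_labels(boxes: list[BBox], path: str | Path) -> None:
    """One ``class cx cy w h`` row per box, 6 decimal places; empty list → empty file."""
    Path(path).write_text("".join(_format_row(b) + "\n" for b in boxes))


def read_yolo_labels(
    path: str | Path, image_shape: tuple[int, int] | None = None
) -> LabelFile:
    """Parse a 5-column YOLO label file.  ``image_shape`` is unused for parsing
    (boxes are normalized) and retained for interface symmetry with detections."""
    path = Path(path)
    boxes: list[BBox] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 5:
            raise YoloParseError(
                f"{path}:{lineno}: expected 5 fields (class cx cy w h), got {len(fields)}"
            )
        class_id, vals = _parse_fields(fields, lineno, path)
        try:
            boxes.append(BBox(*vals, class_id=class_id))
        except ValueError as exc:
            raise YoloParseError(f"{path}:{lineno}: {exc}") from None
    return LabelFile(image_id=path.stem, boxes=boxes)


def write_detections(detections: list[Detection], path: str | Path) -> None:
    """Six-column detection rows: ``class cx cy w h conf``."""
    Path(path).write_text(
        "".join(_format_row(d.bbox, d.confidence) + "\n" for d in detections)
    )


def read_detections(
    path: str | Path, image_shape: tuple[int, int] | None = None
) -> DetectionFile:
    """Parse a detection file.

    Accepts the 6-column inference dialect; 5-column rows are tolerated with
    confidence assumed 1.0 and ``missing_confidence`` flagged on the result.
    """
    path = Path(path)
    dets: list[Detection] = []
    missing = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) not in (5, 6):
            raise YoloParseError(
                f"{path}:{lineno}: expected 5 or 6 fields, got {len(fields)}"
            )
        class_id, vals = _parse_fields(fields, lineno, path)
        if len(vals) == 4:
            conf = 1.0
            missing = True
        else:
            conf = vals[4]
        try:
            dets.append(Detection(BBox(*vals[:4], class_id=class_id), conf))
        except ValueError as exc:
            raise YoloParseError(f"{path}:{lineno}: {exc}") from None
    return DetectionFile(image_id=path.stem, detections=dets, missing_confidence=missing)
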