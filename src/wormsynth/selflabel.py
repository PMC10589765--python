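"""Supervised self-labeling: count-capped inference, count filtering, manual
review bookkeeping, and labeling time-savings estimation.

The procedure curates labels for images whose *worm count* is known but
whose box positions are not (a common situation for video frames, where the
count is fixed per video):

1. group the unlabeled pool by expected worm count;
2. run the detector with its detection cap set to that count, so it can
   never overcount;
3. keep only images where the detected count equals the expected count
   (undercounts and zero-detection images are logically deleted, with the
   reason recorded);
4. a human reviews the kept images and accepts or rejects each;
5. accepted detections are stripped of confidences and become training
   labels for the next iteration.

Because the cap makes overcounting impossible, detected == expected is the
strongest automatic correctness signal available without ground-truth boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .annotations import BBox, Detection
from .detector import DetectorParams, detect

__all__ = [
    "ImagePool",
    "FilterReport",
    "IterationLog",
    "group_by_count",
    "capped_inference",
    "filter_by_count",
    "apply_review",
    "estimate_time_saved",
]


@dataclass
class ImagePool:
    """Unlabeled images with known expected worm counts."""

    expected_counts: dict[str, int]

    def __post_init__(self) -> None:
        for image_id, n in self.expected_counts.items():
            if n < 0:
                raise ValueError(f"negative expected count for {image_id!r}: {n}")

    def __len__(self) -> int:
        return len(self.expected_counts)


@dataclass
class FilterReport:
    """Outcome of the count filter: kept/deleted partition with reasons."""

    kept: dict[str, list[Detection]]
    deleted: dict[str, str]  # image id -> "zero-detections" | "undercount"

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_deleted(self) -> int:
        return len(self.deleted)

    @property
    def kept_worms(self) -> int:
        return sum(len(d) for d in self.kept.values())


@dataclass
class IterationLog:
    """Cumulative bookkeeping across self-labeling iterations."""

    records: list[dict] = field(default_factory=list)

    def log(self, pool_size: int, kept: int, accepted: int, accepted_worms: int) -> None:
        prev_imgs = self.records[-1]["cumulative_accepted_images"] if self.records else 0
        prev_worms = self.records[-1]["cumulative_accepted_worms"] if self.records else 0
        self.records.append(
            {
                "iteration": len(self.records) + 1,
                "pool_size": pool_size,
                "kept": kept,
                "accepted": accepted,
                "accepted_worms": accepted_worms,
                "cumulative_accepted_images": prev_imgs + accepted,
                "cumulative_accepted_worms": prev_worms + accepted_worms,
            }
        )


def group_by_count(pool: ImagePool) -> dict[int, list[str]]:
    """Partition the pool's image ids by expected worm count.

    Group keys are exactly the distinct counts present; ids keep pool order.
    """
    groups: dict[int, list[str]] = {}
    for image_id, n in pool.expected_counts.items():
        groups.setdefault(n, []).append(image_id)
    return groups


def capped_inference(
    detector: Callable[[np.ndarray], list[Detection]] | DetectorParams,
    images: Mapping[str, np.ndarray],
    group: Sequence[str],
    expected_count: int,
) -> dict[str, list[Detection]]:
    """Run the detector on a count group with max detections = expected count.

    ``detector`` may be ``DetectorParams`` (the cap is applied inside the
    detector) or any callable returning confidence-sorted detections (the cap
    is applied to its output, highest confidence first, ties by emit order).
    """
    results: dict[str, list[Detection]] = {}
    for image_id in group:
        image = images[image_id]
        if isinstance(detector, DetectorParams):
            dets = detect(image, detector.with_cap(expected_count))
        else:
            dets = detector(image)
            order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
            dets = [dets[i] for i in order[:expected_count]]
        assert len(dets) <= expected_count
        results[image_id] = dets
    return results


def filter_by_count(
    detections: Mapping[str, Sequence[Detection]], pool: ImagePool
) -> FilterReport:
    """Keep images whose detected count equals the expected count.

    Images with zero detections (and nonzero expectation) are deleted as
    ``zero-detections``; images with fewer detections than expected as
    ``undercount``.  Overcounts are impossible under capped inference and
    are rejected as a contract violation.  Deletion is logical — the report
    records ids and reasons; no files are touched.
    """
    unknown = set(detections) - set(pool.expected_counts)
    if unknown:
        raise ValueError(f"detections for image ids not in pool: {sorted(unknown)}")
    kept: dict[str, list[Detection]] = {}
    deleted: dict[str, str] = {}
    for image_id, expected in pool.expected_counts.items():
        dets = list(detections.get(image_id, []))
        n = len(dets)
        if n > expected:
            raise ValueError(
                f"{image_id!r}: {n} detections exceed expected {expected}; "
                "capped inference violated"
            )
        if n == expected:
            kept[image_id] = dets
        elif n == 0:
            deleted[image_id] = "zero-detections"
        else:
            deleted[image_id] = "undercount"
    return FilterReport(kept=kept, deleted=deleted)


def apply_review(
    report: FilterReport, decisions: Mapping[str, bool]
) -> dict[str, list[BBox]]:
    """Apply manual accept/reject decisions to the kept images.

    Decisions are only valid for kept images.  Accepted images' detections
    are re-emitted as plain label boxes (confidence stripped), ready for
    training ingestion.
    """
    invalid = set(decisions) - set(report.kept)
    if invalid:
        raise ValueError(
            f"review decisions for images not in the kept set: {sorted(invalid)}"
        )
    return {
        image_id: [d.bbox for d in report.kept[image_id]]
        for image_id, accept in decisions.items()
        if accept
    }


def estimate_time_saved(n_worms: int, seconds_per_worm: float = 5.0) -> float:
    """Manual-labeling hours avoided, at one decimal place.

    Assumes an average manual labeling speed of ``seconds_per_worm`` (default
    5 s per worm): hours = n_worms * seconds_per_worm / 3600.
    """
    if n_worms < 0:
        raise ValueError("n_worms must be >= 0")
    return round(n_worms * seconds_per_worm / 3600.0, 1)
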