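"""Classical CPU worm detector: background flattening + thresholding +
connected-component shape filtering.

This is a deliberately simple, learning-free detector whose job is to
exercise the self-labeling and evaluation pipelines end to end on synthetic
imagery.  The pipeline: estimate the slowly varying background with a large
Gaussian kernel, form a polarity-resolved residual (worms darker or brighter
than local background), Otsu-threshold the residual, label connected
components, reject components by area and elongation (round agar speckle has
low elongation), and score each surviving component by its normalized mean
residual.  An optional cap keeps only the top-confidence boxes — the
max-detect mechanism the self-labeling procedure relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label, regionprops

from .annotations import BBox, Detection

__all__ = ["DetectorParams", "detect"]


@dataclass(frozen=True)
class DetectorParams:
    """Tunables for the classical detector.

    ``flatten_kernel_px`` must be much larger than the worm width so the
    background estimate does not absorb the worms themselves.  ``polarity``
    'auto' infers dark-vs-light worms from the skew of the raw residual.
    ``min_elongation`` is the minimum major/minor second-moment axis ratio —
    worms are elongated, speckle is round.  ``max_detections`` of None means
    unlimited.
    """

    flatten_kernel_px: float = 31.0
    polarity: Literal["auto", "dark", "light"] = "auto"
    min_area_px: int = 60
    max_area_px: int = 50_000
    min_elongation: float = 2.0
    max_detections: int | None = None
    #: residual floor added under Otsu so pure-noise images yield nothing
    min_residual: float = 0.05

    def __post_init__(self) -> None:
        if self.min_area_px >= self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")
        if self.flatten_kernel_px <= 0:
            raise ValueError("flatten_kernel_px must be positive")
        if self.max_detections is not None and self.max_detections < 0:
            raise ValueError("max_detections must be >= 0 or None")

    def with_cap(self, max_detections: int | None) -> "DetectorParams":
        return replace(self, max_detections=max_detections)


def detect(image: np.ndarray, params: DetectorParams = DetectorParams()) -> list[Detection]:
    """Run the classical detector on a grayscale or RGB image.

    Returns detections sorted by descending confidence, at most
    ``params.max_detections`` of them.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if img.ndim == 3:
        img = img.mean(axis=2)
    h, w = img.shape

    background = ndimage.gaussian_filter(img, sigma=params.flatten_kernel_px)
    raw = img - background
    if params.polarity == "auto":
        # dark worms pull the residual's left tail: negative skew
        centered = raw - raw.mean()
        m3 = (centered**3).mean()
        polarity = "dark" if m3 <= 0 else "light"
    else:
        polarity = params.polarity
    residual = np.clip(-raw if polarity == "dark" else raw, 0.0, None)

    if residual.max() <= 0:
        return []
    try:
        thr = threshold_otsu(residual)
    except ValueError:  # constant residual
        return []
    thr = max(thr, params.min_residual)
    fg = residual > thr
    if not fg.any():
        return []

    comp = _cc_label(fg, connectivity=2)
    max_resid = residual.max()
    dets: list[Detection] = []
    for rp in regionprops(comp, intensity_image=residual):
        if not (params.min_area_px <= rp.area <= params.max_area_px):
            continue
        minor = rp.axis_minor_length
        elongation = np.inf if minor == 0 else rp.axis_major_length / minor
        if elongation < params.min_elongation:
            continue
        y0, x0, y1, x1 = rp.bbox  # half-open
        bbox = BBox.from_pixel_box((x0, y0, x1 - 1, y1 - 1), (h, w))
        conf = float(np.clip(rp.intensity_mean / max_resid, 0.0, 1.0))
        dets.append(Detection(bbox, conf))

    dets.sort(key=lambda d: -d.confidence)
    if params.max_detections is not None:
        dets = dets[: params.max_detections]
    return dets
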