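"""Worm appearance rendering, scene assembly with automatic labels, and
detection-style data augmentation.

The appearance model is procedural: a worm mask is painted with a noisy body
intensity, band-limited texture, a darkened (or lightened) outline and a
Gaussian blur, then alpha-composited onto a synthetic agar-like background
(grain + low-frequency mottle + vignette + salt speckle).  Because each
worm's final mask in the scene is known, bounding-box labels come for free —
this is the core economy of synthetic detection data: the generator and the
labeler are the same process.

Augmentations mirror the standard single-stage-detector training repertoire:
multiplicative HSV jitter, affine translate/scale, horizontal flip, 2x2
mosaic composition, and aspect-preserving letterbox resize to a square whose
side is a multiple of 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor
from skimage import transform as _sktransform

from .annotations import BBox, mask_to_bbox, mask_to_pixel_box
from .shapes import WormMask

__all__ = [
    "AppearanceParams",
    "AugmentConfig",
    "SceneSpec",
    "WormCrop",
    "Placement",
    "SyntheticScene",
    "APPEARANCE_PRESETS",
    "make_background",
    "render_worm",
    "place_worms",
    "hsv_jitter",
    "geometric_augment",
    "mosaic",
    "letterbox_resize",
    "LetterboxTransform",
]

Polarity = Literal["dark-on-light", "light-on-dark"]


@dataclass(frozen=True)
class AppearanceParams:
    """Procedural appearance: worm body photometry and background statistics.

    All intensities are in [0, 1].  ``polarity`` selects dark worms on bright
    agar (the common transmitted-light case) or the inverted darkfield-like
    case.  ``edge_gain`` strengthens the body outline in the polarity
    direction; ``texture_scale`` is the correlation length (px) of the body
    texture; ``speckle_density`` is the per-pixel probability of a bright
    dust speck on the background.
    """

    polarity: Polarity = "dark-on-light"
    fg_mean: float = 0.30
    fg_std: float = 0.05
    edge_gain: float = 0.12
    texture_scale: float = 4.0
    blur_sigma: float = 1.0
    bg_mean: float = 0.75
    bg_std: float = 0.03
    vignette_strength: float = 0.20
    speckle_density: float = 0.0005

    def __post_init__(self) -> None:
        for name in ("fg_mean", "fg_std", "bg_mean", "bg_std", "vignette_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"AppearanceParams.{name} must be in [0, 1], got {v}")
        if self.blur_sigma < 0 or self.edge_gain < 0 or self.texture_scale < 0:
            raise ValueError("blur_sigma, edge_gain and texture_scale must be >= 0")
        if not 0.0 <= self.speckle_density <= 1.0:
            raise ValueError("speckle_density must be a probability")


APPEARANCE_PRESETS: dict[str, AppearanceParams] = {
    "default": AppearanceParams(),
    # high contrast, low noise, no distractors: the "easy" synthetic condition
    "easy": AppearanceParams(
        fg_mean=0.20,
        fg_std=0.02,
        edge_gain=0.10,
        texture_scale=3.0,
        blur_sigma=0.7,
        bg_mean=0.80,
        bg_std=0.01,
        vignette_strength=0.05,
        speckle_density=0.0,
    ),
    "inverted": AppearanceParams(polarity="light-on-dark", fg_mean=0.75, bg_mean=0.20),
}


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentation gains (detector-convention defaults)."""

    hsv_h: float = 0.015
    hsv_s: float = 0.7
    hsv_v: float = 0.4
    translate: float = 0.1
    scale: float = 0.5
    fliplr_p: float = 0.5
    mosaic_p: float = 1.0

    def __post_init__(self) -> None:
        for name in ("fliplr_p", "mosaic_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"AugmentConfig.{name} must be a probability, got {v}")
        for name in ("hsv_h", "hsv_s", "hsv_v", "translate", "scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"AugmentConfig.{name} must be >= 0")


@dataclass(frozen=True)
class SceneSpec:
    """How many worms to place on what canvas, and how they may interact."""

    canvas: tuple[int, int] = (512, 512)
    n_worms: int = 3
    max_pairwise_mask_overlap_frac: float = 0.0
    brightness_jitter: tuple[float, float] = (-0.05, 0.05)
    contrast_jitter: tuple[float, float] = (0.9, 1.1)
    placement_retries: int = 50

    def __post_init__(self) -> None:
        if min(self.canvas) < 64:
            raise ValueError(f"canvas dims must be >= 64, got {self.canvas}")
        if self.n_worms < 0:
            raise ValueError("n_worms must be >= 0")
        if not 0.0 <= self.max_pairwise_mask_overlap_frac <= 1.0:
            raise ValueError("overlap fraction must be in [0, 1]")


@dataclass
class WormCrop:
    """A rendered worm on its own tight canvas: intensity patch + soft alpha + hard mask."""

    patch: np.ndarray  # float (h, w)
    alpha: np.ndarray  # float (h, w), blurred mask
    mask: np.ndarray  # bool (h, w), the exact silhouette
    strain: str = ""


@dataclass
class Placement:
    worm_id: int
    mask: np.ndarray  # bool, scene-sized
    pixel_box: tuple[int, int, int, int]  # inclusive tight box of the mask
    bbox: BBox  # normalized


@dataclass
class SyntheticScene:
    """Composed image plus the per-worm placement records that label it."""

    image: np.ndarray
    placements: list[Placement]
    provenance: dict = field(default_factory=dict)
    #: True when the placement budget ran out and fewer worms than requested
    #: were placed; never silent.
    placement_shortfall: bool = False

    @property
    def labels(self) -> list[BBox]:
        return [p.bbox for p in self.placements]


# ---------------------------------------------------------------------------
# background and worm rendering


def make_background(
    appearance: AppearanceParams, canvas: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Synthetic worm-free agar background.

    Base intensity plus per-pixel Gaussian grain and low-frequency mottle
    (both with amplitude ``bg_std``), a radial vignette, and salt speckle at
    ``speckle_density``; clipped to [0, 1].
    """
    h, w = canvas
    img = np.full((h, w), appearance.bg_mean, dtype=float)
    if appearance.bg_std > 0:
        img += rng.normal(0.0, appearance.bg_std, size=(h, w))
        mottle = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 8.0)
        sd = mottle.std()
        if sd > 0:
            img += appearance.bg_std * mottle / sd
    if appearance.vignette_strength > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = ((yy - (h - 1) / 2.0) / (h / 2.0)) ** 2 + ((xx - (w - 1) / 2.0) / (w / 2.0)) ** 2
        img *= 1.0 - appearance.vignette_strength * r2 / 2.0
    if appearance.speckle_density > 0:
        salt = rng.random((h, w)) < appearance.speckle_density
        img[salt] = 1.0
    return np.clip(img, 0.0, 1.0)


def render_worm(
    worm_mask: WormMask | np.ndarray,
    appearance: AppearanceParams,
    rng: np.random.Generator,
) -> WormCrop:
    """Paint a worm silhouette with the procedural appearance model.

    Body intensity ~ N(fg_mean, fg_std) smoothed to ``texture_scale`` px
    correlation length; a 2-px outline band is pushed in the polarity
    direction by ``edge_gain``; patch and alpha are blurred by
    ``blur_sigma``.  With all of these at zero the crop is an exact
    constant-intensity silhouette and alpha equals the mask.
    """
    mask = worm_mask.raster if isinstance(worm_mask, WormMask) else np.asarray(worm_mask)
    strain = worm_mask.strain if isinstance(worm_mask, WormMask) else ""
    intensity = np.full(mask.shape, appearance.fg_mean, dtype=float)
    if appearance.fg_std > 0:
        noise = rng.standard_normal(mask.shape)
        if appearance.texture_scale > 0:
            noise = ndimage.gaussian_filter(noise, sigma=appearance.texture_scale)
            sd = noise.std()
            if sd > 0:
                noise /= sd
        intensity += appearance.fg_std * noise
    if appearance.edge_gain > 0:
        inner = ndimage.binary_erosion(mask, iterations=2)
        band = mask & ~inner
        sign = -1.0 if appearance.polarity == "dark-on-light" else 1.0
        intensity[band] += sign * appearance.edge_gain
    patch = np.clip(intensity, 0.0, 1.0)
    alpha = mask.astype(float)
    if appearance.blur_sigma > 0:
        patch = ndimage.gaussian_filter(patch, appearance.blur_sigma)
        alpha = np.clip(ndimage.gaussian_filter(alpha, appearance.blur_sigma), 0.0, 1.0)
    return WormCrop(patch=patch, alpha=alpha, mask=mask, strain=strain)


def _overlap_frac(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    if inter == 0:
        return 0.0
    return inter / min(a.sum(), b.sum())


def place_worms(
    background: np.ndarray,
    crops: Sequence[WormCrop],
    scene_spec: SceneSpec,
    rng: np.random.Generator,
) -> SyntheticScene:
    """Rejection-place worm crops onto a background, labelling as we go.

    Each crop gets a random quarter-turn (continuous rotation already comes
    from centerline sampling; quarter-turns stay raster-exact) and a uniform
    position, retried until the pairwise mask-overlap constraint is met.  A
    per-worm brightness/contrast jitter is applied before alpha compositing.
    When the retry budget runs out the scene is returned with fewer worms and
    ``placement_shortfall`` set.
    """
    h, w = background.shape[:2]
    if (h, w) != tuple(scene_spec.canvas):
        raise ValueError(
            f"background shape {(h, w)} != scene canvas {scene_spec.canvas}"
        )
    img = background.astype(float).copy()
    placements: list[Placement] = []
    shortfall = False
    for worm_id, crop in enumerate(crops[: scene_spec.n_worms]):
        placed = False
        for _ in range(scene_spec.placement_retries):
            k = int(rng.integers(0, 4))
            mask = np.rot90(crop.mask, k)
            ch, cw = mask.shape
            if ch > h or cw > w:
                break  # crop cannot fit this canvas at all
            top = int(rng.integers(0, h - ch + 1))
            left = int(rng.integers(0, w - cw + 1))
            scene_mask = np.zeros((h, w), dtype=bool)
            scene_mask[top : top + ch, left : left + cw] = mask
            if any(
                _overlap_frac(scene_mask, p.mask) > scene_spec.max_pairwise_mask_overlap_frac
                for p in placements
            ):
                continue
            patch = np.rot90(crop.patch, k)
            alpha = np.rot90(crop.alpha, k)
            gain = rng.uniform(*scene_spec.contrast_jitter)
            offset = rng.uniform(*scene_spec.brightness_jitter)
            patch = np.clip((patch - 0.5) * gain + 0.5 + offset, 0.0, 1.0)
            region = img[top : top + ch, left : left + cw]
            img[top : top + ch, left : left + cw] = region * (1.0 - alpha) + patch * alpha
            pixel_box = mask_to_pixel_box(scene_mask)
            placements.append(
                Placement(
                    worm_id=worm_id,
                    mask=scene_mask,
                    pixel_box=pixel_box,
                    bbox=mask_to_bbox(scene_mask),
                )
            )
            placed = True
            break
        if not placed:
            shortfall = True
    return SyntheticScene(
        image=img,
        placements=placements,
        provenance={"scene_spec": scene_spec},
        placement_shortfall=shortfall,
    )


# ---------------------------------------------------------------------------
# augmentation


def hsv_jitter(
    image: np.ndarray,
    gains: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Random multiplicative HSV jitter.

    Per-image gains are drawn uniformly from ``[1 - g, 1 + g]`` for each
    channel; hue wraps modulo 1, saturation and value clip.  Grayscale
    images are treated as value-only.  Zero gains are an exact identity.
    """
    gh, gs, gv = gains
    if min(gains) < 0:
        raise ValueError("HSV gains must be >= 0")
    rh, rs, rv = (rng.uniform(1.0 - g, 1.0 + g) for g in gains)
    if gh == gs == gv == 0.0:
        return image.copy()
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return np.clip(img * rv, 0.0, 1.0)
    hsv = _skcolor.rgb2hsv(np.clip(img, 0.0, 1.0))
    hsv[..., 0] = (hsv[..., 0] * rh) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * rs, 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] * rv, 0.0, 1.0)
    return np.clip(_skcolor.hsv2rgb(hsv), 0.0, 1.0)


_MIN_VISIBLE_AREA_PX = 8.0  # boxes smaller than this after clipping are dropped


def _transform_boxes(
    boxes: Sequence[BBox],
    map_xy,
    image_shape: tuple[int, int],
    min_area_px: float = _MIN_VISIBLE_AREA_PX,
) -> list[BBox]:
    """Map box corners through a point transform, clip to canvas, drop slivers."""
    h, w = image_shape[:2]
    out: list[BBox] = []
    for b in boxes:
        x0, y0, x1, y1 = b.to_corners(image_shape)
        corners = np.array([[x0, y0], [x1, y0], [x0, y1], [x1, y1]], dtype=float)
        mapped = np.asarray([map_xy(x, y) for x, y in corners])
        nx0, ny0 = mapped.min(axis=0)
        nx1, ny1 = mapped.max(axis=0)
        nx0, nx1 = np.clip([nx0, nx1], 0.0, w)
        ny0, ny1 = np.clip([ny0, ny1], 0.0, h)
        if (nx1 - nx0) * (ny1 - ny0) < min_area_px:
            continue
        out.append(BBox.from_corners((nx0, ny0, nx1, ny1), image_shape, b.class_id))
    return out


def geometric_augment(
    image: np.ndarray,
    labels: Sequence[BBox],
    translate: float,
    scale: float,
    fliplr_p: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[BBox]]:
    """Random uniform scale, translation, and horizontal flip with label remap.

    Scale is drawn in ``[1 - scale, 1 + scale]`` about the image center;
    translation up to ``±translate`` of each dimension.  Labels are mapped
    with the image, clipped to the canvas, and dropped when their visible
    area falls below 8 px².  A pure flip (or the identity draw) is applied
    raster-exactly.
    """
    h, w = image.shape[:2]
    s = rng.uniform(1.0 - scale, 1.0 + scale)
    tx = rng.uniform(-translate, translate) * w
    ty = rng.uniform(-translate, translate) * h
    flip = rng.random() < fliplr_p

    def map_xy(x: float, y: float) -> tuple[float, float]:
        if flip:
            x = w - x
        return (s * (x - w / 2.0) + w / 2.0 + tx, s * (y - h / 2.0) + h / 2.0 + ty)

    new_labels = _transform_boxes(labels, map_xy, (h, w))
    if s == 1.0 and tx == 0.0 and ty == 0.0:
        out = np.flip(image, axis=1).copy() if flip else image.copy()
        return out, new_labels
    # inverse map for warping (pad with the image median)
    def inv_map(coords: np.ndarray) -> np.ndarray:
        xy = coords[:, ::-1].astype(float)  # (row, col) -> (x, y)
        xy[:, 0] -= w / 2.0 + tx
        xy[:, 1] -= h / 2.0 + ty
        xy /= s
        xy[:, 0] += w / 2.0
        xy[:, 1] += h / 2.0
        if flip:
            xy[:, 0] = w - xy[:, 0]
        return xy[:, ::-1]

    warped = _sktransform.warp(
        np.asarray(image, dtype=float),
        inv_map,
        order=1,
        cval=float(np.median(image)),
        preserve_range=True,
    )
    return warped, new_labels


def mosaic(
    sources: Sequence[tuple[np.ndarray, Sequence[BBox]]],
    out_canvas: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[BBox]]:
    """Compose a 2x2 mosaic of four (image, labels) sources.

    The split point is drawn uniformly in the central 50% of each dimension;
    each source is resized to its tile and its labels remapped into the
    output frame, dropping boxes below the 8 px² visibility floor.
    """
    if len(sources) != 4:
        raise ValueError(f"mosaic needs exactly 4 sources, got {len(sources)}")
    h, w = out_canvas
    yc = int(round(rng.uniform(0.25, 0.75) * h))
    xc = int(round(rng.uniform(0.25, 0.75) * w))
    tiles = [
        (0, 0, yc, xc),
        (0, xc, yc, w),
        (yc, 0, h, xc),
        (yc, xc, h, w),
    ]
    out = np.zeros((h, w), dtype=float)
    first = np.asarray(sources[0][0])
    if first.ndim == 3:
        out = np.zeros((h, w, first.shape[2]), dtype=float)
    labels: list[BBox] = []
    for (img, boxes), (y0, x0, y1, x1) in zip(sources, tiles):
        th, tw = y1 - y0, x1 - x0
        img = np.asarray(img, dtype=float)
        tile = _sktransform.resize(
            img, (th, tw) + img.shape[2:], order=1, preserve_range=True, anti_aliasing=True
        )
        out[y0:y1, x0:x1] = tile
        for b in boxes:
            bx0, by0, bx1, by1 = b.to_corners(img.shape[:2])
            sx, sy = tw / img.shape[1], th / img.shape[0]
            nx0, ny0 = x0 + bx0 * sx, y0 + by0 * sy
            nx1, ny1 = x0 + bx1 * sx, y0 + by1 * sy
            if (nx1 - nx0) * (ny1 - ny0) < _MIN_VISIBLE_AREA_PX:
                continue
            labels.append(BBox.from_corners((nx0, ny0, nx1, ny1), (h, w), b.class_id))
    return out, labels


@dataclass(frozen=True)
class LetterboxTransform:
    """Record of a letterbox resize; maps boxes exactly in both directions."""

    scale: float
    pad_x: float
    pad_y: float
    orig_shape: tuple[int, int]
    target: int

    def apply_box(self, b: BBox) -> BBox:
        x0, y0, x1, y1 = b.to_corners(self.orig_shape)
        t = self.target
        return BBox.from_corners(
            (
                x0 * self.scale + self.pad_x,
                y0 * self.scale + self.pad_y,
                x1 * self.scale + self.pad_x,
                y1 * self.scale + self.pad_y,
            ),
            (t, t),
            b.class_id,
        )

    def invert_box(self, b: BBox) -> BBox:
        x0, y0, x1, y1 = b.to_corners((self.target, self.target))
        return BBox.from_corners(
            (
                (x0 - self.pad_x) / self.scale,
                (y0 - self.pad_y) / self.scale,
                (x1 - self.pad_x) / self.scale,
                (y1 - self.pad_y) / self.scale,
            ),
            self.orig_shape,
            b.class_id,
        )


def letterbox_resize(
    image: np.ndarray,
    labels: Sequence[BBox],
    target_long_side: int,
    pad_value: float | None = None,
) -> tuple[np.ndarray, list[BBox], LetterboxTransform]:
    """Aspect-preserving resize + symmetric padding to a square multiple of 32.

    Padding uses the image median by default (avoids artificial high-contrast
    borders).  The returned transform record maps boxes exactly in both
    directions.
    """
    if target_long_side % 32 != 0:
        raise ValueError(f"target size must be a multiple of 32, got {target_long_side}")
    img = np.asarray(image, dtype=float)
    h, w = img.shape[:2]
    r = target_long_side / max(h, w)
    nh, nw = int(round(h * r)), int(round(w * r))
    if (nh, nw) == (h, w):
        resized = img.copy()
    else:
        resized = _sktransform.resize(
            img, (nh, nw) + img.shape[2:], order=1, preserve_range=True, anti_aliasing=r < 1
        )
    pad_y = (target_long_side - nh) // 2
    pad_x = (target_long_side - nw) // 2
    if pad_value is None:
        pad_value = float(np.median(img))
    out_shape = (target_long_side, target_long_side) + img.shape[2:]
    out = np.full(out_shape, pad_value, dtype=float)
    out[pad_y : pad_y + nh, pad_x : pad_x + nw] = resized
    tfm = LetterboxTransform(
        scale=r, pad_x=float(pad_x), pad_y=float(pad_y), orig_shape=(h, w), target=target_long_side
    )
    return out, [tfm.apply_box(b) for b in labels], tfm
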