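"""Parametric worm body masks: sinusoidal centerline + power-taper width profile.

A worm silhouette is modelled as a variable-width tube around a smooth
centerline.  The centerline is a single sinusoidal undulation (amplitude and
wavelength drawn as fractions of body length) under a random rigid rotation
and translation; the half-width profile is ``w(s) = w_max * (4 s (1 - s))^tau``
on normalized arclength ``s``, which is zero at both ends, peaks at mid-body
and tapers with exponent ``tau``.  Rasterizing the union of disks of radius
``w(s)`` along the centerline produces a binary mask — a stadium-like shape
for a straight worm.

Strain presets encode the classical *C. elegans* morphology mutants relative
to wild type: *dpy*-like animals are short and wide, *lon*-like animals long
and narrow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import LineString
from skimage.draw import disk as _draw_disk
from skimage.measure import label as _cc_label

__all__ = [
    "StrainParams",
    "StrainRealization",
    "Centerline",
    "WidthProfile",
    "WormMask",
    "PRESETS",
    "sample_strain",
    "sample_centerline",
    "width_profile",
    "rasterize_worm",
    "generate_worm_mask",
]

Range = tuple[float, float]


def _check_range(name: str, r: Range) -> None:
    lo, hi = r
    if not (0 < lo <= hi):
        raise ValueError(f"{name} must satisfy 0 < min <= max, got {r}")


@dataclass(frozen=True)
class StrainParams:
    """Parameter ranges defining a strain's body-shape distribution.

    Lengths and widths are in pixels; undulation amplitude and wavelength are
    fractions of body length.
    """

    name: str
    length_px: Range
    max_halfwidth_px: Range
    undulation_amplitude_frac: Range
    undulation_wavelength_frac: Range
    taper_exponent: float

    def __post_init__(self) -> None:
        _check_range("length_px", self.length_px)
        _check_range("max_halfwidth_px", self.max_halfwidth_px)
        _check_range("undulation_amplitude_frac", self.undulation_amplitude_frac)
        _check_range("undulation_wavelength_frac", self.undulation_wavelength_frac)
        if self.taper_exponent <= 0:
            raise ValueError("taper_exponent must be positive")

    def scaled(self, name: str, length: float = 1.0, halfwidth: float = 1.0) -> "StrainParams":
        """A derived preset with length/halfwidth ranges multiplied by factors."""
        lo, hi = self.length_px
        wlo, whi = self.max_halfwidth_px
        return StrainParams(
            name=name,
            length_px=(lo * length, hi * length),
            max_halfwidth_px=(wlo * halfwidth, whi * halfwidth),
            undulation_amplitude_frac=self.undulation_amplitude_frac,
            undulation_wavelength_frac=self.undulation_wavelength_frac,
            taper_exponent=self.taper_exponent,
        )


_WILD_TYPE = StrainParams(
    name="wild-type",
    length_px=(200.0, 400.0),
    max_halfwidth_px=(8.0, 14.0),
    undulation_amplitude_frac=(0.05, 0.20),
    undulation_wavelength_frac=(0.4, 1.0),
    taper_exponent=0.8,
)

#: Built-in strain presets.  dpy-like = short and wide, lon-like = long and
#: narrow, both derived from the wild-type ranges; "wild-type-small" is a
#: 0.4x-scale variant used for compact demo scenes.
PRESETS: Mapping[str, StrainParams] = {
    "wild-type": _WILD_TYPE,
    "dpy-like": _WILD_TYPE.scaled("dpy-like", length=0.5, halfwidth=1.8),
    "lon-like": _WILD_TYPE.scaled("lon-like", length=1.5, halfwidth=0.7),
    "wild-type-small": _WILD_TYPE.scaled("wild-type-small", length=0.4, halfwidth=0.45),
}


@dataclass(frozen=True)
class StrainRealization:
    """Scalar shape parameters drawn from a preset's ranges."""

    strain: str
    length_px: float
    max_halfwidth_px: float
    amplitude_px: float
    wavelength_px: float
    taper_exponent: float

    def as_dict(self) -> dict[str, float | str]:
        return {
            "strain": self.strain,
            "length_px": self.length_px,
            "max_halfwidth_px": self.max_halfwidth_px,
            "amplitude_px": self.amplitude_px,
            "wavelength_px": self.wavelength_px,
            "taper_exponent": self.taper_exponent,
        }


@dataclass
class Centerline:
    """Ordered 2-D polyline (continuous 0-based pixel coords, x right / y down)."""

    points: np.ndarray  # (N, 2) float, columns (x, y)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 16:
            raise ValueError("centerline needs >= 16 (x, y) points")

    @property
    def arclength(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def is_simple(self) -> bool:
        return LineString(self.points).is_simple


@dataclass
class WidthProfile:
    halfwidths: np.ndarray  # per-centerline-point half-width, px

    def __post_init__(self) -> None:
        self.halfwidths = np.asarray(self.halfwidths, dtype=float)
        if np.any(self.halfwidths < 0):
            raise ValueError("half-widths must be non-negative")


@dataclass
class WormMask:
    """Binary raster of one worm plus the parameters that produced it."""

    raster: np.ndarray  # bool, (H, W)
    strain: str
    seed: int | list[int] | None
    params_used: dict

    @property
    def area(self) -> int:
        return int(self.raster.sum())


def sample_strain(
    preset: str | StrainParams, rng: np.random.Generator
) -> StrainRealization:
    """Draw one scalar realization from a preset's parameter ranges.

    Amplitude and wavelength fractions are converted to pixels using the drawn
    length.  The same generator state always yields the same realization.
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown strain preset {preset!r}; known: {sorted(PRESETS)}"
            ) from None
    length = rng.uniform(*preset.length_px)
    return StrainRealization(
        strain=preset.name,
        length_px=length,
        max_halfwidth_px=rng.uniform(*preset.max_halfwidth_px),
        amplitude_px=rng.uniform(*preset.undulation_amplitude_frac) * length,
        wavelength_px=rng.uniform(*preset.undulation_wavelength_frac) * length,
        taper_exponent=preset.taper_exponent,
    )


def _sinusoid_arc(real: StrainRealization, phase: float, n_fine: int = 2048):
    """Sinusoid sampled so that its arclength matches the requested body length.

    Solves for the x-extent iteratively (the curve is longer than its chord),
    then returns fine (x, y) samples and cumulative arclength.
    """
    L = real.length_px
    extent = L
    for _ in range(4):
        x = np.linspace(0.0, extent, n_fine)
        if real.amplitude_px == 0.0:
            y = np.zeros_like(x)
        else:
            y = real.amplitude_px * np.sin(2.0 * np.pi * x / real.wavelength_px + phase)
        seg = np.hypot(np.diff(x), np.diff(y))
        arclen = seg.sum()
        extent *= L / arclen
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return x, y, cum


def sample_centerline(
    real: StrainRealization,
    rng: np.random.Generator,
    canvas_shape: tuple[int, int] | None = None,
    margin: float = 2.0,
    n_points: int | None = None,
    max_retries: int = 20,
) -> Centerline:
    """Sample an undulating centerline under a random rigid motion.

    The curve is a sinusoid with the realization's amplitude/wavelength and a
    random phase, resampled to uniform spacing, rotated by a random angle and —
    when ``canvas_shape`` is given — translated uniformly among positions where
    the full tube (centerline dilated by the maximum half-width plus ``margin``)
    fits inside the canvas.  Self-intersecting draws (possible only through
    numerical degeneracy) are redrawn up to ``max_retries`` times.
    """
    if n_points is None:
        n_points = max(16, int(round(real.length_px / 3.0)))
    pad = real.max_halfwidth_px + margin
    for _ in range(max_retries):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        x, y, cum = _sinusoid_arc(real, phase)
        s_targets = np.linspace(0.0, cum[-1], n_points)
        xs = np.interp(s_targets, cum, x)
        ys = np.interp(s_targets, cum, y)
        pts = np.column_stack([xs, ys])
        pts -= pts.mean(axis=0)
        c, s = np.cos(theta), np.sin(theta)
        pts = pts @ np.array([[c, -s], [s, c]]).T
        if canvas_shape is not None:
            h, w = canvas_shape
            lo = pts.min(axis=0)
            hi = pts.max(axis=0)
            # feasible translation range so the tube keeps >= margin from borders
            tx_lo, ty_lo = pad - lo
            tx_hi, ty_hi = np.array([w - 1, h - 1]) - pad - hi
            if tx_hi < tx_lo or ty_hi < ty_lo:
                continue  # worm does not fit at this orientation; redraw
            pts = pts + np.array([rng.uniform(tx_lo, tx_hi), rng.uniform(ty_lo, ty_hi)])
        cl = Centerline(pts)
        if cl.is_simple():
            return cl
    raise RuntimeError(
        f"could not sample a feasible centerline in {max_retries} attempts "
        f"(length {real.length_px:.0f} px on canvas {canvas_shape})"
    )


def width_profile(real: StrainRealization, n_points: int) -> WidthProfile:
    """Power-taper half-width profile ``w(s) = w_max (4 s (1-s))^tau``.

    The profile is exactly 0 at both endpoints and reaches ``w_max`` at mid
    body (s = 0.5).
    """
    if n_points < 16:
        raise ValueError(f"n_points must be >= 16, got {n_points}")
    s = np.linspace(0.0, 1.0, n_points)
    w = real.max_halfwidth_px * (4.0 * s * (1.0 - s)) ** real.taper_exponent
    return WidthProfile(w)


_MIN_DISK_RADIUS = 0.8  # keeps consecutive stamped disks 8-connected
_SKIP_RADIUS = 0.3  # tail tips thinner than this contribute no pixels


def rasterize_worm(
    centerline: Centerline,
    widths: WidthProfile,
    canvas_shape: tuple[int, int],
    *,
    strain: str = "",
    seed: int | None = None,
    params_used: dict | None = None,
) -> WormMask:
    """Rasterize the variable-width tube as a union of disks on the centerline.

    The centerline and width profile are first resampled to sub-pixel spacing
    so the stamped disks overlap; radii below ~0.3 px (the extreme tail tips)
    are skipped and radii up to 0.8 px are clamped to 0.8 px to keep the mask
    a single 8-connected component.
    """
    pts = centerline.points
    w = widths.halfwidths
    if len(w) != len(pts):
        raise ValueError("width profile and centerline must have the same length")
    h_c, w_c = canvas_shape
    lo = (pts - w[:, None]).min(axis=0)
    hi = (pts + w[:, None]).max(axis=0)
    if lo[0] < 2 or lo[1] < 2 or hi[0] > w_c - 3 or hi[1] > h_c - 3:
        raise ValueError(
            f"worm tube (extent x {lo[0]:.1f}..{hi[0]:.1f}, y {lo[1]:.1f}..{hi[1]:.1f}) "
            f"does not fit canvas {canvas_shape} with a 2 px margin"
        )

    # dense resample along arclength (~0.7 px spacing)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n_dense = max(len(pts), int(np.ceil(cum[-1] / 0.7)) + 1)
    s = np.linspace(0.0, cum[-1], n_dense)
    xd = np.interp(s, cum, pts[:, 0])
    yd = np.interp(s, cum, pts[:, 1])
    wd = np.interp(s, cum, w)

    mask = np.zeros(canvas_shape, dtype=bool)
    for x, y, r in zip(xd, yd, wd):
        if r < _SKIP_RADIUS:
            continue
        rr, cc = _draw_disk((y, x), max(r, _MIN_DISK_RADIUS), shape=canvas_shape)
        mask[rr, cc] = True

    n_comp = _cc_label(mask, connectivity=2).max()
    if n_comp != 1:
        raise RuntimeError(f"rasterized mask has {n_comp} components, expected 1")
    return WormMask(
        raster=mask, strain=strain, seed=seed, params_used=dict(params_used or {})
    )


def generate_worm_mask(
    preset: str | StrainParams,
    seed: int | Sequence[int] | np.random.Generator,
    canvas_shape: tuple[int, int] | None = None,
    margin: float = 2.0,
) -> WormMask:
    """Sample a strain realization and rasterize it in one step.

    When ``canvas_shape`` is omitted the canvas is auto-sized to the worm's
    extent plus margin, producing a tight single-worm crop.
    """
    if isinstance(seed, np.random.Generator):
        rng, seed_rec = seed, None
    else:
        rng = np.random.default_rng(seed)
        seed_rec = int(seed) if np.isscalar(seed) else list(seed)
    real = sample_strain(preset, rng)
    if canvas_shape is None:
        cl = sample_centerline(real, rng, canvas_shape=None, margin=margin)
        pts = cl.points
        pad = real.max_halfwidth_px + margin + 1
        pts = pts - pts.min(axis=0) + pad
        cl = Centerline(pts)
        hi = pts.max(axis=0) + pad
        canvas_shape = (int(np.ceil(hi[1])) + 1, int(np.ceil(hi[0])) + 1)
    else:
        cl = sample_centerline(real, rng, canvas_shape=canvas_shape, margin=margin)
    wp = width_profile(real, len(cl.points))
    return rasterize_worm(
        cl, wp, canvas_shape, strain=real.strain, seed=seed_rec, params_used=real.as_dict()
    )
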