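"""Appearance rendering, scene assembly with auto-labels, and augmentation."""

import numpy as np
import pytest

from wormsynth.annotations import BBox, mask_to_bbox, mask_to_pixel_box
from wormsynth.render import (
    AppearanceParams,
    AugmentConfig,
    SceneSpec,
    geometric_augment,
    hsv_jitter,
    letterbox_resize,
    make_background,
    mosaic,
    place_worms,
    render_worm,
)
from wormsynth.shapes import generate_worm_mask


def _flat_appearance(**kw):
    base = dict(
        fg_mean=0.25,
        fg_std=0.0,
        edge_gain=0.0,
        texture_scale=0.0,
        blur_sigma=0.0,
        bg_mean=0.75,
        bg_std=0.0,
        vignette_strength=0.0,
        speckle_density=0.0,
    )
    base.update(kw)
    return AppearanceParams(**base)


class TestAugmentConfigDefaults:
    def test_detector_convention_defaults(self):
        cfg = AugmentConfig()
        assert (cfg.hsv_h, cfg.hsv_s, cfg.hsv_v) == (0.015, 0.7, 0.4)
        assert (cfg.translate, cfg.scale) == (0.1, 0.5)
        assert (cfg.fliplr_p, cfg.mosaic_p) == (0.5, 1.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(mosaic_p=1.5)


class TestMakeBackground:
    def test_all_noise_off_gives_constant(self, rng):
        bg = make_background(_flat_appearance(), (64, 64), rng)
        assert np.all(bg == 0.75)

    def test_speckle_count_within_binomial_bounds(self, rng):
        app = _flat_appearance(bg_mean=0.5, speckle_density=0.001)
        bg = make_background(app, (512, 512), rng)
        count = int((bg == 1.0).sum())
        expected = 0.001 * 512 * 512  # 262.1
        sigma = np.sqrt(expected * 0.999)
        assert abs(count - expected) <= 3 * sigma

    def test_same_seed_is_reproducible(self):
        app = AppearanceParams()
        a = make_background(app, (96, 96), np.random.default_rng(3))
        b = make_background(app, (96, 96), np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_values_clipped_to_unit_range(self, rng):
        app = AppearanceParams(bg_mean=0.9, bg_std=0.3, speckle_density=0.01)
        bg = make_background(app, (64, 64), rng)
        assert bg.min() >= 0.0 and bg.max() <= 1.0


class TestRenderWorm:
    def test_flat_params_give_constant_silhouette(self, rng):
        mask = generate_worm_mask("wild-type-small", 0)
        crop = render_worm(mask, _flat_appearance(), rng)
        assert np.array_equal(crop.alpha, mask.raster.astype(float))
        assert np.all(crop.patch == 0.25)

    def test_dark_on_light_body_darker_than_background(self, rng):
        mask = generate_worm_mask("wild-type-small", 1)
        app = AppearanceParams(fg_mean=0.3, bg_mean=0.8)
        crop = render_worm(mask, app, rng)
        assert crop.patch[mask.raster].mean() < app.bg_mean

    def test_alpha_equals_mask_when_blur_zero(self, rng):
        mask = generate_worm_mask("dpy-like", 2)
        crop = render_worm(mask, _flat_appearance(fg_std=0.05, texture_scale=3.0), rng)
        assert np.array_equal(crop.alpha, mask.raster.astype(float))


class TestPlaceWorms:
    def _crops(self, n, rng_seed=0):
        app = _flat_appearance()
        rng = np.random.default_rng(rng_seed)
        return [
            render_worm(generate_worm_mask("wild-type-small", [rng_seed, i]), app, rng)
            for i in range(n)
        ]

    def test_zero_worms_returns_background_unchanged(self, rng):
        bg = make_background(_flat_appearance(), (256, 256), rng)
        spec = SceneSpec(canvas=(256, 256), n_worms=0)
        scene = place_worms(bg, [], spec, rng)
        assert np.array_equal(scene.image, bg)
        assert scene.placements == [] and not scene.placement_shortfall

    def test_five_worms_no_overlap(self, rng):
        bg = np.full((512, 512), 0.75)
        crops = self._crops(5)
        spec = SceneSpec(canvas=(512, 512), n_worms=5)
        scene = place_worms(bg, crops, spec, rng)
        assert len(scene.placements) == 5
        for i, a in enumerate(scene.placements):
            for b in scene.placements[i + 1 :]:
                assert not np.logical_and(a.mask, b.mask).any()

    def test_recorded_bbox_is_tight_bbox_of_placed_mask(self, rng):
        bg = np.full((384, 384), 0.8)
        spec = SceneSpec(canvas=(384, 384), n_worms=3)
        scene = place_worms(bg, self._crops(3, 1), spec, rng)
        for p in scene.placements:
            assert p.pixel_box == mask_to_pixel_box(p.mask)
            assert p.bbox == mask_to_bbox(p.mask)
            # brute-force tightness via row/column projections
            rows = np.flatnonzero(p.mask.any(axis=1))
            cols = np.flatnonzero(p.mask.any(axis=0))
            assert p.pixel_box == (cols[0], rows[0], cols[-1], rows[-1])

    def test_budget_exhaustion_flags_shortfall(self, rng):
        # worms larger than the canvas can never be placed
        bg = np.full((64, 64), 0.75)
        spec = SceneSpec(canvas=(64, 64), n_worms=2, placement_retries=5)
        scene = place_worms(bg, self._crops(2), spec, rng)
        assert scene.placement_shortfall
        assert len(scene.placements) < 2


class TestHsvJitter:
    def test_zero_gains_identity(self, rng):
        img = np.random.default_rng(0).random((32, 32, 3))
        out = hsv_jitter(img, (0, 0, 0), rng)
        assert np.array_equal(out, img)

    def test_output_stays_in_range(self, rng):
        img = np.random.default_rng(0).random((32, 32, 3))
        out = hsv_jitter(img, (0.015, 0.7, 0.4), rng)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_fixed_seed_reproducible(self):
        img = np.random.default_rng(0).random((32, 32, 3))
        a = hsv_jitter(img, (0.015, 0.7, 0.4), np.random.default_rng(5))
        b = hsv_jitter(img, (0.015, 0.7, 0.4), np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_grayscale_is_value_only_gain(self):
        img = np.full((16, 16), 0.5)
        out = hsv_jitter(img, (0.0, 0.0, 0.4), np.random.default_rng(1))
        assert out.shape == img.shape
        assert np.unique(out).size == 1  # uniform multiplicative gain


class TestGeometricAugment:
    def test_identity_when_all_off(self, rng):
        img = np.random.default_rng(0).random((64, 64))
        labels = [BBox(0.5, 0.5, 0.2, 0.2)]
        out, lab = geometric_augment(img, labels, 0.0, 0.0, 0.0, rng)
        assert np.array_equal(out, img)
        assert lab[0].cx == pytest.approx(0.5) and lab[0].w == pytest.approx(0.2)

    def test_flip_twice_restores_labels(self):
        img = np.random.default_rng(0).random((64, 96))
        labels = [BBox(0.3, 0.6, 0.1, 0.2), BBox(0.7, 0.2, 0.15, 0.1)]
        once_img, once = geometric_augment(img, labels, 0.0, 0.0, 1.0,
                                           np.random.default_rng(0))
        twice_img, twice = geometric_augment(once_img, once, 0.0, 0.0, 1.0,
                                             np.random.default_rng(0))
        assert np.array_equal(twice_img, img)
        for a, b in zip(labels, twice):
            assert a.cx == pytest.approx(b.cx, abs=1e-9)
            assert a.w == pytest.approx(b.w, abs=1e-9)

    def test_transformed_box_matches_transformed_mask_bbox(self, rng):
        # mask-backed oracle: warp the worm mask with the same transform and
        # compare its tight box against the transformed label
        from skimage.transform import rescale

        mask = generate_worm_mask("wild-type-small", 3).raster
        h, w = 256, 256
        canvas = np.zeros((h, w), bool)
        mh, mw = mask.shape
        canvas[60 : 60 + mh, 80 : 80 + mw] = mask
        label = mask_to_bbox(canvas)
        # pure flip: raster-exact on masks
        _, labels = geometric_augment(
            canvas.astype(float), [label], 0.0, 0.0, 1.0, np.random.default_rng(2)
        )
        flipped_box = mask_to_bbox(np.flip(canvas, axis=1))
        got = labels[0].to_pixel_box((h, w))
        want = flipped_box.to_pixel_box((h, w))
        assert all(abs(a - b) <= 1 for a, b in zip(got, want))

    def test_scale_and_translate_move_labels_consistently(self):
        img = np.full((128, 128), 0.5)
        img[40:60, 30:50] = 0.0
        label = BBox.from_pixel_box((30, 40, 49, 59), (128, 128))
        out, labels = geometric_augment(img, [label], 0.2, 0.3, 0.0,
                                        np.random.default_rng(7))
        assert len(labels) == 1
        # the dark square's warped footprint contains the new box center
        x0, y0, x1, y1 = labels[0].to_corners((128, 128))
        assert out[int((y0 + y1) / 2), int((x0 + x1) / 2)] < 0.3


class TestMosaic:
    def _one_worm_scene(self, seed):
        rng = np.random.default_rng(seed)
        bg = np.full((128, 128), 0.75)
        crop = render_worm(generate_worm_mask("wild-type-small", [9, seed]),
                           _flat_appearance(), rng)
        scene = place_worms(bg, [crop], SceneSpec(canvas=(128, 128), n_worms=1), rng)
        return scene.image, scene.labels

    def test_four_one_worm_scenes_give_four_labels(self, rng):
        sources = [self._one_worm_scene(s) for s in range(4)]
        img, labels = mosaic(sources, (256, 256), rng)
        assert img.shape == (256, 256)
        assert len(labels) == 4

    def test_label_count_never_exceeds_source_total(self, rng):
        sources = [self._one_worm_scene(s) for s in range(4)]
        for trial in range(5):
            _, labels = mosaic(sources, (160, 160), np.random.default_rng(trial))
            assert len(labels) <= sum(len(l) for _, l in sources)

    def test_every_output_box_inside_canvas(self, rng):
        sources = [self._one_worm_scene(s) for s in range(4)]
        _, labels = mosaic(sources, (200, 200), rng)
        for b in labels:
            x0, y0, x1, y1 = b.to_corners((200, 200))
            assert 0 <= x0 <= x1 <= 200 and 0 <= y0 <= y1 <= 200

    def test_wrong_source_count_rejected(self, rng):
        with pytest.raises(ValueError, match="exactly 4"):
            mosaic([self._one_worm_scene(0)] * 3, (128, 128), rng)


class TestLetterboxResize:
    def test_square_input_at_target_is_identity(self):
        img = np.random.default_rng(0).random((160, 160))
        labels = [BBox(0.4, 0.6, 0.1, 0.1)]
        out, lab, tfm = letterbox_resize(img, labels, 160)
        assert np.array_equal(out, img)
        assert tfm.scale == 1.0 and tfm.pad_x == 0.0 and tfm.pad_y == 0.0
        assert lab[0].cx == pytest.approx(0.4)

    def test_rectangular_scaling_and_padding_arithmetic(self):
        img = np.zeros((500, 1000))
        out, _, tfm = letterbox_resize(img, [], 1728)
        assert out.shape == (1728, 1728)
        assert tfm.scale == pytest.approx(1.728)
        assert tfm.pad_y == 432.0 and tfm.pad_x == 0.0  # (1728 - 864) / 2

    def test_non_multiple_of_32_rejected(self):
        with pytest.raises(ValueError, match="multiple of 32"):
            letterbox_resize(np.zeros((100, 100)), [], 100)

    def test_box_roundtrip_through_transform(self):
        img = np.zeros((300, 700))
        boxes = [BBox(0.31, 0.62, 0.11, 0.23), BBox(0.81, 0.21, 0.05, 0.4)]
        _, mapped, tfm = letterbox_resize(img, boxes, 640)
        for orig, m in zip(boxes, mapped):
            back = tfm.invert_box(m)
            assert back.cx == pytest.approx(orig.cx, abs=1e-6)
            assert back.cy == pytest.approx(orig.cy, abs=1e-6)
            assert back.w == pytest.approx(orig.w, abs=1e-6)
            assert back.h == pytest.approx(orig.h, abs=1e-6)

    def test_padding_uses_background_median(self):
        img = np.full((100, 200), 0.6)
        out, _, _ = letterbox_resize(img, [], 224)
        assert out[0, 0] == 0.6
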