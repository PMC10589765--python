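"""Apply the detection-training augmentation repertoire to generated scenes.

Shows HSV/value jitter, random scale+translate+flip with label remapping,
2x2 mosaic composition, and letterbox resize to a square multiple of 32 —
the same transform family single-stage detectors train with.
"""

import numpy as np

from wormsynth.pipeline import GenerationConfig, make_scene, scene_rng
from wormsynth.render import AugmentConfig, geometric_augment, hsv_jitter, letterbox_resize, mosaic

rng = np.random.default_rng(3)
cfg = AugmentConfig()  # hsv 0.015/0.7/0.4, translate 0.1, scale 0.5, flip 0.5, mosaic 1.0
scenes = [make_scene(GenerationConfig(canvas=(256, 256)), scene_rng(3, i)) for i in range(4)]

jittered = hsv_jitter(scenes[0].image, (cfg.hsv_h, cfg.hsv_s, cfg.hsv_v), rng)
print(f"value jitter: mean {scenes[0].image.mean():.3f} -> {jittered.mean():.3f}")

img, labels = geometric_augment(
    scenes[0].image, scenes[0].labels, cfg.translate, cfg.scale, cfg.fliplr_p, rng
)
print(f"geometric: {len(scenes[0].labels)} labels in -> {len(labels)} labels out "
      "(boxes clipped to canvas, slivers dropped)")

mosaic_img, mosaic_labels = mosaic(
    [(s.image, s.labels) for s in scenes], (256, 256), rng
)
source_total = sum(len(s.labels) for s in scenes)
print(f"mosaic: 4 scenes with {source_total} labels -> one {mosaic_img.shape} "
      f"image with {len(mosaic_labels)} labels")

boxed, mapped, tfm = letterbox_resize(scenes[0].image, scenes[0].labels, 320)
print(f"letterbox: {scenes[0].image.shape} -> {boxed.shape} at scale {tfm.scale:.3f}; "
      "the transform record maps boxes exactly both ways.")
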