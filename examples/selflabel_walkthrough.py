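"""Walk through the count-capped self-labeling procedure on a synthetic pool.

The pool's images have known worm counts but no boxes.  The detector runs
with its detection cap set to each image's expected count (so it can never
overcount), images whose detected count equals the expected count are kept,
the rest are logically deleted with a reason, and accepted detections become
plain training labels.  The printed hours figure is what hand-labeling the
kept worms would have cost at 5 s per worm.
"""

from wormsynth.detector import detect
from wormsynth.pipeline import EASY_DETECTOR, GenerationConfig, generate_scenes
from wormsynth.selflabel import (
    ImagePool,
    apply_review,
    capped_inference,
    estimate_time_saved,
    filter_by_count,
    group_by_count,
)

scenes = generate_scenes(GenerationConfig(), n_images=40, seed=5)
ids = [f"frame_{i:03d}" for i in range(len(scenes))]
images = {i: s.image for i, s in zip(ids, scenes)}
pool = ImagePool({i: len(s.placements) for i, s in zip(ids, scenes)})

groups = group_by_count(pool)
print(f"pool of {len(pool)} images grouped by count: "
      + ", ".join(f"{k} worms x{len(v)}" for k, v in sorted(groups.items())))

capped = {}
for expected, group in sorted(groups.items()):
    capped.update(capped_inference(EASY_DETECTOR, images, group, expected))

report = filter_by_count(capped, pool)
print(f"kept {report.n_kept} images (detected == expected), "
      f"deleted {report.n_deleted}: {dict(sorted(report.deleted.items()))}")

labels = apply_review(report, {i: True for i in report.kept})  # accept-all review
hours = estimate_time_saved(report.kept_worms)
print(f"accepted {len(labels)} images with {report.kept_worms} worms; "
      f"manual labeling would have taken {hours} h at 5 s/worm.")
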