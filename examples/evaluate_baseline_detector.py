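"""Run the classical baseline detector over seeded scenes and score it.

Precision is the fraction of detections that hit a real worm (IoU >= 0.5),
recall the fraction of worms found, and AP@0.5 the area under the
precision-recall curve as confidence is swept.
"""

from wormsynth.detector import detect
from wormsynth.metrics import evaluate_dataset
from wormsynth.pipeline import EASY_DETECTOR, GenerationConfig, generate_scenes

scenes = generate_scenes(GenerationConfig(), n_images=30, seed=11)
labels = {f"s{i}": s.labels for i, s in enumerate(scenes)}
detections = {f"s{i}": detect(s.image, EASY_DETECTOR) for i, s in enumerate(scenes)}

result = evaluate_dataset(detections, labels, (512, 512))
n_gt = sum(len(b) for b in labels.values())
n_det = sum(len(d) for d in detections.values())
print(f"{len(scenes)} scenes, {n_gt} worms, {n_det} detections")
print(f"precision={float(result.precision):.3f}  recall={float(result.recall):.3f}  "
      f"AP@0.5={result.ap:.3f}")
misses = {k: v for k, v in result.per_image.items() if v["fp"] or v["fn"]}
print(f"images with any error: {len(misses)} of {len(scenes)}")
print("on this high-contrast low-noise condition the classical detector is "
      "near-perfect; errors come from worms whose components merge or fall "
      "below the area floor.")
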