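"""Generate a small auto-labeled synthetic dataset and write it to disk.

Each scene is a synthetic agar background with 1-5 rendered worms; the
bounding-box labels come for free because the compositor knows every worm's
final mask.  The dataset layout (images/, labels/ in YOLO txt, manifest.json
with every seed) is reconstructible from the manifest alone.
"""

import tempfile
from pathlib import Path

from wormsynth.pipeline import GenerationConfig, generate_scenes, write_dataset

config = GenerationConfig(strain_preset="wild-type", appearance="easy")
scenes = generate_scenes(config, n_images=8, seed=42)

out = Path(tempfile.mkdtemp(prefix="wormsynth_")) / "dataset"
write_dataset(scenes, out, config, seed=42)

n_worms = sum(len(s.placements) for s in scenes)
print(f"wrote {len(scenes)} images with {n_worms} worms total to {out}")
for i, scene in enumerate(scenes[:3]):
    boxes = ", ".join(f"({b.cx:.2f},{b.cy:.2f},{b.w:.2f},{b.h:.2f})" for b in scene.labels)
    print(f"  scene {i}: {len(scene.labels)} labels {boxes}")
print("labels are normalized (cx, cy, w, h); every box is the tight box of its worm mask.")
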