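"""Sample parametric worm masks for the three strain presets and compare
their body proportions.

dpy-like (dumpy) worms are short and wide, lon-like worms long and narrow;
the printed aspect ratios (body length / max half-width) should separate the
two cleanly, with wild type in between.
"""

import numpy as np

from wormsynth.shapes import generate_worm_mask, sample_strain

for preset in ("wild-type", "dpy-like", "lon-like"):
    reals = [sample_strain(preset, np.random.default_rng(s)) for s in range(50)]
    aspect = [r.length_px / r.max_halfwidth_px for r in reals]
    print(
        f"{preset:>10}: length {np.mean([r.length_px for r in reals]):6.1f} px, "
        f"half-width {np.mean([r.max_halfwidth_px for r in reals]):5.1f} px, "
        f"aspect {np.mean(aspect):5.1f} (min {min(aspect):.1f}, max {max(aspect):.1f})"
    )

mask = generate_worm_mask("dpy-like", seed=7)
print(
    f"\none dpy-like mask: canvas {mask.raster.shape}, {mask.area} foreground px, "
    f"drawn from {mask.params_used['length_px']:.0f} px body length"
)
print("aspect ratios: higher = longer and thinner; dpy < wild type < lon.")
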