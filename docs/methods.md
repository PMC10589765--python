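# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what its synthetic conditions do and do not say
about real plate imagery.

## Worm shape model

A worm silhouette is a variable-width tube around a smooth centerline.

**Centerline.** A single sinusoid `y(x) = A sin(2πx/λ + φ)` with random
phase, rotated rigidly by a uniform angle and translated uniformly among
positions where the full tube keeps a ≥ 2 px margin from the canvas border.
The x-extent is solved iteratively (four fixed-point steps) so the *arc
length* matches the drawn body length within ±5%; the curve is then
resampled to uniform spacing (one point per ~3 px of body). Because a
rotated function graph cannot self-intersect, simplicity violations can only
arise numerically; they are checked (shapely `is_simple`) and redrawn, with
a bound of 20 attempts before an error — an intentional signal of infeasible
parameters rather than a silent fallback.

**Width profile.** `w(s) = w_max (4 s (1 − s))^τ` on normalized arclength
`s ∈ [0, 1]`: exactly zero at both ends, maximal at mid-body, taper
controlled by `τ`. The default `τ = 0.8` gives a slightly fuller taper than
linear.

**Strain presets** (pixels; ranges sampled uniformly per worm):

| preset     | length (px) | max half-width (px) | amplitude (×L) | wavelength (×L) |
|------------|-------------|---------------------|----------------|------------------|
| wild-type  | 200–400     | 8–14                | 0.05–0.20      | 0.4–1.0          |
| dpy-like   | ×0.5        | ×1.8                | same           | same             |
| lon-like   | ×1.5        | ×0.7                | same           | same             |

The dpy/lon factors are chosen to reproduce the qualitative "short and
wide" vs "long and narrow" contrast of the classical morphology mutants;
they are not fitted to measurements. A `wild-type-small` preset (×0.4
length, ×0.45 width) exists for compact fixtures. All presets are
user-overridable via `StrainParams`.

**Rasterization.** The mask is the union of disks along the centerline,
resampled to ~0.7 px spacing so consecutive disks overlap. Disk radii below
0.3 px (the extreme tail tips) are skipped; radii up to 0.8 px are clamped
to 0.8 px so the mask stays one 8-connected component. `skimage.draw.disk`
uses a strict `dist < r` inclusion test, which is unbiased for generic
subpixel centers; masks are validated to be single-component with no
foreground on the canvas border. Coordinates are 0-based pixels, x right /
y down, row-major.

## Appearance and scene model

The renderer is procedural, standing in for a learned image-to-image
generator while keeping the same dataflow (mask → appearance → crop →
assembly → automatic label), so a learned backend could be swapped in
without touching labels or metrics.

Background: constant base intensity + per-pixel Gaussian grain and
low-frequency mottle (both amplitude `bg_std`; mottle correlation length =
canvas/8), radial vignette, and salt speckle (per-pixel probability
`speckle_density`). Worm crop: body intensity N(`fg_mean`, `fg_std`)
smoothed to `texture_scale` px, a 2-px outline band pushed darker (or
lighter, under inverted polarity) by `edge_gain`, then Gaussian blur of
patch and alpha by `blur_sigma`. Per-worm brightness/contrast jitter is
applied before alpha-compositing.

Placement rejection-samples positions (and raster-exact quarter-turns; the
continuous rotation already comes from centerline sampling — interpolating
a rotated raster would break the exact mask/bbox correspondence) until the
pairwise mask-overlap constraint is met, 50 tries per worm. The default
overlap budget is 0 (non-touching): worm aggregation is a known error mode
of real plates and is deliberately out of this generator's scope. Budget
exhaustion returns a scene with fewer worms and an explicit
`placement_shortfall` flag, never silently.

The "easy" appearance preset (fg 0.20 vs bg 0.80, σ = 0.01–0.02, no
speckle) defines the package's reference condition: high contrast, low
noise, ≤ 5 non-touching worms per 512×512 scene.

**What passing on this condition shows.** The synthetic scenes exercise the
full label-generation, curation and evaluation machinery with exactly known
ground truth. They do not contain touching/coiled worms, debris, plate
edges, condensation, or focus gradients; detector performance here is an
internal consistency bar (AP@0.5 ≥ 0.9), not a claim about real-plate
accuracy.

## Augmentation conventions

HSV jitter draws per-image multiplicative gains in `[1−g, 1+g]` per channel
(hue wraps modulo 1; grayscale degrades to a value gain). Geometric
augmentation composes horizontal flip, uniform scale in `[1−s, 1+s]` about
the image center and translation up to ±t per dimension; boxes are mapped
with the transform, clipped, and dropped below 8 px² visible area. The
mosaic split point is uniform in the central 50% of each dimension; sources
are resized to their tiles and labels remapped with the same floor.
Letterbox resize is aspect-preserving with symmetric padding (pad value =
image median, avoiding artificial high-contrast borders) to a square whose
side must be a multiple of 32; its transform record inverts boxes exactly.
Defaults (HSV 0.015/0.7/0.4, translate 0.1, scale 0.5, flip 0.5, mosaic
1.0) follow single-stage-detector training convention.

## Baseline detector

Background flattening (Gaussian, σ = `flatten_kernel_px`, default 31 —
about 3× the worm width so worms don't leak into the background estimate),
polarity resolved automatically from the sign of the residual's third
moment, Otsu threshold on the non-negative residual with a 0.05 floor (so
pure-noise images yield nothing), 8-connected components, area window, and
an elongation filter (major/minor second-moment axis ratio). The default
elongation floor of 2.0 suppresses round speckle; the easy-condition
profile (`EASY_DETECTOR`) lowers it to 1.1 because strongly undulating
worms can have axis ratios well below 2 and the easy condition has no
speckle to reject. Confidence is the component's mean residual normalized
by the image's maximum residual; the optional cap keeps the top-confidence
boxes — the mechanism the self-labeling procedure relies on.

## Self-labeling

Images are grouped by expected worm count; inference runs with
max-detections = expected count, making overcounting structurally
impossible; an image is kept iff detected == expected, else logically
deleted (reason recorded: `zero-detections` or `undercount` — no files are
removed, for auditability). Review is human-in-the-loop by design: the
module defines the accept/reject decision contract and validates that
decisions reference only kept images; accepted detections are re-emitted as
confidence-stripped label files. Ties at the confidence cap break by
confidence then emit order, deterministically. Time savings are reported at
one decimal as `worms × seconds_per_worm / 3600` with the conventional 5 s
per worm.

## Evaluation

Matching is PASCAL-VOC greedy: detections in descending confidence (ties by
file order), each taking the unmatched ground truth of highest IoU ≥ 0.5
(ties by first ground truth). Precision and recall use the 0-when-undefined
convention with an explicit degenerate flag rather than an exception, for
batch robustness. AP integrates the exact right-max precision envelope over
recall (all-points); a 101-point interpolated variant is provided for
comparability with common detector tooling — the two agree to within a few
hundredths on dense curves. Dataset-level evaluation matches per image but
pools TP/FP flags in global confidence order into one PR curve; headline P
and R are taken at the end of the ranked list (every emitted detection
counted). The full PR curve is exposed so any operating point can be read
off.

## Replicate statistics

With three replicates per training condition, normality is checked with the
exact n = 3 Shapiro–Wilk form `W = ½(x₍₃₎ − x₍₁₎)² / Σ(xᵢ − x̄)²`,
`p = (6/π)(asin√W − asin√¾)` (W = 1 and p = 1 for an equally spaced
triple); the general-n path delegates to scipy's Royston approximation.
Method comparisons use the **paired**, **two-sided** Student's t-test with
replicates paired by index (df = 2 for triples; for df = 2 the two-sided p
has the closed form `1 − |t|/√(t² + 2)`, used as an independent oracle in
the tests). The paired variant is the package's reading of how such
triplicate comparisons are computed — it is the variant whose p-values
match the packaged reference table's published summary, where unpaired
variants do not. Zero difference variance raises rather than returning an
infinite statistic. Strain-change robustness is summarized as the relative
drop `100(AP_ref − AP_new)/AP_ref`.

## Determinism and problem sizes

Every pipeline is a pure function of (config, root seed): per-image streams
are `SeedSequence([seed, index])`, so any image regenerates in isolation,
and the demo's JSON summary is byte-identical across runs with the same
seed. The reference problem sizes — 200 scenes for evaluation properties
and the end-to-end bar, a 100-image pool for self-labeling, 500 draws for
the self-intersection property — were chosen to give stable statistics
while keeping the full suite around a minute and a half on one CPU.

## Known limitations

- Single sinusoidal undulation mode: no coiling, omega turns, or
  self-overlap; the simplicity check enforces this rather than modeling it.
- No touching or aggregated worms (overlap budget defaults to 0); splitting
  aggregates is explicitly out of scope.
- The procedural appearance model does not attempt photorealism and is not
  benchmarked against real datasets; it exists to exercise the pipeline
  with exact ground truth.
- The classical detector is a pipeline test vehicle, not a competitive
  worm detector; its accuracy claims are restricted to the easy synthetic
  condition.
- Mosaic and geometric augmentation propagate boxes, not masks; mask-level
  labels do not survive resampling augmentation.
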