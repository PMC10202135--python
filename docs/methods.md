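# Methods

## The simulation model

### Plant development and architecture

Wheat seedling development follows the Haun scale: the number of fully
expanded main-stem leaves. We model it as linear in cumulative thermal
time `T` (°C·day since emergence) with slope `1/P`, where `P` is the
phyllochron (°C·day per leaf): `H = T / P`. A plant at stage `H` carries
`⌈H⌉` leaves — `⌊H⌋` fully expanded plus, when `H` is fractional, one
youngest leaf expanded to the fraction `H − ⌊H⌋`. A partially expanded
leaf is modelled as the full leaf's midrib uniformly scaled so its arc
length equals `expansion × nominal length`; its maximum blade width scales
by the same fraction.

Each leaf's midrib is a quadratic Bézier in the vertical plane of the
leaf's azimuth: it leaves the insertion point at `inclination_angle` from
vertical and its end tangent is rotated a further `curvature × 90°`
outward (droop). The curve is sampled at uniform arc length (13 vertices)
and rescaled so the polyline arc length is exact. The blade is swept
horizontally across the midrib with a width profile that starts at 0.7 ×
maximum width at insertion (the blade emerges from a sheath at near-full
width), peaks at 30% of the midrib, and tapers **concavely** (exponent
0.4) to exactly zero at the tip. The concave taper matters: with a linear
taper the final ~5 mm of blade is narrower than one pixel at field ground
sampling distances (0.1–0.5 mm/px), making the very feature to be detected
optically invisible; real blade tips keep near-millimetre width until
close to the point. Successive leaves insert 12 mm higher on the
pseudostem (`pseudostem_rise`), as in real grass seedlings — this is what
lets the emerging youngest leaf stand above, rather than under, the older
blades. Azimuths alternate by 180° with Gaussian jitter
(`phyllotaxy_jitter`, default sd 15°). Tillers (off by default, since the
seedling window of interest ends where tillering begins) are smaller
secondary shoots sharing the base.

Default parameter ranges shipped for Latin hypercube sampling
(`DEFAULT_PARAMETER_RANGES`): phyllochron 80–120 °C·day, maximum leaf
length 40–200 mm, maximum width 3–10 mm, inclination 20–70°, curvature
0–0.8, sowing density 100–400 plants/m², thermal time 80–420 °C·day
(Haun ≈ 1–4). Latin hypercube sampling is delegated to
`scipy.stats.qmc.LatinHypercube`; its defining property (each marginal
occupies all `n` strata) is asserted by brute-force stratum counting in
the tests.

### Canopy layout

Plant count is `round(density × plot area)`; rows run along x, spaced
`row_spacing` in y, plants evenly spread per row with Gaussian positional
jitter (default sd 10 mm), clipped to the plot. All randomness flows
through one `numpy` generator per scene, so scenes are bit-reproducible.

### Rendering

A z-buffer rasterizer with an exact pinhole camera. Conventions: world
units mm, z up, soil at z = 0; pixel centers at integer coordinates,
origin top-left, half-open image domain. Depth is the Euclidean distance
from the optical center along each pixel's view ray; per-triangle depth
comes from exact ray/plane intersection, so depth buffers are analytic,
not interpolated. The owner buffer records which leaf (or the soil) is
front-most per pixel. RGB is supersampled `aa_factor²` per pixel and
averaged; the depth/owner buffers are always computed at pixel centers so
they align with annotation geometry. Color is linear [0, 1] in memory;
gamma 2.2 is applied only at PNG write.

Shading is Lambertian with a diffuse/direct split:
`albedo × (k + (1 − k) · max(0, n·s) · lit)`, `k` the diffuse fraction,
`s` the unit sun vector, `lit` zeroed by hard cast shadows. Blades are
two-sided (normals flipped toward the camera). Shadows are computed either
by exact per-sample ray casting against the full triangle set
(`shadow_mode="ray"`) or, by default, an orthographic light-space depth
map (768 texels across the scene, depth bias two texels + 1 mm). The map
is the package's own speed/accuracy trade: on dataset-scale runs it is
orders of magnitude faster, and the test suite verifies it matches the ray
mode on >97% of pixels (differences are confined to shadow-edge texels).
With `diffuse_fraction = 1` the image is shadow-independent bit-for-bit.

Textures are procedural by default so nothing is downloaded: leaves get
longitudinal vein bands over a base green, soil gets multi-octave value
noise over a base brown, both seeded; user-supplied images override them
(leaf images sampled in blade (u, v) coordinates, soil images in world mm
at `texture_scale`).

### Automatic annotation

Every leaf mesh carries its exact 3D tip. A tip is projected through the
render camera and labelled **visible** when either (a) some pixel in the
3 × 3 window around its projection is owned by that leaf, or (b) the
z-buffer at the projection pixel itself is no closer than the tip depth
minus 2 mm (nothing materially occludes it there). The window absorbs the
sub-pixel thinness of the blade tip; the depth clause is deliberately
single-pixel, because neighbouring pixels can legitimately see past an
occluder that hides the tip. This heuristic is validated against an
independent brute-force ray-cast (Möller–Trumbore, tip→camera, skipping
the first 2 mm to mirror the same tolerance): agreement is ≈99.3% of tips
over random 10-plant canopies, and the residual disagreements are
sub-pixel edge grazes.

Visible, in-frame tips receive fixed 12 × 12 px boxes. Frames are tiled by
a sliding window (default 1024 px tiles, 896 px stride, last window
clamped to abut the border); an annotation joins a tile iff its center
lies inside it, duplicated across overlaps (each tile is an independent
training sample). Datasets are written as PNG + COCO JSON + flat CSV + a
manifest that round-trips field-for-field. For externally translated
images (e.g. GAN-based appearance transfer that preserves leaf
boundaries), `attach_annotations_to_translated` re-points the manifest
after checking per-file existence and exact dimensions — labels are never
rescaled.

## The classical baseline detector

The deep detectors this pipeline is meant to serve are deliberately out of
scope; the baseline exists so the loop closes without any learned
component, and it fixes the detector plug-in contract (image in, scored
12 × 12 boxes out, serialized in the annotation dialect).

1. **Vegetation mask**: excess-green `ExG = 2G − R − B`, Otsu threshold,
   radius-1 opening. Equivariant to common channel scaling.
2. **Skeleton endpoints**: endpoints are skeleton pixels with exactly one
   8-connected neighbour; spurs shorter than `min_branch` (5 px) are
   dropped.
3. **Tip classification**: with a known GSD, an endpoint is a tip iff its
   local blade half-width (distance transform × GSD) is below
   `tip_max_width_mm` (1.0 mm) — blades taper to a sub-millimetre point
   while bases and truncated ends stay wider. Without a GSD the relative
   rule applies: endpoint distance-transform below `taper_ratio` (0.6) of
   the branch median. Candidates must also be free-standing: mask pixels
   on a 6 px ring around the tip may occupy at most 45% of the ring
   (bases and truncations are attached to wider structure and fail).
4. **Sub-pixel refinement**: skeletonization and opening recede 10–25 px
   from a thin tip, far more than the ~3 px the IoU > 0.5 match tolerates.
   A greedy march (0.75 px steps, up to ±35° bends) follows the blade
   outward over a relaxed ExG support (0.3 × the Otsu threshold — mixed
   leaf/soil pixels past the hard mask still trace the blade), then snaps
   to the extreme mask pixel along the approach direction plus half a
   pixel.

All thresholds are exposed in `DetectorConfig`. The defaults were fixed on
generated clean fixtures (single plants, Haun 1–2, 0.3 mm/px, diffuse
light) where the detector reaches precision/recall ≈ 0.95; it is *not*
expected to survive dense canopies, oblique crossing blades, or coarse
GSDs — that degradation is itself one of the measured results.

## Evaluation metrics

Greedy one-to-one matching in decreasing IoU order at threshold 0.5;
matched pairs are TP, unmatched detections FP, unmatched truths FN;
`p = TP/(TP+FP)`, `r = TP/(TP+FN)`. Counting quality uses per-image
counts: `MAE = mean |y − ŷ|`, `RMSE = sqrt(mean (y − ŷ)²)`, and the
standard coefficient of determination
`R² = 1 − Σ(y−ŷ)² / Σ(y−ȳ)²`. Undefined cases (zero denominators, zero
variance) are reported as `None`, never raised. Per-stage reports bin
images by `⌊H⌋` clamped to {1..4}. Greedy matching can in principle differ
from optimal assignment; the tests check equality on decisive
configurations and the divergence is accepted as the price of determinism.

## Domain-gap measure

`d(A, B) = ‖x̄ − ȳ‖₂` between dataset centroids after per-dimension
standardization over the pooled features — a single scalar, with an
alternative computed on a joint 2-D t-SNE embedding (perplexity 30,
clamped below (n−1)/3, fixed seed, KL divergence reported). The default
extractor is handcrafted and GPU-free: 3 × 16-bin color histograms, an
8-bin gradient-orientation histogram, and 5 texture-energy statistics
(d = 61). Any callable image → fixed-length vector can replace it (e.g.
features exported from a detection network). Which feature space a
published gap number lives in is often ambiguous; providing both spaces
makes the choice explicit.

## Experiment drivers

**Realism ablation** — factors LT (leaf texture), SB (soil background),
LC (light conditions). Off = pinned to the standard defaults (flat
standard leaf color, flat standard soil, fully diffuse shadowless light);
on = varied per image (banded leaf texture, seeded noisy soil, random sun
geometry with diffuse fraction 0.2–1.0 and cast shadows). All 7 non-empty
combinations are run; each row reports the baseline detector's counting
metrics and the feature-space distance to a reference dataset generated
with all factors on under an independent seed stream (standing in for a
real-image target domain).

**Resolution sweep** — the same scenes re-rendered over a GSD grid
(default 0.1–2.0 mm/px in 0.1 steps) purely by raising the camera; scene
geometry and labels are identical across resolutions, so metric drift is
attributable to resolution alone.

## What the synthetic data does and does not show

The generator emulates the structural drivers of the detection problem:
development stage, occlusion from canopy density and leaf crossing, tip
thinness relative to GSD, illumination and shadow variation, and texture
contrast between canopy and soil. It does **not** emulate specular leaf
optics, senescence or disease coloration, wind blur, lens distortion, soil
litter/stones, or the full morphological diversity of field cultivars.
Passing tests therefore demonstrate internal consistency of the
simulate→label→detect→evaluate loop and qualitative orderings (resolution
degradation, lighting-driven domain shift), not field-level accuracy of
any detector.

## Numerical choices and degenerate inputs

- Visibility tolerance 2 mm; occluders nearer than that to a tip count as
  grazes for both the labelling rule and the validating ray oracle.
- Zero-area triangles are skipped with a warning count; constant-ExG
  images yield an empty mask with a warning; empty plots yield a valid
  empty scene with a warning.
- t-SNE on zero-variance feature matrices returns a collapsed embedding
  instead of propagating NaNs from the initializer.
- Matching ties are broken by (−IoU, detection index, truth index) for
  determinism; detection results are invariant to input order.
- Standardization guards zero-variance dimensions (std set to 1).
- Seeds: every study derives child seeds from one master seed via
  `numpy.random.SeedSequence`; written PNGs are byte-deterministic.

## Validation studies (scripts/acceptance.py)

Problem sizes, chosen to exercise each property while keeping single-CPU
runtimes in minutes: 150 random canopies (≤10 plants, 256 px) for the
visibility-oracle agreement; 100 single-plant seeds (Haun ≤ 2.5, chosen so
unoccludedness holds by construction) for tip-count conservation; 30
clean single-plant images at 0.3 mm/px for detector precision/recall; 20
scenes at 0.3 vs 2.0 mm/px for resolution degradation; 10 repetitions of
20-image datasets (200 mm plots, 128 px) for the gap ordering; plus exact
determinism, round-trip, and stratification checks.

## Known limitations

- The rasterizer has no specularity, translucency, soft shadows, sky
  model, or lens distortion; realism factors are the three manipulated
  ones (texture, background, illumination geometry/split).
- The plant model covers main-stem seedling architecture (Haun ≤ ~5);
  sheath/internode dynamics, senescence, and root systems are out of
  scope, and tillers are geometric stand-ins.
- The classical detector is a pipeline-exercising baseline, not a
  competitive field detector.
- The published parameter space of the full wheat-architecture literature
  is not reconstructed; the shipped ranges are editable defaults.
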