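# tipsim

Procedural simulation of wheat seedling canopies with automatically
annotated leaf-tip labels, plus the evaluation stack for leaf-tip
detection and counting.

Counting leaves on young wheat plants is a standard way to track crop
development (the Haun scale: number of fully expanded main-stem leaves),
but manual field counts are slow and noisy. A practical alternative is to
detect **leaf tips** in RGB images and count them. Training and evaluating
such detectors needs large annotated datasets — which a plant simulator can
produce for free, because the 3D position of every leaf tip is known
exactly.

`tipsim` provides that loop end-to-end, at desk scale and with zero
external data:

- **plant_model** — parametric 3D wheat seedlings. Development is driven by
  thermal time *T* and the phyllochron *P* through the Haun stage
  *H = T / P*; a plant carries ⌈H⌉ leaves, the youngest expanded to the
  fractional part of *H*. Leaves are triangle meshes swept around a
  quadratic Bézier midrib (insertion angle, droop). Canopies place plants
  on jittered rows at a sowing density; parameter space is explored with
  Latin hypercube sampling.
- **renderer** — a z-buffer rasterizer with pinhole projection, per-pixel
  depth and primitive-owner buffers, Lambertian shading with a
  diffuse/direct split, hard cast shadows (light-space depth map, or exact
  ray casting), and procedural or user-supplied leaf/soil textures. The
  camera can be placed by ground sampling distance (GSD):
  `height = GSD · W · cos θ / (2 tan(fov/2))`.
- **annotation** — projects every leaf tip, decides visibility from the
  depth/owner buffers, emits 12 × 12 px boxes, tiles full frames into
  training-size subimages, and reads/writes COCO JSON + CSV + a lossless
  manifest. Labels can be re-attached to externally translated
  (appearance-transferred) copies of the images.
- **detector** — a fully classical baseline (excess-green index → Otsu →
  skeleton endpoints → taper/isolation tests) that exercises the whole
  pipeline and defines the plug-in contract for external detectors.
- **evaluation** — greedy IoU > 0.5 matching (precision, recall) and
  per-image counting metrics (MAE, RMSE, R²), with per-Haun-stage bins.
- **gap / experiments** — a scalar domain-gap measure (Euclidean distance
  between dataset centroids on standardized features, with a joint t-SNE
  embedding for inspection) and drivers for two ablations: the
  leaf-texture / soil-background / light-condition realism grid, and a
  0.1–2.0 mm/px spatial-resolution sweep.

## Worked example

```python
import numpy as np
from tipsim import (FieldConfig, PlantParams, LightConfig, build_canopy,
                    camera_for_gsd, render_scene, annotate_tips, detect,
                    match_detections, precision_recall)

field = FieldConfig(plot_width=200, plot_depth=200, row_spacing=100,
                    sowing_density=150, thermal_time=220, seed=5)
scene = build_canopy(field, PlantParams())
cam = camera_for_gsd(0.5, view_zenith=45, sensor_width_px=512,
                     look_at=(100, 100, 0))
frame = render_scene(scene, cam, LightConfig(diffuse_fraction=0.6))
labels = annotate_tips(scene, frame)
dets = detect(frame.rgb, gsd=0.5)
counts, _ = match_detections([d.box for d in dets], [a.box for a in labels])
print(f"{scene.leaf_count()} leaves, {len(labels)} visible tips, "
      f"{len(dets)} detections")
print("precision/recall:", precision_recall(counts))
```

Output:

```
18 leaves, 16 visible tips, 19 detections
precision/recall: (0.5263157894736842, 0.625)
```

18 simulated leaves, of which 16 tips are visible from this oblique camera
(the rest hide behind other blades); the classical detector proposes 19
candidates of which 10 match a true tip under the IoU > 0.5 criterion.
On a textured, obliquely viewed canopy with partial shading the classical
baseline is deliberately modest — on the clean nadir fixtures used for
validation it reaches precision/recall ≈ 0.95 (see
`scripts/acceptance.py` below), and the gap between those two settings is
exactly the kind of effect the ablation drivers measure.

The same workflow is available from the shell:

```bash
tipsim generate --n-scenes 20 --seed 1 --out sim_ds
tipsim detect sim_ds --out dets.json
tipsim evaluate sim_ds dets.json --out-json report.json
tipsim gap sim_ds other_ds --out-json gap.json
tipsim ablate-realism --n-images 20 --out-csv ablation.csv
tipsim sweep-resolution --n-scenes 20 --out-csv sweep.csv
```

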