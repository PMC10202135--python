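"""Self-validation studies: oracle cross-checks of the simulation pipeline.

Each function here runs one end-to-end property study on freshly generated
scenes and reports a scalar outcome.  The studies cross-check independent
routes through the code base — e.g. z-buffer visibility versus direct
ray-triangle casting, or fast rendering versus a detector's view of it —
and are what the repository's acceptance checks and benchmark script call.

All studies are deterministic given their seed and sized to run on one CPU
in seconds to a couple of minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import annotation as ann
from . import plant_model as pm
from . import renderer as rnd
from .detector import detect
from .evaluation import EvalCounts, match_detections, precision_recall
from .experiments import _light_for, run_resolution_sweep
from .gap import dataset_distance, extract_features

__all__ = [
    "ray_cast_tip_visible",
    "visibility_agreement",
    "tip_count_conservation",
    "detector_precision_recall",
    "resolution_mae_pair",
    "gap_sanity_wins",
    "generation_is_deterministic",
    "dataset_roundtrip_ok",
    "lhs_stratification_ok",
]

#: Matches the annotation depth tolerance: occluders closer than this to the
#: tip are grazes, not occlusions, for both the z-buffer rule and the oracle.
RAY_GUARD_MM = 2.0


def ray_cast_tip_visible(tip: np.ndarray, cam_pos: np.ndarray,
                         tris: np.ndarray) -> bool:
    """Brute-force visibility: does any triangle block the tip->camera ray?

    Moller-Trumbore over the full triangle set; the first ``RAY_GUARD_MM``
    of the ray is skipped so the tip's own blade surface (and sub-tolerance
    grazes) do not count as occluders.  Independent of the rasterizer.
    """
    d = cam_pos - tip
    L = float(np.linalg.norm(d))
    d = d / L
    orig = tip + d * RAY_GUARD_MM
    v0 = tris[:, 0]
    e1 = tris[:, 1] - v0
    e2 = tris[:, 2] - v0
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-12
    safe = np.where(ok, det, 1.0)
    tvec = orig - v0
    u = np.einsum("ij,ij->i", tvec, pvec) / safe
    qvec = np.cross(tvec, e1)
    v = (qvec @ d) / safe
    t = np.einsum("ij,ij->i", qvec, e2) / safe
    hit = ok & (u >= 0) & (u <= 1) & (v >= 0) & (u + v <= 1) & (t > 1e-6) & (t < L - 1.0)
    return not bool(hit.any())


def _random_canopy(seed: int) -> pm.CanopyScene:
    gen = np.random.default_rng(seed)
    n = int(gen.integers(3, 11))
    fc = pm.FieldConfig(
        sowing_density=float(n / 0.04), plot_width=200.0, plot_depth=200.0,
        row_spacing=100.0, thermal_time=float(gen.uniform(120.0, 380.0)),
        seed=seed,
    )
    return pm.build_canopy(fc, pm.PlantParams())


def visibility_agreement(n_scenes: int = 150, seed: int = 0) -> tuple[float, int]:
    """Fraction of in-frame tips whose z-buffer visibility flag matches the
    ray-cast oracle, over random canopies of up to 10 plants at 256 px."""
    ss = np.random.SeedSequence(seed).generate_state(n_scenes) % 2**31
    agree = total = 0
    for s in ss:
        scene = _random_canopy(int(s))
        gen = np.random.default_rng(int(s) + 1)
        cam = rnd.camera_for_gsd(
            1.0, view_zenith=float(gen.uniform(0.0, 50.0)),
            sensor_width_px=256, look_at=(100.0, 100.0, 0.0),
        )
        frame = rnd.render_scene(scene, cam, rnd.LightConfig(), aa_factor=1)
        keys = {(a.plant_id, a.leaf_rank) for a in ann.annotate_tips(scene, frame)}
        tris, _, _ = scene.triangle_arrays()
        W, H = cam.sensor_width_px, cam.sensor_height_px
        for pid, leaf in scene.all_leaves():
            try:
                u, v, _ = rnd.project_point(leaf.tip_point, cam)
            except rnd.BehindCameraError:
                continue
            if not (-0.5 <= u < W - 0.5 and -0.5 <= v < H - 0.5):
                continue
            total += 1
            agree += ((pid, leaf.rank) in keys) == ray_cast_tip_visible(
                leaf.tip_point, cam.position, tris
            )
    return (agree / total if total else 1.0), total


def tip_count_conservation(n_seeds: int = 100, seed: int = 0) -> tuple[int, int]:
    """Count seeds for which a single unoccluded in-frame plant yields
    exactly one annotation per leaf.

    Plants are held below Haun stage 2.5 so the expanding third leaf stays
    too short for any blade to arch over another blade's tip: every tip is
    geometrically unoccluded at the nadir view used.
    """
    ss = np.random.SeedSequence([seed, 1]).generate_state(n_seeds) % 2**31
    ok = 0
    for s in ss:
        gen = np.random.default_rng(int(s))
        tt = float(gen.uniform(50.0, 250.0))
        base = np.array([gen.uniform(-30, 30), gen.uniform(-30, 30), 0.0])
        plant = pm.build_plant(tt, pm.PlantParams(), gen, base)
        scene = pm.CanopyScene(plants=[plant],
                               soil_extent=(-160.0, -160.0, 160.0, 160.0))
        cam = rnd.camera_for_gsd(1.25, view_zenith=0.0, sensor_width_px=256,
                                 look_at=(0.0, 0.0, 0.0))
        frame = rnd.render_scene(scene, cam, rnd.LightConfig(), aa_factor=1)
        ok += len(ann.annotate_tips(scene, frame)) == len(plant.leaves)
    return ok, n_seeds


def detector_precision_recall(
    n_images: int = 30, seed: int = 0
) -> tuple[float, float, EvalCounts]:
    """Classical detector on clean sparse fixtures: single plants below Haun
    stage 2 at 0.3 mm/px, flat textures, fully diffuse light."""
    ss = np.random.SeedSequence([seed, 2]).generate_state(n_images) % 2**31
    total = EvalCounts()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in ss:
            gen = np.random.default_rng(int(s))
            tt = float(gen.uniform(100.0, 200.0))
            base = np.array([gen.uniform(-30, 30), gen.uniform(-30, 30), 0.0])
            plant = pm.build_plant(tt, pm.PlantParams(), gen, base)
            scene = pm.CanopyScene(plants=[plant],
                                   soil_extent=(-115.0, -115.0, 115.0, 115.0))
            cam = rnd.camera_for_gsd(0.3, view_zenith=0.0, sensor_width_px=768,
                                     look_at=(0.0, 0.0, 0.0))
            frame = rnd.render_scene(
                scene, cam, rnd.LightConfig(diffuse_fraction=1.0, cast_shadows=False),
                rnd.TextureSet(leaf_texture="leaf_flat", soil_texture="soil_flat"),
                aa_factor=2,
            )
            gts = ann.annotate_tips(scene, frame)
            dets = detect(frame.rgb, 0.3)
            counts, _ = match_detections([d.box for d in dets],
                                         [a.box for a in gts])
            total = total + counts
    p, r = precision_recall(total)
    return (p if p is not None else 0.0), (r if r is not None else 0.0), total


def resolution_mae_pair(
    n_scenes: int = 20, seed: int = 0, gsd_fine: float = 0.3, gsd_coarse: float = 2.0
) -> tuple[float, float]:
    """Counting MAE of the classical detector at a fine and a coarse ground
    sampling distance over the same scenes (150 mm plot fully in frame)."""
    gen = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    seeds = [int(s) for s in gen.integers(0, 2**31 - 1, size=n_scenes)]
    field = pm.FieldConfig(plot_width=150.0, plot_depth=150.0, row_spacing=75.0,
                           sowing_density=200.0, thermal_time=250.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = run_resolution_sweep(
            scene_seeds=seeds, gsd_list=(gsd_fine, gsd_coarse),
            sensor_px=512, field_template=field,
        )
    mae = dict(zip(table["gsd"], table["mae"]))
    return float(mae[gsd_fine]), float(mae[gsd_coarse])


def gap_sanity_wins(
    reps: int = 10, n_images: int = 20, seed: int = 0
) -> tuple[int, list[tuple[float, float]]]:
    """Repetitions in which two same-configuration datasets (different
    seeds) are closer in feature space than a lighting-varied dataset."""
    cam = rnd.camera_for_gsd(1.5, view_zenith=45.0, sensor_width_px=128,
                             look_at=(100.0, 100.0, 0.0))
    field = pm.FieldConfig(plot_width=200.0, plot_depth=200.0,
                           row_spacing=100.0, sowing_density=200.0)
    flat = rnd.LightConfig(diffuse_fraction=1.0, cast_shadows=False)
    varied = _light_for(frozenset({"LC"}))
    base_seeds = np.random.SeedSequence([seed, 4]).generate_state(3 * reps) % 2**31
    wins = 0
    pairs: list[tuple[float, float]] = []
    for rep in range(reps):
        sa, sb, sc = (int(s) for s in base_seeds[3 * rep : 3 * rep + 3])
        a = ann.generate_dataset(n_images, field_template=field, camera=cam,
                                 light=flat, seed=sa)
        b = ann.generate_dataset(n_images, field_template=field, camera=cam,
                                 light=flat, seed=sb)
        c = ann.generate_dataset(n_images, field_template=field, camera=cam,
                                 light=varied, seed=sc)
        fa = extract_features([r.image for r in a.records])
        fb = extract_features([r.image for r in b.records])
        fc = extract_features([r.image for r in c.records])
        d_same = dataset_distance(fa, fb)
        d_light = dataset_distance(fa, fc)
        pairs.append((d_same, d_light))
        wins += d_same < d_light
    return wins, pairs


def _small_dataset(seed: int) -> ann.DatasetManifest:
    return ann.generate_dataset(
        2,
        camera=rnd.camera_for_gsd(1.5, sensor_width_px=64),
        field_template=pm.FieldConfig(plot_width=150.0, plot_depth=150.0,
                                      row_spacing=75.0),
        seed=seed,
    )


def generation_is_deterministic(workdir, seed: int = 0) -> bool:
    """Two runs with the same seed write byte-identical PNGs and metadata."""
    workdir = Path(workdir)
    dirs = (workdir / "run_a", workdir / "run_b")
    for d in dirs:
        ann.write_dataset(_small_dataset(seed), d)
    files_a = sorted(p for p in dirs[0].rglob("*") if p.is_file())
    for fa in files_a:
        fb = dirs[1] / fa.relative_to(dirs[0])
        if not fb.exists() or fa.read_bytes() != fb.read_bytes():
            return False
    return True


def dataset_roundtrip_ok(workdir, seed: int = 0) -> bool:
    """write -> read preserves every field, including after re-attaching the
    labels to identity-copied (trivially 'translated') images."""
    workdir = Path(workdir)
    manifest = _small_dataset(seed)
    out = workdir / "ds"
    ann.write_dataset(manifest, out)
    back = ann.read_dataset(out)
    if back.to_dict() != manifest.to_dict():
        return False
    tdir = workdir / "translated"
    tdir.mkdir(exist_ok=True)
    for rec in back.records:
        (tdir / rec.image_path).write_bytes(
            (out / "images" / rec.image_path).read_bytes()
        )
    attached = ann.attach_annotations_to_translated(back, tdir)
    return all(
        a.annotations == b.annotations and (a.width, a.height) == (b.width, b.height)
        for a, b in zip(back.records, attached.records)
    )


def lhs_stratification_ok(seed: int = 0, ns=(2, 8, 32)) -> bool:
    """Latin hypercube marginals occupy all n strata for every parameter."""
    ranges = dict(pm.DEFAULT_PARAMETER_RANGES)
    for n in ns:
        sets = pm.sample_parameter_sets(n, ranges, seed=seed)
        for name, (lo, hi) in ranges.items():
            idx = np.floor(
                (np.array([s[name] for s in sets]) - lo) / (hi - lo) * n
            ).astype(int)
            idx = np.clip(idx, 0, n - 1)
            if sorted(idx) != list(range(n)):
                return False
    return True
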