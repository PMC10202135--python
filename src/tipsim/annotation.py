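"""Automatic leaf-tip labelling, frame tiling, and dataset I/O.

Every leaf in a canopy scene carries an exact 3D tip point, so ground-truth
labels come for free: the tip is projected through the same camera used for
rendering and declared visible when the depth/owner buffers show it to be
front-most.  Visible tips receive fixed 12 x 12 px boxes — small enough to
localize the tip, large enough for an IoU > 0.5 match criterion to be
meaningful.

Full-resolution frames are divided into training-size subimages by a
sliding window with overlap; annotations follow their tile by center
membership.  Datasets are written as PNG images plus COCO-format JSON, a
flat CSV, and a manifest that round-trips losslessly.  For externally
translated (appearance-transferred) copies of the images, labels are
re-attached unchanged, since geometry-preserving translation keeps tip
positions valid.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from . import plant_model as pm
from . import renderer as rnd
from .renderer import BehindCameraError, CameraConfig, LightConfig, RenderedFrame, TextureSet

__all__ = [
    "TipAnnotation",
    "ImageRecord",
    "DatasetManifest",
    "annotate_tips",
    "tile_with_annotations",
    "write_dataset",
    "read_dataset",
    "attach_annotations_to_translated",
    "generate_dataset",
    "DatasetIOError",
]

BOX_SIZE = 12  # px, side of every tip bounding box
FORMAT_VERSION = "1"


class DatasetIOError(RuntimeError):
    """Malformed or inconsistent dataset files; message names the record."""


@dataclass(frozen=True)
class TipAnnotation:
    """One leaf-tip label in image space.

    ``box`` is (x, y, w, h) with w = h = 12 centered on the sub-pixel tip
    projection, unclipped (clipping to image bounds happens at write time).
    ``depth`` is the tip's distance from the camera in mm.
    """

    center_u: float
    center_v: float
    visible: bool
    plant_id: int
    leaf_rank: int
    depth: float

    @property
    def box(self) -> tuple[float, float, float, float]:
        return (self.center_u - BOX_SIZE / 2, self.center_v - BOX_SIZE / 2,
                float(BOX_SIZE), float(BOX_SIZE))

    def to_dict(self) -> dict:
        return {
            "center_u": self.center_u,
            "center_v": self.center_v,
            "visible": self.visible,
            "plant_id": self.plant_id,
            "leaf_rank": self.leaf_rank,
            "depth": self.depth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TipAnnotation":
        return cls(**d)


@dataclass
class ImageRecord:
    """One image with its tip annotations and provenance.

    ``image`` holds the pixel array when the record was produced in this
    process; it is not serialized (the PNG on disk is authoritative) and is
    excluded from equality.
    """

    image_path: str
    width: int
    height: int
    gsd: float
    haun_stage: float
    annotations: list[TipAnnotation]
    provenance: dict = field(default_factory=dict)
    image: np.ndarray | None = field(default=None, compare=False, repr=False)

    def to_dict(self) -> dict:
        return {
            "image_path": self.image_path,
            "width": self.width,
            "height": self.height,
            "gsd": self.gsd,
            "haun_stage": self.haun_stage,
            "annotations": [a.to_dict() for a in self.annotations],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImageRecord":
        d = dict(d)
        d["annotations"] = [TipAnnotation.from_dict(a) for a in d["annotations"]]
        return cls(**d)


@dataclass
class DatasetManifest:
    """All records of a generated dataset plus the generating configuration."""

    records: list[ImageRecord]
    config: dict = field(default_factory=dict)
    version: str = FORMAT_VERSION
    master_seed: int = 0

    def total_annotations(self) -> int:
        return sum(len(r.annotations) for r in self.records)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "master_seed": self.master_seed,
            "config": self.config,
            "records": [r.to_dict() for r in self.records],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetManifest":
        return cls(
            records=[ImageRecord.from_dict(r) for r in d["records"]],
            config=d.get("config", {}),
            version=d.get("version", FORMAT_VERSION),
            master_seed=d.get("master_seed", 0),
        )


def annotate_tips(
    scene: pm.CanopyScene,
    frame: RenderedFrame,
    depth_tolerance_mm: float = 2.0,
    window: int = 1,
) -> list[TipAnnotation]:
    """Place a 12 x 12 px label on every visible, in-frame leaf tip.

    Each tip is projected through the frame's camera.  It counts as visible
    when either some pixel in a (2*window+1)^2 neighbourhood of its
    projection is owned by that leaf, or the z-buffer at the projection
    pixel itself is no closer than the tip depth minus
    ``depth_tolerance_mm`` (nothing occludes the tip there).  The owner
    window and the depth tolerance absorb the sub-pixel thinness of the
    blade tip, which a strict single-pixel z-test would frequently miss;
    the depth clause stays single-pixel because neighbouring pixels can
    legitimately see past an occluder that hides the tip.
    """
    cam = frame.camera
    W, H = cam.sensor_width_px, cam.sensor_height_px
    out: list[TipAnnotation] = []
    leaves = scene.all_leaves()
    any_projected = False
    for idx, (pid, leaf) in enumerate(leaves):
        try:
            u, v, d = rnd.project_point(leaf.tip_point, cam)
        except BehindCameraError:
            continue
        if not (-0.5 <= u < W - 0.5 and -0.5 <= v < H - 0.5):
            continue
        any_projected = True
        iu, iv = int(round(u)), int(round(v))
        j0, j1 = max(iv - window, 0), min(iv + window, H - 1)
        i0, i1 = max(iu - window, 0), min(iu + window, W - 1)
        own = frame.owner[j0 : j1 + 1, i0 : i1 + 1]
        visible = bool(
            np.any(own == idx + 1)
            or frame.depth[iv, iu] >= d - depth_tolerance_mm
        )
        if visible:
            out.append(
                TipAnnotation(
                    center_u=float(u),
                    center_v=float(v),
                    visible=True,
                    plant_id=pid,
                    leaf_rank=leaf.rank,
                    depth=float(d),
                )
            )
    if leaves and not any_projected:
        warnings.warn("no leaf tips project into the frame; camera/scene mismatch?")
    return out


def _window_starts(extent: int, tile: int, stride: int) -> list[int]:
    """Sliding-window start offsets; the last window abuts the far border."""
    if tile >= extent:
        return [0]
    n = int(np.ceil((extent - tile) / stride)) + 1
    return [min(i * stride, extent - tile) for i in range(n)]


def tile_with_annotations(
    record: ImageRecord, tile_size: int = 1024, stride: int = 896
) -> list[ImageRecord]:
    """Split a frame into overlapping tiles, reassigning annotations.

    An annotation belongs to a tile iff its center lies inside the tile's
    half-open pixel domain; in overlap regions it is duplicated into every
    containing tile (each tile is an independent training sample).
    """
    if stride <= 0 or stride > tile_size:
        raise ValueError("stride must satisfy 0 < stride <= tile_size")
    if tile_size > record.width or tile_size > record.height:
        warnings.warn("tile larger than image; emitting a single clamped tile")
    xs = _window_starts(record.width, tile_size, stride)
    ys = _window_starts(record.height, tile_size, stride)
    stem = Path(record.image_path).stem
    suffix = Path(record.image_path).suffix or ".png"
    tiles: list[ImageRecord] = []
    for j, y0 in enumerate(ys):
        for i, x0 in enumerate(xs):
            tw = min(tile_size, record.width)
            th = min(tile_size, record.height)
            anns = [
                replace(a, center_u=a.center_u - x0, center_v=a.center_v - y0)
                for a in record.annotations
                if x0 - 0.5 <= a.center_u < x0 + tw - 0.5
                and y0 - 0.5 <= a.center_v < y0 + th - 0.5
            ]
            img = None
            if record.image is not None:
                img = record.image[y0 : y0 + th, x0 : x0 + tw]
            tiles.append(
                ImageRecord(
                    image_path=f"{stem}_t{j}_{i}{suffix}",
                    width=tw,
                    height=th,
                    gsd=record.gsd,
                    haun_stage=record.haun_stage,
                    annotations=anns,
                    provenance={**record.provenance, "tile_origin": [x0, y0],
                                "parent": record.image_path},
                    image=img,
                )
            )
    return tiles


# ---------------------------------------------------------------------------
# dataset I/O


def _clip_box(box, width, height):
    x, y, w, h = box
    x0, y0 = max(x, 0.0), max(y, 0.0)
    x1, y1 = min(x + w, float(width)), min(y + h, float(height))
    return [x0, y0, max(x1 - x0, 0.0), max(y1 - y0, 0.0)]


def to_coco(manifest: DatasetManifest) -> dict:
    """COCO-format dict: one ``leaf_tip`` category, boxes clipped to bounds."""
    images, annotations = [], []
    ann_id = 1
    for img_id, rec in enumerate(manifest.records, start=1):
        images.append(
            {"id": img_id, "file_name": rec.image_path,
             "width": rec.width, "height": rec.height}
        )
        for a in rec.annotations:
            bbox = _clip_box(a.box, rec.width, rec.height)
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": 1,
                    "bbox": bbox,
                    "area": bbox[2] * bbox[3],
                    "iscrowd": 0,
                    "center": [a.center_u, a.center_v],
                    "plant_id": a.plant_id,
                    "leaf_rank": a.leaf_rank,
                }
            )
            ann_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "leaf_tip"}],
    }


def write_dataset(manifest: DatasetManifest, out_dir) -> dict[str, Path]:
    """Write PNGs, manifest.json, annotations.json (COCO) and annotations.csv."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for rec in manifest.records:
        dst = out / "images" / rec.image_path
        if rec.image is not None:
            Image.fromarray(rnd.to_uint8(rec.image)).save(dst)
        elif not dst.exists():
            src = Path(rec.image_path)
            if src.exists():
                dst.write_bytes(src.read_bytes())
            else:
                raise DatasetIOError(f"no pixel data for record {rec.image_path!r}")
    paths = {
        "manifest": out / "manifest.json",
        "coco": out / "annotations.json",
        "csv": out / "annotations.csv",
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1)
    with open(paths["coco"], "w") as fh:
        json.dump(to_coco(manifest), fh, indent=1)
    with open(paths["csv"], "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["image", "center_u", "center_v", "plant_id", "leaf_rank"])
        for rec in manifest.records:
            for a in rec.annotations:
                wr.writerow([rec.image_path, a.center_u, a.center_v,
                             a.plant_id, a.leaf_rank])
    return paths


def read_dataset(dataset_dir) -> DatasetManifest:
    """Reload a written dataset; inverse of :func:`write_dataset`."""
    path = Path(dataset_dir) / "manifest.json"
    if not path.exists():
        raise DatasetIOError(f"missing manifest.json under {dataset_dir}")
    try:
        with open(path) as fh:
            return DatasetManifest.from_dict(json.load(fh))
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise DatasetIOError(f"malformed manifest {path}: {exc}") from exc


def load_image(record: ImageRecord, dataset_dir) -> np.ndarray:
    """Load a record's PNG as a linear-light float array in [0, 1]."""
    p = Path(dataset_dir) / "images" / record.image_path
    arr = np.asarray(Image.open(p).convert("RGB"), dtype=float) / 255.0
    return arr**2.2


def attach_annotations_to_translated(
    manifest: DatasetManifest, translated_dir
) -> DatasetManifest:
    """Point the manifest at appearance-translated images, labels unchanged.

    Translation that preserves leaf boundaries preserves tip positions, so
    the automatically generated labels remain valid; only the image paths
    change.  Every record must have a same-named counterpart with identical
    pixel dimensions — annotations are never rescaled.
    """
    tdir = Path(translated_dir)
    errors = []
    new_records = []
    for rec in manifest.records:
        cand = tdir / rec.image_path
        if not cand.exists():
            errors.append(f"{rec.image_path}: missing in {tdir}")
            continue
        with Image.open(cand) as im:
            w, h = im.size
        if (w, h) != (rec.width, rec.height):
            errors.append(
                f"{rec.image_path}: dimensions {w}x{h} != {rec.width}x{rec.height}"
            )
            continue
        new_records.append(
            replace(rec, image=None,
                    provenance={**rec.provenance, "translated_from": rec.image_path})
        )
    if errors:
        raise DatasetIOError("translated dataset mismatch:\n" + "\n".join(errors))
    return DatasetManifest(
        records=new_records,
        config={**manifest.config, "translated_dir": str(tdir)},
        version=manifest.version,
        master_seed=manifest.master_seed,
    )


# ---------------------------------------------------------------------------
# end-to-end generation


def _resolve(cfg, rng):
    return cfg(rng) if callable(cfg) else cfg


def generate_dataset(
    n_scenes: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    field_template: pm.FieldConfig | None = None,
    camera: CameraConfig | None = None,
    light: LightConfig | object = None,
    textures: TextureSet | object = None,
    seed: int = 0,
    tile_size: int | None = None,
    stride: int = 896,
    aa_factor: int = 1,
    base_params: pm.PlantParams | None = None,
) -> DatasetManifest:
    """Sample -> build -> render -> annotate -> (optionally) tile.

    One Latin-hypercube parameter set and one frame per scene; ``light`` and
    ``textures`` may be callables ``rng -> config`` to vary illumination or
    texture across the dataset.  Fully deterministic given ``seed``.
    """
    ranges = ranges or pm.DEFAULT_PARAMETER_RANGES
    field_template = field_template or pm.FieldConfig()
    if camera is None:
        camera = rnd.camera_for_gsd(
            0.5, view_zenith=45.0, sensor_width_px=256,
            look_at=(field_template.plot_width / 2, field_template.plot_depth / 2, 0.0),
        )
    if light is None:
        light = LightConfig()
    if textures is None:
        textures = TextureSet()

    records: list[ImageRecord] = []
    if n_scenes > 0:
        samples = pm.sample_parameter_sets(n_scenes, ranges, seed)
        child_seeds = np.random.SeedSequence(seed).spawn(n_scenes)
        for i, (sample, ss) in enumerate(zip(samples, child_seeds)):
            rng = np.random.default_rng(ss)
            params = pm.params_from_sample(sample, base_params)
            fc = replace(
                field_template,
                sowing_density=sample.get("sowing_density", field_template.sowing_density),
                thermal_time=sample.get("thermal_time", field_template.thermal_time),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            scene = pm.build_canopy(fc, params, rng)
            li = _resolve(light, rng)
            tx = _resolve(textures, rng)
            frame = rnd.render_scene(scene, camera, li, tx, aa_factor=aa_factor)
            anns = annotate_tips(scene, frame)
            rec = ImageRecord(
                image_path=f"scene_{i:04d}.png",
                width=camera.sensor_width_px,
                height=camera.sensor_height_px,
                gsd=camera.gsd_center(),
                haun_stage=scene.metadata["mean_haun_stage"],
                annotations=anns,
                provenance={"scene_seed": fc.seed, "parameter_set": i,
                            "n_leaves": scene.leaf_count()},
                image=frame.rgb,
            )
            if tile_size:
                records.extend(tile_with_annotations(rec, tile_size, stride))
            else:
                records.append(rec)
    return DatasetManifest(
        records=records,
        config={"n_scenes": n_scenes, "ranges": {k: list(v) for k, v in ranges.items()},
                "tile_size": tile_size, "stride": stride},
        master_seed=seed,
    )
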