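"""Automatic tip labelling, tiling, dataset round-trips, label re-attachment."""

import shutil
from pathlib import Path

import numpy as np
import pytest

from tipsim import plant_model as pm
from tipsim import renderer as rnd
from tipsim.annotation import (
    BOX_SIZE,
    DatasetIOError,
    DatasetManifest,
    ImageRecord,
    TipAnnotation,
    annotate_tips,
    attach_annotations_to_translated,
    generate_dataset,
    read_dataset,
    tile_with_annotations,
    write_dataset,
)
from tipsim.renderer import camera_for_gsd, render_scene

from conftest import DIFFUSE_LIGHT, FLAT_TEXTURES, make_single_plant_scene


class TestAnnotateTips:
    def test_single_upright_leaf_nadir(self):
        """An isolated leaf yields exactly one annotation at the projected tip."""
        params = pm.PlantParams(inclination_angle=20.0, curvature=0.0,
                                phyllotaxy_jitter=0.0)
        plant = pm.build_plant(100, params, np.random.default_rng(0))
        scene = pm.CanopyScene(plants=[plant], soil_extent=(-100, -100, 100, 100))
        cam = camera_for_gsd(1.0, view_zenith=0, sensor_width_px=128,
                             look_at=(0, 0, 0))
        frame = render_scene(scene, cam, DIFFUSE_LIGHT, aa_factor=1)
        anns = annotate_tips(scene, frame)
        assert len(anns) == 1
        u, v, d = rnd.project_point(plant.leaves[0].tip_point, cam)
        assert anns[0].center_u == pytest.approx(u)
        assert anns[0].center_v == pytest.approx(v)
        assert anns[0].depth == pytest.approx(d)
        x, y, w, h = anns[0].box
        assert (w, h) == (BOX_SIZE, BOX_SIZE)
        assert x == pytest.approx(u - BOX_SIZE / 2)

    def test_fully_occluded_tip_dropped(self):
        """A full-frame opaque panel 50 mm in front of the tip hides it."""
        params = pm.PlantParams(inclination_angle=20.0, curvature=0.0)
        plant = pm.build_plant(100, params, np.random.default_rng(0))
        tip_z = plant.leaves[0].tip_point[2]
        panel_z = tip_z + 50.0
        s = 500.0
        panel = [
            np.array([[[-s, -s, panel_z], [s, -s, panel_z], [s, s, panel_z]]]),
            np.array([[[-s, -s, panel_z], [s, s, panel_z], [-s, s, panel_z]]]),
        ]

        class Panelled(pm.CanopyScene):
            def triangle_arrays(self):
                tris, uv, own = super().triangle_arrays()
                extra = np.concatenate(panel)
                return (
                    np.concatenate([tris, extra]),
                    np.concatenate([uv, np.zeros((2, 3, 2))]),
                    np.concatenate([own, np.full(2, len(self.all_leaves()) - 1,
                                                 dtype=np.int32)]),
                )

            def all_leaves(self):
                # the panel is registered as an extra pseudo-leaf so the
                # owner buffer can reference it
                return super().all_leaves() + [(99, plant.leaves[0])]

        scene = Panelled(plants=[plant], soil_extent=(-100, -100, 100, 100))
        cam = camera_for_gsd(1.0, view_zenith=0, sensor_width_px=128,
                             look_at=(0, 0, 0))
        frame = render_scene(scene, cam, DIFFUSE_LIGHT, aa_factor=1)
        anns = [a for a in annotate_tips(scene, frame) if a.plant_id == 0]
        assert anns == []

    def test_out_of_frame_tips_not_emitted(self):
        scene = make_single_plant_scene(0)
        cam = camera_for_gsd(0.1, view_zenith=0, sensor_width_px=32,
                             look_at=(1000, 1000, 0))
        frame = render_scene(scene, cam, DIFFUSE_LIGHT, aa_factor=1)
        with pytest.warns(UserWarning, match="no leaf tips project"):
            anns = annotate_tips(scene, frame)
        assert anns == []

    def test_adding_plants_never_reveals_more_tips(self):
        """Monotone occlusion: extra plants can only hide the original tips."""
        base_scene = make_single_plant_scene(1)
        cam = camera_for_gsd(1.25, view_zenith=0, sensor_width_px=256,
                             look_at=(0, 0, 0))
        frame = render_scene(base_scene, cam, DIFFUSE_LIGHT, aa_factor=1)
        solo = {(a.plant_id, a.leaf_rank) for a in annotate_tips(base_scene, frame)}
        rng = np.random.default_rng(99)
        extra = [
            pm.build_plant(float(rng.uniform(100, 300)), pm.PlantParams(), rng,
                           np.array([rng.uniform(-80, 80), rng.uniform(-80, 80), 0]),
                           plant_id=1 + i)
            for i in range(4)
        ]
        crowded = pm.CanopyScene(plants=base_scene.plants + extra,
                                 soil_extent=base_scene.soil_extent)
        frame2 = render_scene(crowded, cam, DIFFUSE_LIGHT, aa_factor=1)
        crowded_orig = {
            (a.plant_id, a.leaf_rank)
            for a in annotate_tips(crowded, frame2)
            if a.plant_id == base_scene.plants[0].plant_id
        }
        assert crowded_orig <= solo


class TestTiling:
    def _blank_record(self, w, h, anns=()):
        return ImageRecord(image_path="frame.png", width=w, height=h, gsd=0.3,
                           haun_stage=2.0, annotations=list(anns))

    def test_field_frame_tile_count(self):
        """5472 x 3648 with 1024 px tiles and 896 px stride -> 6 x 4 tiles."""
        tiles = tile_with_annotations(self._blank_record(5472, 3648), 1024, 896)
        assert len(tiles) == 24
        origins = {tuple(t.provenance["tile_origin"]) for t in tiles}
        assert (0, 0) in origins and (5472 - 1024, 3648 - 1024) in origins

    def test_every_pixel_covered(self):
        tiles = tile_with_annotations(self._blank_record(2000, 1500), 640, 512)
        cover = np.zeros((1500, 2000), dtype=bool)
        for t in tiles:
            x0, y0 = t.provenance["tile_origin"]
            cover[y0 : y0 + t.height, x0 : x0 + t.width] = True
        assert cover.all()

    def test_annotation_translated_into_tile(self):
        a = TipAnnotation(center_u=100.0, center_v=100.0, visible=True,
                          plant_id=0, leaf_rank=1, depth=500.0)
        tiles = tile_with_annotations(self._blank_record(2048, 2048, [a]), 1024, 896)
        first = [t for t in tiles if t.provenance["tile_origin"] == [0, 0]][0]
        assert len(first.annotations) == 1
        assert first.annotations[0].center_u == 100.0

    def test_partition_when_stride_equals_tile(self):
        anns = [
            TipAnnotation(center_u=u, center_v=v, visible=True, plant_id=0,
                          leaf_rank=1, depth=1.0)
            for u, v in [(10.5, 20.5), (600.0, 100.0), (1000.0, 1000.0)]
        ]
        tiles = tile_with_annotations(self._blank_record(1024, 1024, anns), 512, 512)
        assert len(tiles) == 4
        assert sum(len(t.annotations) for t in tiles) == len(anns)

    def test_oversized_tile_warns_single(self):
        with pytest.warns(UserWarning, match="clamped"):
            tiles = tile_with_annotations(self._blank_record(100, 80), 256, 200)
        assert len(tiles) == 1 and tiles[0].width == 100

    def test_image_pixels_sliced(self):
        rec = self._blank_record(64, 64)
        rec.image = np.arange(64 * 64 * 3, dtype=float).reshape(64, 64, 3) / 1e5
        tiles = tile_with_annotations(rec, 32, 32)
        t = [t for t in tiles if t.provenance["tile_origin"] == [32, 32]][0]
        np.testing.assert_array_equal(t.image, rec.image[32:, 32:])


class TestDatasetIO:
    def test_empty_manifest_roundtrip(self, tmp_path):
        m = DatasetManifest(records=[], master_seed=1)
        write_dataset(m, tmp_path)
        assert read_dataset(tmp_path).to_dict() == m.to_dict()

    def test_roundtrip_field_for_field(self, tmp_path):
        manifest = generate_dataset(
            3, camera=camera_for_gsd(1.5, sensor_width_px=64),
            field_template=pm.FieldConfig(plot_width=150, plot_depth=150,
                                          row_spacing=75),
            seed=11,
        )
        write_dataset(manifest, tmp_path)
        back = read_dataset(tmp_path)
        assert back.to_dict() == manifest.to_dict()
        assert back.records == manifest.records

    def test_annotation_count_conserved_in_files(self, tmp_path):
        import csv as csvmod
        import json

        manifest = generate_dataset(
            2, camera=camera_for_gsd(1.5, sensor_width_px=64),
            field_template=pm.FieldConfig(plot_width=150, plot_depth=150,
                                          row_spacing=75),
            seed=4,
        )
        paths = write_dataset(manifest, tmp_path)
        coco = json.loads(paths["coco"].read_text())
        assert len(coco["annotations"]) == manifest.total_annotations()
        with open(paths["csv"]) as fh:
            rows = list(csvmod.DictReader(fh))
        assert len(rows) == manifest.total_annotations()

    def test_missing_manifest_raises(self, tmp_path):
        with pytest.raises(DatasetIOError, match="manifest"):
            read_dataset(tmp_path)


class TestAttachTranslated:
    def _written(self, tmp_path, n=3):
        manifest = generate_dataset(
            n, camera=camera_for_gsd(1.5, sensor_width_px=64),
            field_template=pm.FieldConfig(plot_width=150, plot_depth=150,
                                          row_spacing=75),
            seed=2,
        )
        write_dataset(manifest, tmp_path)
        return read_dataset(tmp_path)

    def test_identity_copies_keep_annotations(self, tmp_path):
        manifest = self._written(tmp_path)
        tdir = tmp_path / "translated"
        tdir.mkdir()
        for rec in manifest.records:
            shutil.copy(tmp_path / "images" / rec.image_path, tdir / rec.image_path)
        out = attach_annotations_to_translated(manifest, tdir)
        for a, b in zip(manifest.records, out.records):
            assert a.annotations == b.annotations
            assert b.provenance["translated_from"] == a.image_path

    def test_missing_file_named_in_error(self, tmp_path):
        manifest = self._written(tmp_path, n=3)
        tdir = tmp_path / "translated"
        tdir.mkdir()
        for rec in manifest.records[:-1]:
            shutil.copy(tmp_path / "images" / rec.image_path, tdir / rec.image_path)
        missing = manifest.records[-1].image_path
        with pytest.raises(DatasetIOError, match=missing):
            attach_annotations_to_translated(manifest, tdir)

    def test_dimension_mismatch_rejected(self, tmp_path):
        from PIL import Image

        manifest = self._written(tmp_path)
        tdir = tmp_path / "translated"
        tdir.mkdir()
        for rec in manifest.records:
            src = tmp_path / "images" / rec.image_path
            Image.open(src).resize((32, 32)).save(tdir / rec.image_path)
        with pytest.raises(DatasetIOError, match="dimensions"):
            attach_annotations_to_translated(manifest, tdir)


class TestGenerateDataset:
    def test_zero_scenes_empty(self):
        m = generate_dataset(0, seed=0)
        assert m.records == [] and m.total_annotations() == 0

    def test_deterministic_byte_identical(self, tmp_path):
        kwargs = dict(
            camera=camera_for_gsd(1.5, sensor_width_px=64),
            field_template=pm.FieldConfig(plot_width=150, plot_depth=150,
                                          row_spacing=75),
            seed=8,
        )
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(2, **kwargs), a_dir)
        write_dataset(generate_dataset(2, **kwargs), b_dir)
        for name in ("manifest.json", "annotations.json", "annotations.csv"):
            assert (a_dir / name).read_bytes() == (b_dir / name).read_bytes()
        for pa in sorted((a_dir / "images").iterdir()):
            pb = b_dir / "images" / pa.name
            assert pa.read_bytes() == pb.read_bytes()

    def test_tips_bounded_by_leaf_census(self):
        manifest = generate_dataset(
            5, camera=camera_for_gsd(1.5, view_zenith=45,
                                     sensor_width_px=128,
                                     look_at=(100, 100, 0)),
            field_template=pm.FieldConfig(plot_width=200, plot_depth=200,
                                          row_spacing=100),
            seed=13,
        )
        assert len(manifest.records) == 5
        for rec in manifest.records:
            assert len(rec.annotations) <= rec.provenance["n_leaves"]
        assert manifest.total_annotations() > 0
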