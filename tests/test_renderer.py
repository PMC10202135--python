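"""Projection geometry, shading model, and z-buffer rasterization."""

import math

import numpy as np
import pytest

from tipsim import plant_model as pm
from tipsim.renderer import (
    BehindCameraError,
    CameraConfig,
    LightConfig,
    RenderedFrame,
    TextureSet,
    _sample_rays,
    camera_for_gsd,
    project_point,
    render_scene,
    shade,
)
from tipsim.plant_model import CanopyScene, InvalidParameterError

from conftest import DIFFUSE_LIGHT, FLAT_TEXTURES, make_random_canopy


class TestCameraForGsd:
    def test_height_inverts_gsd_formula(self):
        # nadir, tan(fov/2) = 0.5 -> fov ~ 53.13 deg, 1000 px, 1 mm/px
        fov = 2 * math.degrees(math.atan(0.5))
        cam = camera_for_gsd(1.0, view_zenith=0.0, fov=fov, sensor_width_px=1000)
        assert cam.height == pytest.approx(1000.0)
        assert cam.gsd_center() == pytest.approx(1.0)

    def test_height_proportional_to_gsd(self):
        a = camera_for_gsd(0.5, view_zenith=30.0)
        b = camera_for_gsd(1.0, view_zenith=30.0)
        assert b.height == pytest.approx(2 * a.height)

    def test_oblique_gsd_doubles_at_60_degrees(self):
        nadir = camera_for_gsd(1.0, view_zenith=0.0)
        oblique = CameraConfig(
            height=nadir.height, view_zenith=60.0,
            horizontal_fov=nadir.horizontal_fov,
            sensor_width_px=nadir.sensor_width_px,
            sensor_height_px=nadir.sensor_height_px,
        )
        assert oblique.gsd_center() == pytest.approx(2 * nadir.gsd_center())

    def test_invalid_gsd_rejected(self):
        with pytest.raises(InvalidParameterError):
            camera_for_gsd(-0.5)


class TestProjectPoint:
    def test_optical_axis_hits_principal_point(self):
        cam = CameraConfig(height=1000, view_zenith=30, view_azimuth=70,
                           sensor_width_px=640, sensor_height_px=480,
                           look_at=(50.0, 80.0, 0.0))
        u, v, d = project_point((50.0, 80.0, 0.0), cam)
        assert u == pytest.approx(320.0, abs=1e-6)
        assert v == pytest.approx(240.0, abs=1e-6)

    def test_lookat_depth_is_camera_distance(self):
        cam = CameraConfig(height=1800, view_zenith=45, look_at=(0.0, 0.0, 0.0))
        _, _, d = project_point((0.0, 0.0, 0.0), cam)
        assert d == pytest.approx(np.linalg.norm(cam.position))

    def test_lateral_offset_matches_matrix_oracle(self):
        """Pinhole projection agrees with an independent homogeneous-matrix
        projection for a cloud of random points."""
        cam = CameraConfig(height=900, view_zenith=25, view_azimuth=130,
                           horizontal_fov=50, sensor_width_px=512,
                           sensor_height_px=384, look_at=(30.0, -40.0, 0.0))
        right, down, fwd = cam.basis()
        f = cam.focal_px
        # 3x4 projection matrix oracle: K [R | -R c]
        K = np.array([[f, 0, 256.0], [0, f, 192.0], [0, 0, 1.0]])
        R = np.stack([right, down, fwd])
        P = K @ np.hstack([R, (-R @ cam.position)[:, None]])
        rng = np.random.default_rng(0)
        pts = rng.uniform([-200, -200, 0], [200, 200, 120], size=(50, 3))
        for p in pts:
            uvw = P @ np.append(p, 1.0)
            u, v, d = project_point(p, cam)
            assert u == pytest.approx(uvw[0] / uvw[2], abs=1e-8)
            assert v == pytest.approx(uvw[1] / uvw[2], abs=1e-8)
            assert d == pytest.approx(np.linalg.norm(p - cam.position))

    def test_point_behind_camera_raises(self):
        cam = CameraConfig(height=500, view_zenith=0, look_at=(0.0, 0.0, 0.0))
        with pytest.raises(BehindCameraError):
            project_point((0.0, 0.0, 600.0), cam)


class TestShade:
    def test_fully_diffuse_returns_albedo(self):
        light = LightConfig(diffuse_fraction=1.0)
        albedo = np.array([0.2, 0.5, 0.1])
        out_lit = shade(np.array([0.0, 0.0, 1.0]), albedo, light, in_shadow=False)
        out_shadow = shade(np.array([0.0, 0.0, 1.0]), albedo, light, in_shadow=True)
        np.testing.assert_array_equal(out_lit, albedo)
        np.testing.assert_array_equal(out_shadow, albedo)

    def test_direct_normal_incidence(self):
        light = LightConfig(sun_zenith=0.0, diffuse_fraction=0.0)
        albedo = np.array([0.3, 0.6, 0.2])
        out = shade(np.array([0.0, 0.0, 1.0]), albedo, light, in_shadow=False)
        np.testing.assert_allclose(out, albedo)

    def test_direct_in_shadow_is_black(self):
        light = LightConfig(sun_zenith=0.0, diffuse_fraction=0.0)
        out = shade(np.array([0.0, 0.0, 1.0]), np.array([0.3, 0.6, 0.2]),
                    light, in_shadow=True)
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_mixed_fraction_interpolates(self):
        light = LightConfig(sun_zenith=0.0, diffuse_fraction=0.4)
        albedo = np.array([0.5, 0.5, 0.5])
        out = shade(np.array([0.0, 0.0, 1.0]), albedo, light, in_shadow=False)
        np.testing.assert_allclose(out, albedo)  # 0.4 + 0.6 * 1
        out_sh = shade(np.array([0.0, 0.0, 1.0]), albedo, light, in_shadow=True)
        np.testing.assert_allclose(out_sh, 0.4 * albedo)


class TestRenderScene:
    def test_empty_scene_all_soil(self):
        scene = CanopyScene(plants=[], soil_extent=(0, 0, 200, 200))
        cam = camera_for_gsd(1.0, view_zenith=0, sensor_width_px=64,
                             look_at=(100, 100, 0))
        frame = render_scene(scene, cam, DIFFUSE_LIGHT, FLAT_TEXTURES, aa_factor=1)
        assert np.all(frame.owner == RenderedFrame.SOIL)
        np.testing.assert_allclose(
            frame.rgb, np.broadcast_to(FLAT_TEXTURES.soil_color, frame.rgb.shape)
        )

    def test_zbuffer_near_triangle_wins(self):
        """Two stacked horizontal triangles: overlap owned by the nearer."""
        t_low = np.array([[[-50, -50, 10], [50, -50, 10], [0, 60, 10]]], float)
        t_high = np.array([[[-50, -50, 40], [50, -50, 40], [0, 60, 40]]], float)

        class TwoTris(CanopyScene):
            def triangle_arrays(self):
                tris = np.concatenate([t_low, t_high])
                uv = np.zeros((2, 3, 2))
                return tris, uv, np.array([0, 1], dtype=np.int32)

            def all_leaves(self):
                return [(0, None), (0, None)]

        scene = TwoTris(plants=[], soil_extent=(-100, -100, 100, 100))
        cam = camera_for_gsd(1.0, view_zenith=0, sensor_width_px=128,
                             look_at=(0, 0, 0))
        frame = render_scene(scene, cam, DIFFUSE_LIGHT, FLAT_TEXTURES, aa_factor=1)
        both = frame.owner > 0
        assert both.any()
        # wherever any triangle is hit, the upper one (id 2) owns the pixel
        # in the overlap region; the lower one is only visible outside it
        assert np.all(frame.owner[both] == 2) or set(np.unique(frame.owner[both])) == {2}

    def test_single_triangle_coverage_matches_bruteforce(self):
        """Covered pixel centers equal an independent point-in-triangle scan."""
        tri = np.array([[[-30, -20, 25], [40, -10, 25], [5, 45, 25]]], float)

        class OneTri(CanopyScene):
            def triangle_arrays(self):
                return tri, np.zeros((1, 3, 2)), np.array([0], dtype=np.int32)

            def all_leaves(self):
                return [(0, None)]

        scene = OneTri(plants=[], soil_extent=(-100, -100, 100, 100))
        cam = camera_for_gsd(1.0, view_zenith=0, sensor_width_px=128,
                             look_at=(0, 0, 0))
        frame = render_scene(scene, cam, DIFFUSE_LIGHT, FLAT_TEXTURES, aa_factor=1)

        # oracle: project vertices, then barycentric point-in-triangle test
        # at every pixel center
        pts2d = np.array([project_point(v, cam)[:2] for v in tri[0]])
        us, vs = np.meshgrid(np.arange(128, dtype=float), np.arange(128, dtype=float))
        d1 = (pts2d[1, 0] - pts2d[0, 0]) * (vs - pts2d[0, 1]) - \
             (pts2d[1, 1] - pts2d[0, 1]) * (us - pts2d[0, 0])
        d2 = (pts2d[2, 0] - pts2d[1, 0]) * (vs - pts2d[1, 1]) - \
             (pts2d[2, 1] - pts2d[1, 1]) * (us - pts2d[1, 0])
        d3 = (pts2d[0, 0] - pts2d[2, 0]) * (vs - pts2d[2, 1]) - \
             (pts2d[0, 1] - pts2d[2, 1]) * (us - pts2d[2, 0])
        inside = ((d1 >= 0) & (d2 >= 0) & (d3 >= 0)) | ((d1 <= 0) & (d2 <= 0) & (d3 <= 0))
        np.testing.assert_array_equal(frame.owner == 1, inside)

    def test_triangle_order_invariance(self, rendered_small_canopy):
        scene, cam, light, frame = rendered_small_canopy
        tris, uv, own = scene.triangle_arrays()
        perm = np.random.default_rng(0).permutation(len(tris))

        class Shuffled(CanopyScene):
            def triangle_arrays(self):
                return tris[perm], uv[perm], own[perm]

        shuffled = Shuffled(plants=scene.plants, soil_extent=scene.soil_extent)
        f2 = render_scene(shuffled, cam, light, aa_factor=2)
        np.testing.assert_array_equal(frame.rgb, f2.rgb)
        np.testing.assert_array_equal(frame.depth, f2.depth)
        np.testing.assert_array_equal(frame.owner, f2.owner)

    def test_diffuse_light_shadow_toggle_identical(self, small_canopy):
        cam = camera_for_gsd(1.5, view_zenith=20, sensor_width_px=96,
                             look_at=(100, 100, 0))
        with_sh = render_scene(small_canopy, cam,
                               LightConfig(diffuse_fraction=1.0, cast_shadows=True),
                               aa_factor=1)
        without = render_scene(small_canopy, cam,
                               LightConfig(diffuse_fraction=1.0, cast_shadows=False),
                               aa_factor=1)
        np.testing.assert_array_equal(with_sh.rgb, without.rgb)

    def test_shadow_map_matches_ray_mode(self, small_canopy):
        """The fast light-space depth map reproduces exact per-sample ray
        casting nearly everywhere (discretization differs only at edges)."""
        cam = camera_for_gsd(1.5, view_zenith=20, sensor_width_px=96,
                             look_at=(100, 100, 0))
        light = LightConfig(sun_zenith=40, sun_azimuth=60,
                            diffuse_fraction=0.0, cast_shadows=True)
        f_map = render_scene(small_canopy, cam, light, aa_factor=1, shadow_mode="map")
        f_ray = render_scene(small_canopy, cam, light, aa_factor=1, shadow_mode="ray")
        same = np.all(np.isclose(f_map.rgb, f_ray.rgb, atol=1e-6), axis=2)
        assert same.mean() > 0.97

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_soil_owner_iff_analytic_soil_depth(self, seed):
        scene = make_random_canopy(seed)
        cam = camera_for_gsd(1.2, view_zenith=35, sensor_width_px=96,
                             look_at=(100, 100, 0))
        frame = render_scene(scene, cam, DIFFUSE_LIGHT, aa_factor=1)
        H, W = frame.depth.shape
        us, vs = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
        dirs = _sample_rays(cam, us, vs)
        t_soil = np.where(dirs[..., 2] < 0, -cam.position[2] / dirs[..., 2], np.inf)
        soil = frame.owner == RenderedFrame.SOIL
        assert np.allclose(frame.depth[soil], t_soil[soil], rtol=1e-9)
        leaf = frame.owner > 0
        assert np.all(frame.depth[leaf] < t_soil[leaf] + 1e-6)

    def test_deterministic(self, small_canopy):
        cam = camera_for_gsd(1.5, view_zenith=45, sensor_width_px=80,
                             look_at=(100, 100, 0))
        light = LightConfig(diffuse_fraction=0.5, cast_shadows=True)
        a = render_scene(small_canopy, cam, light, aa_factor=2)
        b = render_scene(small_canopy, cam, light, aa_factor=2)
        np.testing.assert_array_equal(a.rgb, b.rgb)


class TestTextures:
    def test_image_texture_sampling(self):
        leaf_img = np.zeros((4, 4, 3))
        leaf_img[..., 0] = 1.0  # red leaf texture to make sampling obvious
        tex = TextureSet(leaf_texture=leaf_img, soil_texture="soil_flat")
        scene = make_random_canopy(0)
        cam = camera_for_gsd(1.2, view_zenith=0, sensor_width_px=96,
                             look_at=(100, 100, 0))
        frame = render_scene(scene, cam, DIFFUSE_LIGHT, tex, aa_factor=1)
        leaf = frame.owner > 0
        assert leaf.any()
        assert np.all(frame.rgb[leaf] == [1.0, 0.0, 0.0])

    def test_invalid_texture_scale(self):
        with pytest.raises(InvalidParameterError):
            TextureSet(texture_scale=0.0)
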