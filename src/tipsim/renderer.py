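"""Pinhole projection and z-buffer rasterization of canopy scenes.

The renderer turns a :class:`~tipsim.plant_model.CanopyScene` into an RGB
image plus two auxiliary rasters used for automatic annotation: a depth
buffer (Euclidean distance along each view ray, mm) and an owner buffer
identifying which leaf — or the soil — is front-most at every pixel.

Shading is Lambertian with a diffuse/direct split: a ``diffuse_fraction``
of the irradiance arrives isotropically from the sky and the rest from the
sun direction, optionally blocked by hard cast shadows.  Shadows can be
computed either by exact per-sample ray casting against the full triangle
set (``shadow_mode="ray"``) or through an orthographic light-space depth
map (``shadow_mode="map"``, the default), which is much faster on
dataset-scale runs at the cost of shadow-edge discretization.

Coordinate conventions: world units are mm with z up and the soil at z=0;
image pixel centers sit at integer coordinates, origin top-left, u
rightward, v downward, half-open domain [0, W) x [0, H).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .plant_model import CanopyScene, InvalidParameterError

__all__ = [
    "CameraConfig",
    "LightConfig",
    "TextureSet",
    "RenderedFrame",
    "camera_for_gsd",
    "project_point",
    "shade",
    "render_scene",
    "BehindCameraError",
    "DEFAULT_FIELD_CAMERA",
]


class BehindCameraError(ValueError):
    """Point lies at or behind the camera plane."""


@dataclass(frozen=True)
class CameraConfig:
    """Pinhole camera looking at a point on the soil plane.

    ``height`` is the optical-center height above the soil (mm);
    ``view_zenith`` tilts the optical axis away from nadir (degrees, 0 =
    straight down), ``view_azimuth`` sets the horizontal direction of the
    tilt.  Square pixels; ``horizontal_fov`` spans the sensor width.
    """

    height: float = 1800.0
    view_zenith: float = 45.0
    view_azimuth: float = 0.0
    horizontal_fov: float = 40.0
    sensor_width_px: int = 5472
    sensor_height_px: int = 3648
    look_at: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise InvalidParameterError("camera height must be > 0")
        if not 0.0 <= self.view_zenith <= 60.0:
            raise InvalidParameterError("view_zenith must be in [0, 60] degrees")
        if not 1.0 < self.horizontal_fov < 120.0:
            raise InvalidParameterError("horizontal_fov must be in (1, 120) degrees")
        if min(self.sensor_width_px, self.sensor_height_px) < 16:
            raise InvalidParameterError("sensor must be at least 16 px on each side")

    @property
    def position(self) -> np.ndarray:
        """Optical center in world coordinates (mm)."""
        zen = math.radians(self.view_zenith)
        az = math.radians(self.view_azimuth)
        look = np.asarray(self.look_at, float)
        horiz = self.height * math.tan(zen)
        return look + np.array(
            [-horiz * math.cos(az), -horiz * math.sin(az), self.height]
        )

    @property
    def focal_px(self) -> float:
        """Focal length in pixels for the horizontal axis."""
        return (self.sensor_width_px / 2.0) / math.tan(
            math.radians(self.horizontal_fov) / 2.0
        )

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(right, down, forward) orthonormal camera axes in world frame."""
        pos = self.position
        fwd = np.asarray(self.look_at, float) - pos
        fwd = fwd / np.linalg.norm(fwd)
        world_up = np.array([0.0, 0.0, 1.0])
        right = np.cross(fwd, world_up)
        nr = np.linalg.norm(right)
        if nr < 1e-9:  # nadir view: fix image u along world +x
            right = np.array([1.0, 0.0, 0.0])
        else:
            right = right / nr
        down = np.cross(fwd, right)
        return right, down, fwd

    def gsd_center(self) -> float:
        """Nominal ground sampling distance at the image center (mm/px)."""
        slant = self.height / math.cos(math.radians(self.view_zenith))
        return (
            2.0
            * slant
            * math.tan(math.radians(self.horizontal_fov) / 2.0)
            / self.sensor_width_px
        )


#: Field-survey preset: 45 degree oblique view from 1.8 m, 5472x3648 sensor.
DEFAULT_FIELD_CAMERA = CameraConfig()


@dataclass(frozen=True)
class LightConfig:
    """Sun direction and diffuse/direct irradiance split.

    ``diffuse_fraction`` = 1 models a fully overcast sky (shadowless);
    0 models pure direct sun.  ``sun_zenith`` is measured from vertical.
    """

    sun_zenith: float = 35.0
    sun_azimuth: float = 120.0
    diffuse_fraction: float = 1.0
    cast_shadows: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.diffuse_fraction <= 1.0:
            raise InvalidParameterError("diffuse_fraction must be in [0, 1]")

    @property
    def sun_direction(self) -> np.ndarray:
        """Unit vector pointing from the scene toward the sun."""
        zen = math.radians(self.sun_zenith)
        az = math.radians(self.sun_azimuth)
        return np.array(
            [math.sin(zen) * math.cos(az), math.sin(zen) * math.sin(az), math.cos(zen)]
        )


@dataclass(frozen=True)
class TextureSet:
    """Leaf and soil albedo sources.

    Each texture is either a procedural generator id (``"leaf_flat"``,
    ``"leaf_bands"``, ``"soil_flat"``, ``"soil_noise"``) or an (H, W, 3)
    float array in [0, 1] sampled with wrap-around.  ``texture_scale`` maps
    soil-image pixels to mm on the ground; ``noise_seed`` fixes the
    procedural noise lattice.
    """

    leaf_texture: object = "leaf_bands"
    soil_texture: object = "soil_noise"
    texture_scale: float = 1.0
    leaf_color: tuple[float, float, float] = (0.20, 0.45, 0.14)
    soil_color: tuple[float, float, float] = (0.42, 0.30, 0.20)
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.texture_scale <= 0:
            raise InvalidParameterError("texture_scale must be > 0")
        for tex in (self.leaf_texture, self.soil_texture):
            if isinstance(tex, np.ndarray) and tex.size == 0:
                raise InvalidParameterError("texture image must be non-empty")


@dataclass
class RenderedFrame:
    """RGB raster plus depth and primitive-owner buffers.

    ``owner`` codes: -1 none (ray escapes the plot), 0 soil, k >= 1 the
    (k-1)-th leaf in :meth:`CanopyScene.all_leaves` order.  ``depth`` is the
    Euclidean distance from the optical center along each pixel's view ray
    (mm), +inf where nothing is hit.
    """

    rgb: np.ndarray
    depth: np.ndarray
    owner: np.ndarray
    camera: CameraConfig
    light: LightConfig

    SOIL: int = field(default=0, repr=False)
    NONE: int = field(default=-1, repr=False)


def camera_for_gsd(
    target_gsd: float,
    view_zenith: float = 45.0,
    fov: float = 40.0,
    sensor_width_px: int = 1024,
    sensor_height_px: int | None = None,
    view_azimuth: float = 0.0,
    look_at: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> CameraConfig:
    """Camera whose center ground-sampling distance equals ``target_gsd``.

    Solves GSD = 2 (h / cos zenith) tan(fov/2) / width_px for the height h,
    emulating a camera raised or lowered over the plot to sweep spatial
    resolution.
    """
    if target_gsd <= 0:
        raise InvalidParameterError("target_gsd must be > 0")
    height = (
        target_gsd
        * sensor_width_px
        * math.cos(math.radians(view_zenith))
        / (2.0 * math.tan(math.radians(fov) / 2.0))
    )
    if height <= 0:
        raise InvalidParameterError("requested GSD is unreachable (height <= 0)")
    return CameraConfig(
        height=height,
        view_zenith=view_zenith,
        view_azimuth=view_azimuth,
        horizontal_fov=fov,
        sensor_width_px=sensor_width_px,
        sensor_height_px=sensor_height_px or sensor_width_px,
        look_at=look_at,
    )


def project_point(p, camera: CameraConfig) -> tuple[float, float, float]:
    """Project a world point to sub-pixel image coordinates.

    Returns ``(u, v, d)`` where d is the Euclidean distance from the optical
    center (the depth along the view ray of that pixel).
    """
    p = np.asarray(p, float)
    pos = camera.position
    right, down, fwd = camera.basis()
    rel = p - pos
    z = float(rel @ fwd)
    if z <= 1e-9:
        raise BehindCameraError("point at or behind the camera plane")
    f = camera.focal_px
    u = camera.sensor_width_px / 2.0 + f * float(rel @ right) / z
    v = camera.sensor_height_px / 2.0 + f * float(rel @ down) / z
    return u, v, float(np.linalg.norm(rel))


def shade(
    normal: np.ndarray,
    albedo: np.ndarray,
    light: LightConfig,
    in_shadow: bool | np.ndarray = False,
) -> np.ndarray:
    """Lambertian shading with a diffuse/direct irradiance split.

    color = albedo * (k + (1 - k) * max(0, n.s) * lit) clamped to [0, 1],
    with k the diffuse fraction and s the unit sun vector.  Fully diffuse
    light (k = 1) returns the albedo unchanged, shadow-independent.
    """
    normal = np.asarray(normal, float)
    albedo = np.asarray(albedo, float)
    k = light.diffuse_fraction
    lambert = np.maximum(normal @ light.sun_direction, 0.0)
    lit = np.where(np.asarray(in_shadow), 0.0, 1.0)
    factor = np.asarray(k + (1.0 - k) * lambert * lit)
    if factor.ndim:
        factor = factor[..., None]
    return np.clip(albedo * factor, 0.0, 1.0)


# ---------------------------------------------------------------------------
# procedural textures


def _value_noise(x: np.ndarray, y: np.ndarray, seed: int, scale: float) -> np.ndarray:
    """Smooth deterministic value noise on a hashed integer lattice, in [0,1]."""
    xs, ys = x / scale, y / scale
    xi, yi = np.floor(xs), np.floor(ys)
    xf, yf = xs - xi, ys - yi

    def h(ix, iy):
        v = np.sin(ix * 127.1 + iy * 311.7 + seed * 74.7) * 43758.5453
        return v - np.floor(v)

    sx = xf * xf * (3 - 2 * xf)
    sy = yf * yf * (3 - 2 * yf)
    n00, n10 = h(xi, yi), h(xi + 1, yi)
    n01, n11 = h(xi, yi + 1), h(xi + 1, yi + 1)
    return (n00 * (1 - sx) + n10 * sx) * (1 - sy) + (n01 * (1 - sx) + n11 * sx) * sy


def soil_albedo(x: np.ndarray, y: np.ndarray, textures: TextureSet) -> np.ndarray:
    """Albedo of soil points at world (x, y) in mm."""
    base = np.asarray(textures.soil_color)
    tex = textures.soil_texture
    if isinstance(tex, np.ndarray):
        h, w = tex.shape[:2]
        i = np.mod(np.floor(y / textures.texture_scale).astype(int), h)
        j = np.mod(np.floor(x / textures.texture_scale).astype(int), w)
        return tex[i, j]
    if tex == "soil_flat":
        return np.broadcast_to(base, x.shape + (3,)).copy()
    # "soil_noise": multi-octave brightness + slight hue variation
    s = textures.noise_seed
    n = (
        0.55 * _value_noise(x, y, s, 24.0)
        + 0.30 * _value_noise(x, y, s + 1, 7.0)
        + 0.15 * _value_noise(x, y, s + 2, 2.2)
    )
    bright = 0.55 + 0.9 * n
    col = base[None, :] if x.ndim == 1 else base
    out = np.multiply.outer(bright, np.ones(3)) * col
    out[..., 0] *= 0.9 + 0.2 * _value_noise(x, y, s + 3, 15.0)
    return np.clip(out, 0.0, 1.0)


def leaf_albedo(u: np.ndarray, v: np.ndarray, textures: TextureSet) -> np.ndarray:
    """Albedo at blade-surface coordinates (u along, v across), each in [0,1]."""
    base = np.asarray(textures.leaf_color)
    tex = textures.leaf_texture
    if isinstance(tex, np.ndarray):
        h, w = tex.shape[:2]
        i = np.clip((v * (h - 1)).astype(int), 0, h - 1)
        j = np.clip((u * (w - 1)).astype(int), 0, w - 1)
        return tex[i, j]
    if tex == "leaf_flat":
        return np.broadcast_to(base, u.shape + (3,)).copy()
    # "leaf_bands": longitudinal vein bands + tipward brightening
    s = textures.noise_seed
    bands = 0.82 + 0.18 * np.sin(2 * np.pi * (v * 4.0 + 0.15 * np.sin(u * 9.0 + s)))
    grad = 0.9 + 0.25 * u
    out = np.multiply.outer(bands * grad, np.ones(3)) * base
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# rasterization core


def _sample_rays(camera: CameraConfig, us: np.ndarray, vs: np.ndarray):
    """World-space unit ray directions through image coordinates (us, vs)."""
    right, down, fwd = camera.basis()
    f = camera.focal_px
    xc = (us - camera.sensor_width_px / 2.0) / f
    yc = (vs - camera.sensor_height_px / 2.0) / f
    dirs = (
        xc[..., None] * right + yc[..., None] * down + np.ones_like(xc)[..., None] * fwd
    )
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    return dirs


def _rasterize(
    tris: np.ndarray,
    owners: np.ndarray,
    camera: CameraConfig,
    us: np.ndarray,
    vs: np.ndarray,
    soil_extent: tuple[float, float, float, float] | None,
):
    """Z-buffer pass over sample positions (us, vs) (2D arrays of coords).

    Returns dict of per-sample buffers: depth, owner, tri (triangle index or
    -1), point (world hit position), dirs (unit rays).
    """
    H, W = us.shape
    pos = camera.position
    dirs = _sample_rays(camera, us, vs)

    depth = np.full((H, W), np.inf)
    owner = np.full((H, W), RenderedFrame.NONE, dtype=np.int32)
    tri_id = np.full((H, W), -1, dtype=np.int32)

    # soil plane z = 0
    dz = dirs[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_soil = np.where(dz < -1e-12, -pos[2] / dz, np.inf)
    hit = np.isfinite(t_soil)
    if soil_extent is not None:
        px = pos[0] + dirs[..., 0] * t_soil
        py = pos[1] + dirs[..., 1] * t_soil
        xmin, ymin, xmax, ymax = soil_extent
        # the plot's soil plane extends a margin beyond the sown rectangle so
        # oblique views never see the void
        mx = 0.5 * max(xmax - xmin, ymax - ymin) + 2000.0
        hit &= (px >= xmin - mx) & (px <= xmax + mx) & (py >= ymin - mx) & (py <= ymax + mx)
    depth[hit] = t_soil[hit]
    owner[hit] = RenderedFrame.SOIL

    n_degenerate = 0
    f = camera.focal_px
    right, down, fwd = camera.basis()
    if len(tris):
        rel = tris.reshape(-1, 3) - pos
        zc = rel @ fwd
        uc = np.where(zc > 1e-9, camera.sensor_width_px / 2.0 + f * (rel @ right) / zc, 0)
        vc = np.where(zc > 1e-9, camera.sensor_height_px / 2.0 + f * (rel @ down) / zc, 0)
        zc = zc.reshape(-1, 3)
        uc = uc.reshape(-1, 3)
        vc = vc.reshape(-1, 3)
        normals = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])

        u0, v0 = us[0, 0], vs[0, 0]
        su = us[0, 1] - us[0, 0] if W > 1 else 1.0
        sv = vs[1, 0] - vs[0, 0] if H > 1 else 1.0

        for k in range(len(tris)):
            if np.any(zc[k] <= 1e-9):
                continue  # behind camera; scenes are far inside the frustum
            nrm = normals[k]
            if np.linalg.norm(nrm) < 1e-12:
                n_degenerate += 1
                continue
            ua, va = uc[k], vc[k]
            # sample-grid bbox of the projected triangle
            i0 = max(int(math.ceil((ua.min() - u0) / su)), 0)
            i1 = min(int(math.floor((ua.max() - u0) / su)), W - 1)
            j0 = max(int(math.ceil((va.min() - v0) / sv)), 0)
            j1 = min(int(math.floor((va.max() - v0) / sv)), H - 1)
            if i0 > i1 or j0 > j1:
                continue
            gu = us[j0 : j1 + 1, i0 : i1 + 1]
            gv = vs[j0 : j1 + 1, i0 : i1 + 1]
            # edge functions (orientation-independent coverage)
            e0 = (ua[1] - ua[0]) * (gv - va[0]) - (va[1] - va[0]) * (gu - ua[0])
            e1 = (ua[2] - ua[1]) * (gv - va[1]) - (va[2] - va[1]) * (gu - ua[1])
            e2 = (ua[0] - ua[2]) * (gv - va[2]) - (va[0] - va[2]) * (gu - ua[2])
            inside = ((e0 >= 0) & (e1 >= 0) & (e2 >= 0)) | (
                (e0 <= 0) & (e1 <= 0) & (e2 <= 0)
            )
            if not inside.any():
                continue
            d_block = dirs[j0 : j1 + 1, i0 : i1 + 1]
            denom = d_block @ nrm
            num = (tris[k, 0] - pos) @ nrm
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(np.abs(denom) > 1e-12, num / denom, np.inf)
            cand = inside & (t > 1e-6) & (t < depth[j0 : j1 + 1, i0 : i1 + 1])
            if not cand.any():
                continue
            sub_d = depth[j0 : j1 + 1, i0 : i1 + 1]
            sub_o = owner[j0 : j1 + 1, i0 : i1 + 1]
            sub_t = tri_id[j0 : j1 + 1, i0 : i1 + 1]
            sub_d[cand] = t[cand]
            sub_o[cand] = owners[k] + 1
            sub_t[cand] = k
    if n_degenerate:
        warnings.warn(f"skipped {n_degenerate} degenerate (zero-area) triangles")

    t_all = np.where(np.isfinite(depth), depth, 0.0)
    point = pos + dirs * t_all[..., None]
    return {"depth": depth, "owner": owner, "tri": tri_id, "point": point, "dirs": dirs}


def _shadow_mask_ray(points: np.ndarray, exclude_tri: np.ndarray,
                     tris: np.ndarray, sun: np.ndarray) -> np.ndarray:
    """Exact hard-shadow test: does any triangle block the ray to the sun?

    ``points`` (N, 3); ``exclude_tri`` (N,) triangle index owning each point
    (-1 for soil), skipped to avoid self-intersection.  Moller-Trumbore,
    vectorized over points per triangle.
    """
    n = len(points)
    shadow = np.zeros(n, dtype=bool)
    if n == 0 or len(tris) == 0:
        return shadow
    orig = points + sun * 1e-3
    v0 = tris[:, 0]
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    pvec = np.cross(sun, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    for k in range(len(tris)):
        if abs(det[k]) < 1e-12:
            continue
        live = ~shadow & (exclude_tri != k)
        if not live.any():
            continue
        tvec = orig[live] - v0[k]
        u = (tvec @ pvec[k]) / det[k]
        ok = (u >= 0) & (u <= 1)
        if not ok.any():
            continue
        qvec = np.cross(tvec[ok], e1[k])
        v = (qvec @ sun) / det[k]
        ok2 = (v >= 0) & (u[ok] + v <= 1)
        if not ok2.any():
            continue
        t = (qvec[ok2] @ e2[k]) / det[k]
        hit = t > 1e-6
        idx = np.flatnonzero(live)[np.flatnonzero(ok)[ok2][hit]]
        shadow[idx] = True
    return shadow


def _shadow_mask_map(points: np.ndarray, tris: np.ndarray, sun: np.ndarray,
                     map_px: int = 768) -> np.ndarray:
    """Hard shadows via an orthographic depth map seen from the sun.

    Depth is measured along -sun; a point is shadowed when some triangle
    surface lies closer to the sun in its texel.  A depth bias of two texel
    footprints suppresses self-shadow acne.
    """
    if len(points) == 0 or len(tris) == 0:
        return np.zeros(len(points), dtype=bool)
    # orthonormal basis with w = sun
    a = np.array([1.0, 0.0, 0.0])
    if abs(sun @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    ax = np.cross(sun, a)
    ax /= np.linalg.norm(ax)
    ay = np.cross(sun, ax)

    verts = tris.reshape(-1, 3)
    allpts = np.concatenate([verts, points])
    pa = allpts @ ax
    pb = allpts @ ay
    lo_a, hi_a = pa.min() - 1.0, pa.max() + 1.0
    lo_b, hi_b = pb.min() - 1.0, pb.max() + 1.0
    res = max(hi_a - lo_a, hi_b - lo_b) / map_px  # mm per texel
    na = max(int(math.ceil((hi_a - lo_a) / res)), 1)
    nb = max(int(math.ceil((hi_b - lo_b) / res)), 1)

    zmap = np.full((nb, na), np.inf)
    ta = (verts @ ax).reshape(-1, 3)
    tb = (verts @ ay).reshape(-1, 3)
    td = (-(verts @ sun)).reshape(-1, 3)  # distance along -sun (smaller = closer)
    for k in range(len(tris)):
        i0 = max(int((ta[k].min() - lo_a) / res), 0)
        i1 = min(int((ta[k].max() - lo_a) / res) + 1, na - 1)
        j0 = max(int((tb[k].min() - lo_b) / res), 0)
        j1 = min(int((tb[k].max() - lo_b) / res) + 1, nb - 1)
        if i0 > i1 or j0 > j1:
            continue
        gi = lo_a + (np.arange(i0, i1 + 1) + 0.5) * res
        gj = lo_b + (np.arange(j0, j1 + 1) + 0.5) * res
        ga, gb = np.meshgrid(gi, gj)
        ua, va = ta[k], tb[k]
        e0 = (ua[1] - ua[0]) * (gb - va[0]) - (va[1] - va[0]) * (ga - ua[0])
        e1 = (ua[2] - ua[1]) * (gb - va[1]) - (va[2] - va[1]) * (ga - ua[1])
        e2 = (ua[0] - ua[2]) * (gb - va[2]) - (va[0] - va[2]) * (ga - ua[2])
        inside = ((e0 >= 0) & (e1 >= 0) & (e2 >= 0)) | (
            (e0 <= 0) & (e1 <= 0) & (e2 <= 0)
        )
        if not inside.any():
            continue
        area2 = (ua[1] - ua[0]) * (va[2] - va[0]) - (va[1] - va[0]) * (ua[2] - ua[0])
        if abs(area2) < 1e-12:
            dval = np.full_like(ga, td[k].mean())
        else:
            w0 = e1 / area2
            w1 = e2 / area2
            w2 = e0 / area2
            dval = w0 * td[k][0] + w1 * td[k][1] + w2 * td[k][2]
        sub = zmap[j0 : j1 + 1, i0 : i1 + 1]
        upd = inside & (dval < sub)
        sub[upd] = dval[upd]

    qa = np.clip(((points @ ax) - lo_a) / res, 0, na - 1).astype(int)
    qb = np.clip(((points @ ay) - lo_b) / res, 0, nb - 1).astype(int)
    qd = -(points @ sun)
    bias = 2.0 * res + 1.0
    return zmap[qb, qa] < qd - bias


def render_scene(
    scene: CanopyScene,
    camera: CameraConfig,
    light: LightConfig,
    textures: TextureSet | None = None,
    aa_factor: int = 2,
    shadow_mode: str = "map",
) -> RenderedFrame:
    """Rasterize a canopy scene into an RGB + depth + owner frame.

    ``aa_factor`` x ``aa_factor`` supersamples are averaged down for the RGB
    channel; the depth and owner buffers are always computed at pixel
    centers so they line up exactly with annotation geometry.  Output RGB is
    linear [0, 1]; gamma is applied only when frames are written to PNG.
    """
    if aa_factor < 1:
        raise InvalidParameterError("aa_factor must be >= 1")
    if shadow_mode not in ("map", "ray"):
        raise InvalidParameterError("shadow_mode must be 'map' or 'ray'")
    textures = textures or TextureSet()
    W, H = camera.sensor_width_px, camera.sensor_height_px
    tris, uv_arr, tri_owner = scene.triangle_arrays()
    leaves = scene.all_leaves()

    # color pass on the supersampled grid
    ss = aa_factor
    off = (np.arange(ss) + 0.5) / ss - 0.5
    ucoords = (np.arange(W)[:, None] + off[None, :]).ravel()
    vcoords = (np.arange(H)[:, None] + off[None, :]).ravel()
    us, vs = np.meshgrid(ucoords, vcoords)
    buf = _rasterize(tris, tri_owner, camera, us, vs, scene.soil_extent)

    rgb_ss = _shade_buffers(buf, tris, uv_arr, textures, light, shadow_mode, camera)
    rgb = rgb_ss.reshape(H, ss, W, ss, 3).mean(axis=(1, 3))

    if ss == 1:
        depth, owner = buf["depth"], buf["owner"]
    else:
        usc, vsc = np.meshgrid(
            np.arange(W, dtype=float), np.arange(H, dtype=float)
        )
        cbuf = _rasterize(tris, tri_owner, camera, usc, vsc, scene.soil_extent)
        depth, owner = cbuf["depth"], cbuf["owner"]

    return RenderedFrame(
        rgb=np.clip(rgb, 0.0, 1.0), depth=depth, owner=owner, camera=camera, light=light
    )


def _shade_buffers(buf, tris, uv_arr, textures, light, shadow_mode, camera):
    """Compute shaded linear RGB for a rasterization buffer."""
    depth, owner, tri_id = buf["depth"], buf["owner"], buf["tri"]
    point, dirs = buf["point"], buf["dirs"]
    Hs, Ws = depth.shape
    rgb = np.zeros((Hs, Ws, 3))

    albedo = np.zeros((Hs, Ws, 3))
    normal = np.zeros((Hs, Ws, 3))

    soil_sel = owner == RenderedFrame.SOIL
    if soil_sel.any():
        albedo[soil_sel] = soil_albedo(
            point[..., 0][soil_sel], point[..., 1][soil_sel], textures
        )
        normal[soil_sel] = [0.0, 0.0, 1.0]

    leaf_sel = owner > 0
    if leaf_sel.any():
        ks = tri_id[leaf_sel]
        p = point[leaf_sel]
        v0, v1, v2 = tris[ks, 0], tris[ks, 1], tris[ks, 2]
        e1, e2 = v1 - v0, v2 - v0
        x = p - v0
        d11 = np.einsum("ij,ij->i", e1, e1)
        d12 = np.einsum("ij,ij->i", e1, e2)
        d22 = np.einsum("ij,ij->i", e2, e2)
        dx1 = np.einsum("ij,ij->i", x, e1)
        dx2 = np.einsum("ij,ij->i", x, e2)
        det = d11 * d22 - d12 * d12
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        b1 = (d22 * dx1 - d12 * dx2) / det
        b2 = (d11 * dx2 - d12 * dx1) / det
        b1 = np.clip(b1, 0.0, 1.0)
        b2 = np.clip(b2, 0.0, 1.0)
        uvp = (
            uv_arr[ks, 0]
            + b1[:, None] * (uv_arr[ks, 1] - uv_arr[ks, 0])
            + b2[:, None] * (uv_arr[ks, 2] - uv_arr[ks, 0])
        )
        albedo[leaf_sel] = leaf_albedo(
            np.clip(uvp[:, 0], 0, 1), np.clip(uvp[:, 1], 0, 1), textures
        )
        n = np.cross(e1, e2)
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        # two-sided blades: flip normals to face the camera
        facing = np.einsum("ij,ij->i", n, dirs[leaf_sel])
        n[facing > 0] *= -1
        normal[leaf_sel] = n

    visible = owner != RenderedFrame.NONE
    if not visible.any():
        return rgb

    in_shadow = np.zeros((Hs, Ws), dtype=bool)
    if light.cast_shadows and light.diffuse_fraction < 1.0 and len(tris):
        sun = light.sun_direction
        lam = (normal * sun).sum(axis=-1)
        need = visible & (lam > 0)
        if need.any():
            pts = point[need]
            if shadow_mode == "ray":
                mask = _shadow_mask_ray(pts, tri_id[need], tris, sun)
            else:
                mask = _shadow_mask_map(pts, tris, sun)
            in_shadow[need] = mask

    rgb[visible] = shade(
        normal[visible], albedo[visible], light, in_shadow[visible]
    )
    return rgb


def to_uint8(rgb: np.ndarray, gamma: float = 2.2) -> np.ndarray:
    """Gamma-encode a linear [0,1] image to 8-bit for file output."""
    return (np.clip(rgb, 0.0, 1.0) ** (1.0 / gamma) * 255.0).round().astype(np.uint8)


def dump_frame_buffers(frame: RenderedFrame, prefix) -> dict[str, str]:
    """Write the depth and owner buffers as NPY rasters for debugging.

    Returns the paths written ({"depth": ..., "owner": ...}).
    """
    paths = {"depth": f"{prefix}_depth.npy", "owner": f"{prefix}_owner.npy"}
    np.save(paths["depth"], frame.depth)
    np.save(paths["owner"], frame.owner)
    return paths
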