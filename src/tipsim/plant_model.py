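"""Parametric 3D wheat seedling plants and canopy scene assembly.

Plant development is driven by cumulative thermal time through the Haun
scale: ``H = thermal_time / phyllochron`` counts fully expanded main-stem
leaves, with a fractional part denoting the currently expanding leaf.  A
plant at Haun stage H therefore carries ``ceil(H)`` leaves, the topmost one
expanded to the fractional part of H.

Leaves are built as triangle meshes swept around a quadratic Bezier midrib
lying in the vertical plane of the leaf azimuth.  The insertion angle tilts
the midrib away from vertical and a droop coefficient bends it outward and
down, so the blade tip — the feature later detected in images — ends at a
well-defined 3D point stored alongside the mesh.

All randomness flows through an explicit ``numpy.random.Generator`` so that
scenes are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import qmc

__all__ = [
    "PlantParams",
    "LeafMesh",
    "Plant",
    "FieldConfig",
    "CanopyScene",
    "haun_stage",
    "build_leaf",
    "build_plant",
    "build_canopy",
    "sample_parameter_sets",
    "DEFAULT_PARAMETER_RANGES",
]

#: Number of vertices along the midrib polyline (including insertion and tip).
MIDRIB_POINTS = 13

#: Fraction of the midrib length at which the blade reaches maximum width.
WIDTH_PEAK_POSITION = 0.30

#: Blade width at the insertion point, as a fraction of the maximum width.
#: Kept high: the blade emerges from a sheath at near-full width, so only
#: the distal end tapers to a sharp point.
WIDTH_BASE_FRACTION = 0.7

#: Shipped default ranges for Latin hypercube sampling of canopy parameters.
#: Units: lengths/widths mm, angles degrees, phyllochron degC*day/leaf,
#: sowing density plants/m2, thermal time degC*day.
DEFAULT_PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "phyllochron": (80.0, 120.0),
    "leaf_length_max": (40.0, 200.0),
    "leaf_width_max": (3.0, 10.0),
    "inclination_angle": (20.0, 70.0),
    "curvature": (0.0, 0.8),
    "sowing_density": (100.0, 400.0),
    "thermal_time": (80.0, 420.0),
}


class InvalidParameterError(ValueError):
    """A plant/scene parameter violates its stated domain."""


@dataclass(frozen=True)
class PlantParams:
    """Architectural and developmental parameters of a wheat seedling.

    Parameters
    ----------
    phyllochron
        Thermal time between the appearance of two consecutive leaves
        (degC*day per leaf). Must be positive.
    leaf_length_by_rank
        Fully expanded midrib length per leaf rank, in mm.
    leaf_max_width_by_rank
        Maximum blade width per leaf rank, in mm.
    inclination_angle
        Angle of the midrib at insertion, measured from vertical (degrees,
        0 = upright). Must lie in [0, 90].
    curvature
        Dimensionless droop coefficient (>= 0); 0 gives a straight midrib,
        1 bends the tip a further 90 degrees outward along the blade.
    phyllotaxy_jitter
        Standard deviation of the azimuth deviation from strict 180-degree
        alternation between successive leaves (degrees).
    tiller_onset_haun
        Haun stage from which tillers may appear.
    tiller_number
        Number of tillers once past onset (>= 0).
    pseudostem_rise
        Vertical offset between the insertion points of successive leaves
        (mm): each new leaf emerges from the top of the whorl, above the
        older blades, as in real grass seedlings.
    """

    phyllochron: float = 100.0
    leaf_length_by_rank: tuple[float, ...] = (70.0, 110.0, 150.0, 180.0, 200.0, 210.0)
    leaf_max_width_by_rank: tuple[float, ...] = (4.0, 5.0, 6.5, 8.0, 9.0, 10.0)
    inclination_angle: float = 40.0
    curvature: float = 0.35
    phyllotaxy_jitter: float = 15.0
    tiller_onset_haun: float = 4.0
    tiller_number: int = 0
    pseudostem_rise: float = 12.0

    def __post_init__(self) -> None:
        if self.phyllochron <= 0:
            raise InvalidParameterError("phyllochron must be > 0")
        if not self.leaf_length_by_rank or not self.leaf_max_width_by_rank:
            raise InvalidParameterError("leaf dimension tables must be non-empty")
        if any(v <= 0 for v in self.leaf_length_by_rank):
            raise InvalidParameterError("all leaf lengths must be > 0")
        if any(v <= 0 for v in self.leaf_max_width_by_rank):
            raise InvalidParameterError("all leaf widths must be > 0")
        if not 0.0 <= self.inclination_angle <= 90.0:
            raise InvalidParameterError("inclination_angle must be in [0, 90]")
        if self.curvature < 0:
            raise InvalidParameterError("curvature must be >= 0")
        if self.tiller_number < 0:
            raise InvalidParameterError("tiller_number must be >= 0")
        if self.pseudostem_rise < 0:
            raise InvalidParameterError("pseudostem_rise must be >= 0")

    def length_for_rank(self, rank: int) -> float:
        if rank < 1 or rank > len(self.leaf_length_by_rank):
            raise InvalidParameterError(
                f"rank {rank} outside leaf_length_by_rank table "
                f"(1..{len(self.leaf_length_by_rank)})"
            )
        return self.leaf_length_by_rank[rank - 1]

    def width_for_rank(self, rank: int) -> float:
        if rank < 1 or rank > len(self.leaf_max_width_by_rank):
            raise InvalidParameterError(
                f"rank {rank} outside leaf_max_width_by_rank table "
                f"(1..{len(self.leaf_max_width_by_rank)})"
            )
        return self.leaf_max_width_by_rank[rank - 1]


@dataclass
class LeafMesh:
    """Triangle mesh of a single leaf blade with its midrib and tip point.

    ``triangles`` is an (T, 3, 3) float array of vertex coordinates in mm;
    ``uv`` is the matching (T, 3, 2) array of blade-surface coordinates
    (u along the midrib in [0, 1], v across the blade in [0, 1]) used for
    texturing.  ``tip_point`` always equals the final midrib vertex.
    """

    triangles: np.ndarray
    uv: np.ndarray
    midrib: np.ndarray
    tip_point: np.ndarray
    rank: int
    expansion_fraction: float

    def arc_length(self) -> float:
        """Arc length of the midrib polyline in mm."""
        return float(np.linalg.norm(np.diff(self.midrib, axis=0), axis=1).sum())


@dataclass
class Plant:
    """A single wheat shoot: a list of leaves rooted at ``base_position``."""

    leaves: list[LeafMesh]
    base_position: np.ndarray
    haun_stage: float
    plant_id: int


@dataclass(frozen=True)
class FieldConfig:
    """Sowing pattern and developmental time of a canopy plot.

    Distances in mm; ``sowing_density`` in plants per m2; ``thermal_time``
    in degC*day since emergence.
    """

    sowing_density: float = 200.0
    row_spacing: float = 150.0
    plot_width: float = 500.0
    plot_depth: float = 500.0
    position_jitter_sd: float = 10.0
    thermal_time: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sowing_density, self.row_spacing, self.plot_width, self.plot_depth) <= 0:
            raise InvalidParameterError("spatial quantities must be > 0")
        if self.position_jitter_sd < 0:
            raise InvalidParameterError("position_jitter_sd must be >= 0")
        if self.thermal_time < 0:
            raise InvalidParameterError("thermal_time must be >= 0")


@dataclass
class CanopyScene:
    """A collection of plants standing on the z=0 soil plane.

    ``soil_extent`` is (xmin, ymin, xmax, ymax) of the plot rectangle in mm.
    """

    plants: list[Plant]
    soil_extent: tuple[float, float, float, float]
    metadata: dict = field(default_factory=dict)

    def all_leaves(self) -> list[tuple[int, LeafMesh]]:
        """Flat list of (plant_id, leaf) over the scene."""
        return [(p.plant_id, leaf) for p in self.plants for leaf in p.leaves]

    def leaf_count(self) -> int:
        return sum(len(p.leaves) for p in self.plants)

    def triangle_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenate all leaf triangles.

        Returns ``(triangles, uv, owner)`` where ``owner[i]`` is the index of
        the owning leaf in :meth:`all_leaves` order (0-based).
        """
        tris, uvs, owners = [], [], []
        for idx, (_, leaf) in enumerate(self.all_leaves()):
            tris.append(leaf.triangles)
            uvs.append(leaf.uv)
            owners.append(np.full(len(leaf.triangles), idx, dtype=np.int32))
        if not tris:
            return (
                np.zeros((0, 3, 3)),
                np.zeros((0, 3, 2)),
                np.zeros(0, dtype=np.int32),
            )
        return np.concatenate(tris), np.concatenate(uvs), np.concatenate(owners)


def haun_stage(thermal_time: float, phyllochron: float) -> float:
    """Haun stage (number of fully expanded leaves) at a given thermal time.

    Development is linear in thermal time with slope 1/phyllochron, so the
    stage is simply ``thermal_time / phyllochron``.
    """
    if phyllochron <= 0:
        raise InvalidParameterError("phyllochron must be > 0")
    if thermal_time < 0:
        raise InvalidParameterError("thermal_time must be >= 0")
    return thermal_time / phyllochron


def _midrib_curve(
    length: float, inclination_deg: float, curvature: float, n_points: int = MIDRIB_POINTS
) -> np.ndarray:
    """Midrib polyline in the (radial, vertical) plane, arc length == length.

    A quadratic Bezier leaves the origin at ``inclination_deg`` from vertical;
    the end tangent is rotated a further ``curvature * 90`` degrees outward
    (droop).  The curve is sampled at uniform arc length and uniformly scaled
    so the polyline arc length equals ``length`` exactly.
    """
    th0 = math.radians(inclination_deg)
    th1 = th0 + curvature * math.pi / 2.0
    p0 = np.array([0.0, 0.0])
    p1 = p0 + 0.5 * np.array([math.sin(th0), math.cos(th0)])
    p2 = p1 + 0.5 * np.array([math.sin(th1), math.cos(th1)])
    # dense sampling for arc-length parameterization
    t = np.linspace(0.0, 1.0, 257)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.linspace(0.0, total, n_points)
    out = np.empty((n_points, 2))
    out[:, 0] = np.interp(targets, cum, pts[:, 0])
    out[:, 1] = np.interp(targets, cum, pts[:, 1])
    # rescale so the *polyline* arc length is exact
    poly_len = np.linalg.norm(np.diff(out, axis=0), axis=1).sum()
    return out * (length / poly_len)


#: Exponent of the tipward taper; < 1 keeps the blade near-full width along
#: most of its length and collapses it to the point only over the last few
#: mm, matching how real blades look and keeping the tip wider than a pixel
#: at field ground sampling distances.
WIDTH_TAPER_EXPONENT = 0.4


def _width_profile(u: np.ndarray, max_width: float) -> np.ndarray:
    """Blade width at normalized midrib position u in [0, 1].

    Rises from ``WIDTH_BASE_FRACTION * max_width`` at insertion to the
    maximum at ``WIDTH_PEAK_POSITION``, then tapers concavely
    (exponent ``WIDTH_TAPER_EXPONENT``) to exactly 0 at the tip, so the tip
    is sharp but remains optically resolvable almost to its end.
    """
    w = np.empty_like(u)
    rising = u < WIDTH_PEAK_POSITION
    w[rising] = max_width * (
        WIDTH_BASE_FRACTION
        + (1 - WIDTH_BASE_FRACTION) * u[rising] / WIDTH_PEAK_POSITION
    )
    w[~rising] = max_width * (
        (1 - u[~rising]) / (1 - WIDTH_PEAK_POSITION)
    ) ** WIDTH_TAPER_EXPONENT
    return w


def build_leaf(
    rank: int,
    expansion_fraction: float,
    params: PlantParams,
    rng: np.random.Generator,
    azimuth_deg: float = 0.0,
    base_position: np.ndarray | None = None,
    scale: float = 1.0,
) -> LeafMesh:
    """Build the triangle mesh of one leaf blade.

    The fully expanded midrib shape is computed for the leaf's rank and then
    uniformly scaled so its arc length equals
    ``expansion_fraction * leaf_length_by_rank[rank]`` (a growing leaf is a
    shrunken copy of its final shape).  The blade is swept horizontally
    across the midrib following the width taper profile.
    """
    if not 0.0 < expansion_fraction <= 1.0:
        raise InvalidParameterError("expansion_fraction must be in (0, 1]")
    nominal = params.length_for_rank(rank) * scale
    max_width = params.width_for_rank(rank) * expansion_fraction * scale
    length = nominal * expansion_fraction
    rz = _midrib_curve(length, params.inclination_angle, params.curvature)

    az = math.radians(azimuth_deg)
    radial = np.array([math.cos(az), math.sin(az), 0.0])
    up = np.array([0.0, 0.0, 1.0])
    binormal = np.array([-math.sin(az), math.cos(az), 0.0])
    base = np.zeros(3) if base_position is None else np.asarray(base_position, float)

    midrib = base + rz[:, 0:1] * radial + rz[:, 1:2] * up
    u = np.linspace(0.0, 1.0, len(midrib))
    half = 0.5 * _width_profile(u, max_width)
    left = midrib - half[:, None] * binormal
    right = midrib + half[:, None] * binormal

    tris, uvs = [], []
    for i in range(len(midrib) - 1):
        quad = [
            (left[i], (u[i], 0.0)),
            (right[i], (u[i], 1.0)),
            (right[i + 1], (u[i + 1], 1.0)),
            (left[i + 1], (u[i + 1], 0.0)),
        ]
        for a, b, c in ((0, 1, 2), (0, 2, 3)):
            pts = np.array([quad[a][0], quad[b][0], quad[c][0]])
            area = 0.5 * np.linalg.norm(
                np.cross(pts[1] - pts[0], pts[2] - pts[0])
            )
            if area < 1e-9:
                continue  # degenerate strip end at the zero-width tip
            tris.append(pts)
            uvs.append(np.array([quad[a][1], quad[b][1], quad[c][1]]))

    return LeafMesh(
        triangles=np.array(tris),
        uv=np.array(uvs),
        midrib=midrib,
        tip_point=midrib[-1].copy(),
        rank=rank,
        expansion_fraction=expansion_fraction,
    )


def build_plant(
    thermal_time: float,
    params: PlantParams,
    rng: np.random.Generator,
    base_position: np.ndarray | None = None,
    plant_id: int = 0,
) -> Plant:
    """Build a plant at the development stage implied by thermal time.

    Leaves 1..floor(H) are fully expanded; when H is fractional one extra
    leaf is expanding at fraction H - floor(H).  Leaf azimuths alternate by
    180 degrees with Gaussian jitter.  Tillers (smaller secondary shoots at
    the same base) appear only once H >= tiller_onset_haun.
    """
    H = haun_stage(thermal_time, params.phyllochron)
    base = np.zeros(3) if base_position is None else np.asarray(base_position, float)
    n_full = int(math.floor(H))
    frac = H - n_full
    max_rank = len(params.leaf_length_by_rank)

    base_azimuth = rng.uniform(0.0, 360.0)
    leaves: list[LeafMesh] = []

    def shoot_leaves(h: float, scale: float, az0: float) -> None:
        nf = int(math.floor(h))
        fr = h - nf

        def insertion(k: int) -> np.ndarray:
            # each leaf emerges above the previous one along the pseudostem
            return base + np.array([0.0, 0.0, (k - 1) * params.pseudostem_rise * scale])

        for k in range(1, min(nf, max_rank) + 1):
            az = az0 + 180.0 * (k - 1) + rng.normal(0.0, params.phyllotaxy_jitter)
            leaves.append(build_leaf(k, 1.0, params, rng, az, insertion(k), scale))
        if fr > 1e-9 and nf + 1 <= max_rank:
            az = az0 + 180.0 * nf + rng.normal(0.0, params.phyllotaxy_jitter)
            leaves.append(
                build_leaf(nf + 1, fr, params, rng, az, insertion(nf + 1), scale)
            )

    shoot_leaves(H, 1.0, base_azimuth)
    if H >= params.tiller_onset_haun and params.tiller_number > 0:
        for t in range(params.tiller_number):
            h_t = max(H - params.tiller_onset_haun, 0.0)
            if h_t <= 1e-9:
                continue
            az_t = base_azimuth + 90.0 + 137.5 * t
            shoot_leaves(min(h_t, H), 0.6, az_t)

    return Plant(leaves=leaves, base_position=base, haun_stage=H, plant_id=plant_id)


def build_canopy(
    fieldcfg: FieldConfig, params: PlantParams, rng: np.random.Generator | None = None
) -> CanopyScene:
    """Assemble a canopy scene: plants on jittered rows inside the plot.

    Plant count is ``round(sowing_density * plot_area)``; rows run along the
    x axis, spaced ``row_spacing`` apart in y, and plants are evenly spread
    along each row with Gaussian positional jitter.  Deterministic given
    ``fieldcfg.seed`` (an explicitly passed generator overrides it).
    """
    if rng is None:
        rng = np.random.default_rng(fieldcfg.seed)
    area_m2 = (fieldcfg.plot_width / 1000.0) * (fieldcfg.plot_depth / 1000.0)
    n_plants = int(round(fieldcfg.sowing_density * area_m2))

    extent = (0.0, 0.0, fieldcfg.plot_width, fieldcfg.plot_depth)
    meta = {
        "thermal_time": fieldcfg.thermal_time,
        "mean_haun_stage": haun_stage(fieldcfg.thermal_time, params.phyllochron),
        "seed": fieldcfg.seed,
    }
    if n_plants == 0:
        import warnings

        warnings.warn("plot too small for a single plant; returning empty scene")
        return CanopyScene(plants=[], soil_extent=extent, metadata=meta)

    n_rows = max(1, int(round(fieldcfg.plot_depth / fieldcfg.row_spacing)))
    per_row = [n_plants // n_rows + (1 if i < n_plants % n_rows else 0) for i in range(n_rows)]
    plants: list[Plant] = []
    pid = 0
    for i, count in enumerate(per_row):
        y = (i + 0.5) * fieldcfg.plot_depth / n_rows
        for j in range(count):
            x = (j + 0.5) * fieldcfg.plot_width / max(count, 1)
            jitter = rng.normal(0.0, fieldcfg.position_jitter_sd, size=2)
            pos = np.array(
                [
                    np.clip(x + jitter[0], 0.0, fieldcfg.plot_width),
                    np.clip(y + jitter[1], 0.0, fieldcfg.plot_depth),
                    0.0,
                ]
            )
            plants.append(
                build_plant(fieldcfg.thermal_time, params, rng, pos, plant_id=pid)
            )
            pid += 1
    return CanopyScene(plants=plants, soil_extent=extent, metadata=meta)


def sample_parameter_sets(
    n: int, ranges: dict[str, tuple[float, float]], seed: int
) -> list[dict[str, float]]:
    """Latin hypercube sample of ``n`` parameter sets over the given ranges.

    Each parameter's n values occupy n distinct equal-width strata of its
    range.  Deterministic given ``seed``.
    """
    if not ranges:
        raise InvalidParameterError("ranges map must be non-empty")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    names = list(ranges)
    lo = np.array([ranges[k][0] for k in names], dtype=float)
    hi = np.array([ranges[k][1] for k in names], dtype=float)
    if np.any(lo >= hi):
        raise InvalidParameterError("each range must satisfy lo < hi")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    scaled = qmc.scale(unit, lo, hi)
    return [dict(zip(names, row)) for row in scaled]


def params_from_sample(sample: dict[str, float], base: PlantParams | None = None) -> PlantParams:
    """Turn a sampled parameter map into PlantParams.

    ``leaf_length_max`` / ``leaf_width_max`` rescale the whole per-rank
    dimension tables so their largest entry matches the sampled value.
    """
    base = base or PlantParams()
    kwargs: dict = {}
    if "phyllochron" in sample:
        kwargs["phyllochron"] = sample["phyllochron"]
    if "inclination_angle" in sample:
        kwargs["inclination_angle"] = float(np.clip(sample["inclination_angle"], 0.0, 90.0))
    if "curvature" in sample:
        kwargs["curvature"] = max(sample["curvature"], 0.0)
    if "leaf_length_max" in sample:
        f = sample["leaf_length_max"] / max(base.leaf_length_by_rank)
        kwargs["leaf_length_by_rank"] = tuple(v * f for v in base.leaf_length_by_rank)
    if "leaf_width_max" in sample:
        f = sample["leaf_width_max"] / max(base.leaf_max_width_by_rank)
        kwargs["leaf_max_width_by_rank"] = tuple(v * f for v in base.leaf_max_width_by_rank)
    return replace(base, **kwargs)


def scene_to_obj(scene: CanopyScene, path) -> None:
    """Export the scene's leaf triangles as a Wavefront OBJ file."""
    tris, _, _ = scene.triangle_arrays()
    with open(path, "w") as fh:
        fh.write("# tipsim canopy export\n")
        for tri in tris:
            for v in tri:
                fh.write(f"v {v[0]:.4f} {v[1]:.4f} {v[2]:.4f}\n")
        for i in range(len(tris)):
            b = 3 * i
            fh.write(f"f {b + 1} {b + 2} {b + 3}\n")
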