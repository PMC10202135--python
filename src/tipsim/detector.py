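"""Classical leaf-tip detector: vegetation index -> skeleton -> tip test.

This detector exists so the full generate/detect/evaluate loop runs on a
desk-scale machine with no learned components, and it defines the plug-in
contract every external detector must satisfy: RGB image in, scored 12 x 12
boxes out, serialized in the same COCO/CSV dialect as the annotations.

Pipeline:

1. ``vegetation_mask`` — excess-green index ExG = 2G - R - B, thresholded
   by Otsu's method, cleaned by a radius-1 morphological opening.
2. ``skeleton_endpoints`` — morphological skeleton of the mask; endpoints
   are skeleton pixels with exactly one 8-connected skeleton neighbour.
3. ``classify_tips`` — keep endpoints where the blade tapers (an absolute
   physical width bound when the ground sampling distance is known, a
   relative distance-transform ratio otherwise), that are free standing
   (low mask occupancy on a surrounding ring), that sit away from skeleton
   junctions (leaf bases), and that are not frame-edge truncations.  A
   sub-pixel refinement then follows the blade outward from the (receded)
   skeleton endpoint, recovering the true tip that skeletonization and
   opening erode away.

Leaf bases, stems, truncated blades and blob-like regions fail these
tests; blade tips pass them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening, skeletonize

__all__ = [
    "Detection",
    "DetectorConfig",
    "vegetation_mask",
    "skeleton_endpoints",
    "classify_tips",
    "detect",
    "detections_to_dicts",
    "detections_from_dicts",
]

BOX_SIZE = 12


@dataclass(frozen=True)
class Detection:
    """A scored candidate leaf tip with its fixed-size box."""

    center_u: float
    center_v: float
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")

    @property
    def box(self) -> tuple[float, float, float, float]:
        return (self.center_u - BOX_SIZE / 2, self.center_v - BOX_SIZE / 2,
                float(BOX_SIZE), float(BOX_SIZE))


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables of the classical tip detector.

    ``taper_ratio``: endpoint distance-transform value must be below this
    fraction of the branch median to count as a tapering tip (used when no
    ground sampling distance is available).
    ``tip_max_width_mm``: when the GSD is known, an endpoint is a tip iff
    the local blade half-width (distance transform x GSD) is below this
    physical bound — blades taper to a sub-millimetre point while bases,
    stems and truncated blobs stay wider.
    ``branch_window``: skeleton pixels examined along the incident branch.
    ``min_branch``: minimum branch length (px); shorter spurs are rejected.
    ``ring_radius`` / ``max_ring_occupancy``: a candidate tip must be free
    standing — mask pixels on a ring of this radius around it may occupy at
    most this angular fraction.  A genuine blade tip is approached by mask
    from one narrow direction only; truncated blade ends and leaf bases are
    attached to wider structure and fail the test.
    ``junction_radius``: endpoints with foreign skeleton pixels (not on
    their own branch) within this radius are rejected — they sit where
    another limb converges, i.e. at the plant base, not at a tip.
    ``border_margin``: detections closer than this to the image border are
    dropped; blades truncated by the frame edge end in tip-like cuts that
    carry no information about real tips.
    ``refine_max_px``: maximum sub-pixel tip-refinement march distance.
    ``refine_soft_frac``: fraction of the Otsu threshold used as the relaxed
    excess-green level that the refinement march may follow; mixed
    leaf/soil pixels past the hard mask boundary still carry the blade tip.
    """

    taper_ratio: float = 0.6
    tip_max_width_mm: float = 1.0
    branch_window: int = 15
    min_branch: int = 5
    ring_radius: int = 6
    max_ring_occupancy: float = 0.45
    junction_radius: int = 8
    border_margin: int = 6
    opening_radius: int = 1
    refine_max_px: float = 30.0
    refine_soft_frac: float = 0.3


def vegetation_mask(rgb: np.ndarray, opening_radius: int = 1) -> np.ndarray:
    """Binary vegetation mask from the excess-green index.

    ExG = 2G - R - B separates green canopy from soil; the threshold comes
    from Otsu's method on the ExG histogram, so the mask is equivariant to
    a common positive scaling of all channels.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    exg = 2.0 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]
    if np.ptp(exg) < 1e-12:
        warnings.warn("constant excess-green image; returning empty mask")
        return np.zeros(exg.shape, dtype=bool)
    thr = threshold_otsu(exg)
    mask = exg > thr
    if opening_radius > 0:
        mask = opening(mask, disk(opening_radius))
    return mask


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def skeleton_endpoints(mask: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Skeletonize the mask and list endpoint pixels.

    Returns ``(skeleton, endpoints)`` where endpoints are (row, col) pixels
    of the skeleton with exactly one 8-connected skeleton neighbour.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask), []
    skel = skeletonize(mask)
    neighbors = ndimage.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL,
                                 mode="constant")
    ep = skel & (neighbors == 1)
    return skel, [tuple(p) for p in np.argwhere(ep)]


def _trace_branch(skel: np.ndarray, start: tuple[int, int], max_len: int) -> list[tuple[int, int]]:
    """Walk the skeleton from an endpoint, stopping at junctions or max_len."""
    H, W = skel.shape
    path = [start]
    prev = None
    cur = start
    for _ in range(max_len - 1):
        nbrs = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                r, c = cur[0] + dr, cur[1] + dc
                if 0 <= r < H and 0 <= c < W and skel[r, c] and (r, c) != prev \
                        and (r, c) not in path[-3:]:
                    nbrs.append((r, c))
        if len(nbrs) != 1:
            break  # junction or dead end
        prev = cur
        cur = nbrs[0]
        path.append(cur)
    return path


def _refine_tip(mask: np.ndarray, endpoint: tuple[int, int],
                direction: np.ndarray, max_px: float) -> tuple[float, float]:
    """Follow the blade outward from the (receded) skeleton endpoint.

    A greedy curve-following march: at each 0.75 px step the direction may
    bend by up to ~35 degrees to stay on the mask, so curving blades are
    traced to their extreme point rather than clipped by a straight ray.
    Returns the last in-mask sample position (row, col).
    """
    H, W = mask.shape
    n = np.linalg.norm(direction)
    pos = np.array(endpoint, dtype=float)
    if n < 1e-9:
        return tuple(pos)
    d = direction / n
    step = 0.75
    bends = np.radians([0.0, 12.0, -12.0, 24.0, -24.0, 35.0, -35.0])
    cosb, sinb = np.cos(bends), np.sin(bends)
    travelled = 0.0
    while travelled < max_px:
        moved = False
        for cb, sb in zip(cosb, sinb):
            nd = np.array([d[0] * cb - d[1] * sb, d[0] * sb + d[1] * cb])
            cand = pos + nd * step
            ri, ci = int(round(cand[0])), int(round(cand[1]))
            if 0 <= ri < H and 0 <= ci < W and mask[ri, ci]:
                pos, d = cand, nd
                travelled += step
                moved = True
                break
        if not moved:
            break
    # snap to the extreme mask pixel along the final approach direction:
    # the march follows pixel centers and systematically stops ~1 px short
    # of the blade's end
    r0, c0 = int(round(pos[0])), int(round(pos[1]))
    best_proj, best_px = -np.inf, (r0, c0)
    for dr in range(-3, 4):
        for dc in range(-3, 4):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < H and 0 <= c < W and mask[r, c]:
                perp = abs(dr * d[1] - dc * d[0])
                proj = dr * d[0] + dc * d[1] - 0.75 * perp
                if proj > best_proj:
                    best_proj, best_px = proj, (r, c)
    tip = np.array(best_px, dtype=float) + 0.5 * d
    return float(tip[0]), float(tip[1])


def classify_tips(
    endpoints: list[tuple[int, int]],
    mask: np.ndarray,
    skeleton: np.ndarray | None = None,
    config: DetectorConfig | None = None,
    gsd: float | None = None,
    refine_mask: np.ndarray | None = None,
) -> list[Detection]:
    """Keep skeleton endpoints whose local blade tapers toward them.

    The Euclidean distance transform of the mask measures the local blade
    half-width.  With a known ground sampling distance the endpoint
    half-width is converted to mm and compared against the maximum
    physical width of a blade tip (``tip_max_width_mm``); without one the
    endpoint value must fall below ``taper_ratio`` of the median along the
    incident skeleton branch.  ``refine_mask`` (default: the mask itself)
    is the support the sub-pixel tip refinement may march over.
    """
    cfg = config or DetectorConfig()
    mask = np.asarray(mask, dtype=bool)
    if refine_mask is None:
        refine_mask = mask
    if skeleton is None:
        skeleton = skeletonize(mask) if mask.any() else np.zeros_like(mask)
    if not endpoints:
        return []
    dt = ndimage.distance_transform_edt(mask)
    dets: list[Detection] = []
    H, W = mask.shape
    for ep in endpoints:
        branch = _trace_branch(skeleton, ep, cfg.branch_window)
        if len(branch) < cfg.min_branch:
            continue
        if _foreign_skeleton_nearby(skeleton, ep, branch, cfg.junction_radius):
            continue
        vals = np.array([dt[p] for p in branch])
        med = float(np.median(vals))
        if med < 1e-9:
            continue
        ratio = float(dt[ep]) / med
        if gsd is not None:
            half_width_mm = float(dt[ep]) * gsd
            if half_width_mm > cfg.tip_max_width_mm:
                continue
            score = float(np.clip(1.0 - half_width_mm / cfg.tip_max_width_mm,
                                  0.0, 1.0))
        else:
            if ratio >= cfg.taper_ratio:
                continue
            score = float(np.clip(1.0 - ratio, 0.0, 1.0))
        inner = np.array(branch[min(len(branch) - 1, cfg.min_branch)], dtype=float)
        direction = np.array(ep, dtype=float) - inner
        r, c = _refine_tip(refine_mask, ep, direction, cfg.refine_max_px)
        if _ring_occupancy(mask, r, c, cfg.ring_radius) > cfg.max_ring_occupancy:
            continue
        if not (cfg.border_margin <= c < W - cfg.border_margin
                and cfg.border_margin <= r < H - cfg.border_margin):
            continue
        dets.append(Detection(center_u=float(c), center_v=float(r), score=score))
    return dets


def _foreign_skeleton_nearby(skeleton: np.ndarray, ep: tuple[int, int],
                             branch: list[tuple[int, int]], radius: int) -> bool:
    """True when skeleton pixels not on the endpoint's own branch lie within
    ``radius`` of the endpoint (the endpoint sits where limbs converge)."""
    H, W = skeleton.shape
    r0, c0 = ep
    j0, j1 = max(r0 - radius, 0), min(r0 + radius, H - 1)
    i0, i1 = max(c0 - radius, 0), min(c0 + radius, W - 1)
    window = skeleton[j0 : j1 + 1, i0 : i1 + 1]
    count = int(window.sum())
    own = sum(1 for (r, c) in branch if j0 <= r <= j1 and i0 <= c <= i1)
    return count - own >= 2


def _ring_occupancy(mask: np.ndarray, r: float, c: float, radius: int) -> float:
    """Fraction of a 32-point ring around (r, c) that lies on the mask.

    Out-of-image ring samples count as empty, so tips near the border are
    not penalized.
    """
    H, W = mask.shape
    ang = np.linspace(0.0, 2 * np.pi, 32, endpoint=False)
    rr = np.round(r + radius * np.sin(ang)).astype(int)
    cc = np.round(c + radius * np.cos(ang)).astype(int)
    ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
    return float(mask[rr[ok], cc[ok]].sum()) / len(ang)


def detect(
    rgb: np.ndarray, gsd: float | None = None, config: DetectorConfig | None = None
) -> list[Detection]:
    """Full classical pipeline: mask -> skeleton endpoints -> tip test.

    The tip-refinement march is allowed to follow a relaxed excess-green
    support (``refine_soft_frac`` x the Otsu threshold): at the extreme tip
    the blade is narrower than a pixel, so mixed leaf/soil pixels below the
    hard threshold still trace it.  Deterministic: the same image always
    yields identical detections.
    """
    cfg = config or DetectorConfig()
    mask = vegetation_mask(rgb, cfg.opening_radius)
    rgb = np.asarray(rgb, dtype=float)
    exg = 2.0 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]
    soft = mask
    if mask.any() and np.ptp(exg) > 1e-12:
        thr = threshold_otsu(exg)
        if thr > 0:
            soft = mask | (exg > cfg.refine_soft_frac * thr)
    skel, endpoints = skeleton_endpoints(mask)
    return classify_tips(endpoints, mask, skel, cfg, gsd, refine_mask=soft)


def detections_to_dicts(dets: list[Detection]) -> list[dict]:
    """Serialize detections in the annotation dialect plus a score field."""
    return [
        {"center": [d.center_u, d.center_v], "bbox": list(d.box), "score": d.score}
        for d in dets
    ]


def detections_from_dicts(items: list[dict]) -> list[Detection]:
    return [
        Detection(center_u=it["center"][0], center_v=it["center"][1],
                  score=it["score"])
        for it in items
    ]
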