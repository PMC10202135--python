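"""Sim-to-real domain-gap quantification.

Two image datasets are compared by (1) extracting a fixed-length feature
vector per image, (2) optionally embedding all vectors jointly into 2-D
with t-SNE for visual inspection, and (3) reducing the mismatch to one
scalar: the Euclidean distance between the two dataset centroids after
per-dimension standardization over the pooled features,

    d(A, B) = sqrt( sum_i (xbar_i - ybar_i)^2 ).

The default extractor is handcrafted (color histograms, gradient
orientations, texture-energy statistics; 61 dimensions) so the measure
runs without any trained network; any callable mapping an image to a
fixed-length vector can be plugged in instead — e.g. features exported
from a detection network's region-proposal layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.manifold import TSNE

__all__ = [
    "FeatureMatrix",
    "GapResult",
    "extract_features",
    "embed_2d",
    "dataset_distance",
    "HANDCRAFTED_DIM",
]

#: 3 channels x 16 color bins + 8 gradient-orientation bins + 5 texture stats
HANDCRAFTED_DIM = 61


@dataclass
class FeatureMatrix:
    """(n_images, d) feature rows plus the extractor identity."""

    rows: np.ndarray
    extractor: str = "handcrafted"

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("feature matrix must be finite")

    @property
    def dim(self) -> int:
        return self.rows.shape[1]


@dataclass
class GapResult:
    """2-D embedding of both datasets and their scalar distance."""

    embedding: np.ndarray
    labels: np.ndarray  # 0 for dataset A, 1 for dataset B
    distance: float
    extractor: str
    seed: int
    kl_divergence: float | None = None


def _handcrafted_features(img: np.ndarray) -> np.ndarray:
    """61-D descriptor: color histograms, edge orientations, texture energy."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    feats = []
    for c in range(3):
        hist, _ = np.histogram(img[..., c], bins=16, range=(0.0, 1.0))
        feats.append(hist / img[..., c].size)
    gray = img.mean(axis=2)
    gx = ndimage.sobel(gray, axis=1)
    gy = ndimage.sobel(gray, axis=0)
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx)  # [-pi, pi]
    ohist, _ = np.histogram(ang, bins=8, range=(-np.pi, np.pi), weights=mag)
    total = ohist.sum()
    feats.append(ohist / total if total > 0 else ohist)
    lap = ndimage.laplace(gray)
    local_rng = ndimage.maximum_filter(gray, 3) - ndimage.minimum_filter(gray, 3)
    feats.append(
        np.array(
            [gray.std(), np.abs(gx).mean(), np.abs(gy).mean(),
             np.abs(lap).mean(), local_rng.mean()]
        )
    )
    return np.concatenate(feats)


def extract_features(images: list[np.ndarray], extractor="handcrafted") -> FeatureMatrix:
    """Per-image feature vectors.

    ``extractor`` is either ``"handcrafted"`` or any callable mapping one
    image to a 1-D vector (constant length across images).
    """
    if len(images) == 0:
        raise ValueError("image list must be non-empty")
    channels = {im.shape[2] if im.ndim == 3 else 1 for im in images}
    if len(channels) != 1:
        raise ValueError("images must share channel count")
    if callable(extractor):
        fn, name = extractor, getattr(extractor, "__name__", "custom")
    else:
        fn, name = _handcrafted_features, "handcrafted"
    rows = np.stack([np.asarray(fn(im), dtype=float).ravel() for im in images])
    return FeatureMatrix(rows=rows, extractor=name)


def embed_2d(
    features: FeatureMatrix, perplexity: float = 30.0, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Joint t-SNE embedding to 2-D; returns (coords, KL divergence).

    Perplexity is clamped below (rows - 1) / 3; at least 5 rows are
    required for a meaningful neighbourhood structure.
    """
    n = len(features.rows)
    if n < 5:
        raise ValueError(f"need >= 5 rows for t-SNE, got {n}")
    if float(features.rows.var(axis=0).sum()) < 1e-24:
        # all rows identical: the embedding degenerates to a single point
        # (t-SNE itself cannot initialize on zero-variance input)
        return np.zeros((n, 2)), 0.0
    perplexity = min(perplexity, (n - 1) / 3.0 - 1e-9)
    ts = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca",
        max_iter=500,
    )
    coords = ts.fit_transform(features.rows)
    return coords, float(ts.kl_divergence_)


def dataset_distance(
    a: FeatureMatrix | np.ndarray,
    b: FeatureMatrix | np.ndarray,
    space: str = "feature",
    perplexity: float = 30.0,
    seed: int = 0,
) -> float:
    """Centroid-to-centroid Euclidean distance between two datasets.

    ``space="feature"``: per-dimension standardization over the pooled rows
    of A and B, then the distance between the two standardized centroids.
    ``space="embedding"``: the same computed on a joint 2-D t-SNE embedding
    (no further standardization; the embedding fixes the scale).
    """
    ra = a.rows if isinstance(a, FeatureMatrix) else np.atleast_2d(np.asarray(a, float))
    rb = b.rows if isinstance(b, FeatureMatrix) else np.atleast_2d(np.asarray(b, float))
    if ra.shape[1] != rb.shape[1]:
        raise ValueError("feature dimensions differ")
    if isinstance(a, FeatureMatrix) and isinstance(b, FeatureMatrix):
        if a.extractor != b.extractor:
            raise ValueError("datasets use different extractors")
    if space == "embedding":
        joint = FeatureMatrix(np.vstack([ra, rb]))
        coords, _ = embed_2d(joint, perplexity=perplexity, seed=seed)
        ca = coords[: len(ra)].mean(axis=0)
        cb = coords[len(ra) :].mean(axis=0)
        return float(np.linalg.norm(ca - cb))
    if space != "feature":
        raise ValueError("space must be 'feature' or 'embedding'")
    pooled = np.vstack([ra, rb])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    ca = ((ra - mu) / sd).mean(axis=0)
    cb = ((rb - mu) / sd).mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def gap_analysis(
    images_a: list[np.ndarray],
    images_b: list[np.ndarray],
    extractor="handcrafted",
    perplexity: float = 30.0,
    seed: int = 0,
) -> GapResult:
    """Full gap pipeline: features -> joint embedding -> scalar distance."""
    fa = extract_features(images_a, extractor)
    fb = extract_features(images_b, extractor)
    dist = dataset_distance(fa, fb, space="feature")
    joint = FeatureMatrix(np.vstack([fa.rows, fb.rows]), extractor=fa.extractor)
    kl = None
    coords = np.zeros((len(joint.rows), 2))
    if len(joint.rows) >= 5:
        coords, kl = embed_2d(joint, perplexity=perplexity, seed=seed)
    labels = np.concatenate([np.zeros(len(fa.rows)), np.ones(len(fb.rows))])
    return GapResult(embedding=coords, labels=labels, distance=dist,
                     extractor=fa.extractor, seed=seed, kl_divergence=kl)
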