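"""Ultrasound habitat discovery.

The lesion ROI is over-segmented into superpixels by K-means in the joint
(intensity, compactness-scaled coordinate) space with regular-grid seeding
and connectivity enforcement (the SLIC construction). Each superpixel is
profiled (mean, SD, local entropy, local contrast, centroid), and the
profiles are clustered by K-means; the habitat count is chosen by the
Calinski-Harabasz index over a candidate range, or pinned by the caller.

Habitat ids are renumbered by descending mean intensity so "habitat 2 =
hypoechoic heterogeneous" is reproducible as a rank, not a cluster id.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.segmentation import slic, relabel_sequential
from sklearn.cluster import KMeans

from ._types import (
    AnnotatedImage,
    EmptyInputError,
    HabitatMap,
    SuperpixelMap,
    SuperpixelProfile,
)

__all__ = [
    "superpixel_oversegment",
    "profile_superpixels",
    "calinski_harabasz",
    "cluster_habitats",
    "habitats_from_image",
]

#: Sentinel returned when within-cluster dispersion is exactly zero.
CH_INF = 1e12

PROFILE_COLUMNS_2D = ("mean", "sd", "entropy", "contrast", "cy", "cx")


def superpixel_oversegment(image: AnnotatedImage, n_superpixels: int = 60,
                           compactness: float = 0.2,
                           seed: int = 0) -> SuperpixelMap:
    """Over-segment the ROI into at most ``n_superpixels`` connected units.

    K-means in the joint (intensity, compactness-scaled coordinates) space,
    seeded on a regular grid inside the ROI, with post-hoc connectivity
    enforcement. The construction is deterministic; ``seed`` is accepted
    for interface uniformity.

    Returns a :class:`SuperpixelMap` with ``S <= n_superpixels`` labels
    that partition the ROI exactly.
    """
    mask = image.mask
    roi = int(mask.sum())
    if roi == 0:
        raise EmptyInputError("ROI mask is empty")
    if n_superpixels < 2:
        raise ValueError("n_superpixels must be >= 2")
    if n_superpixels > roi:
        raise ValueError("n_superpixels exceeds ROI pixel count")
    if n_superpixels == roi:
        # Saturation: every ROI pixel its own superpixel.
        labels = np.zeros(mask.shape, dtype=np.int64)
        labels[mask] = np.arange(1, roi + 1)
        return SuperpixelMap(labels=labels, n_superpixels=roi)

    img = image.image.astype(float)
    rng = img[mask].max() - img[mask].min()
    norm = (img - img[mask].min()) / (rng if rng > 0 else 1.0)
    labels = slic(
        norm,
        n_segments=n_superpixels,
        compactness=compactness,
        mask=mask,
        start_label=1,
        channel_axis=None,
        # relative spacing: only anisotropy matters to the joint space
        spacing=tuple(s / min(image.spacing) for s in image.spacing),
        enforce_connectivity=True,
    )
    labels, _, _ = relabel_sequential(labels)
    s = int(labels.max())
    if s < 1:
        raise RuntimeError("over-segmentation produced no superpixels")
    return SuperpixelMap(labels=labels.astype(np.int64), n_superpixels=s)


def _entropy_bits(values: np.ndarray, bins: int = 32) -> float:
    """Shannon entropy (bits) of a fixed-bin histogram of ``values``."""
    counts, _ = np.histogram(values, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def profile_superpixels(image: AnnotatedImage,
                        spmap: SuperpixelMap) -> SuperpixelProfile:
    """Compute per-superpixel clustering features.

    One row per superpixel: mean intensity, population SD, 32-bin histogram
    entropy, local contrast (max - min of member pixels), and centroid
    coordinates in pixels.
    """
    if image.image.shape != spmap.labels.shape:
        raise ValueError("image and superpixel map are not aligned")
    img = image.image.astype(float)
    lab = spmap.labels
    s = spmap.n_superpixels
    idx = range(1, s + 1)
    means = ndimage.mean(img, lab, idx)
    sds = np.sqrt(ndimage.variance(img, lab, idx))
    mins = ndimage.minimum(img, lab, idx)
    maxs = ndimage.maximum(img, lab, idx)
    cents = np.asarray(ndimage.center_of_mass(np.ones_like(img), lab, list(idx)))
    ents = np.array([_entropy_bits(img[lab == i]) for i in idx])
    values = np.column_stack([means, sds, ents, maxs - mins, cents])
    cols = PROFILE_COLUMNS_2D[:4] + tuple(
        f"c{ax}" for ax in ("z", "y", "x")[-img.ndim:]
    )
    return SuperpixelProfile(values=values, columns=cols)


def calinski_harabasz(points: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index: [B/(k-1)] / [W/(n-k)].

    B is the between-cluster dispersion (cluster sizes times squared
    distances of cluster means to the grand mean) and W the within-cluster
    dispersion about cluster means. Well-separated tight clusters score
    high; random labels on isotropic noise score ~1. If W is exactly zero
    the capped sentinel ``CH_INF`` is returned.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = x.shape[0], len(uniq)
    if k < 2 or k >= n:
        raise ValueError("Calinski-Harabasz requires 2 <= k < n")
    grand = x.mean(axis=0)
    b = 0.0
    w = 0.0
    for u in uniq:
        xu = x[labels == u]
        mu = xu.mean(axis=0)
        b += len(xu) * float(((mu - grand) ** 2).sum())
        w += float(((xu - mu) ** 2).sum())
    if w <= 0.0:
        return CH_INF
    return (b / (k - 1)) / (w / (n - k))


def _order_by_intensity(cluster_of_sp: np.ndarray, profiles: SuperpixelProfile,
                        spmap: SuperpixelMap):
    """Renumber cluster ids 1..K by descending superpixel-weighted mean
    intensity and paint the map."""
    lab = spmap.labels
    sizes = np.bincount(lab.ravel())[1:].astype(float)
    means = profiles.values[:, 0]
    k = int(cluster_of_sp.max()) + 1
    cluster_mean = np.array([
        np.average(means[cluster_of_sp == c], weights=sizes[cluster_of_sp == c])
        for c in range(k)
    ])
    order = np.argsort(-cluster_mean)           # descending intensity
    rank_of = np.empty(k, dtype=np.int64)
    rank_of[order] = np.arange(1, k + 1)
    habitat_of_sp = rank_of[cluster_of_sp]

    painted = np.zeros_like(lab)
    inside = lab > 0
    painted[inside] = habitat_of_sp[lab[inside] - 1]
    counts = np.bincount(painted[inside], minlength=k + 1)[1:]
    fractions = counts / counts.sum()
    return HabitatMap(labels=painted, n_habitats=k, fractions=fractions)


def cluster_habitats(profiles: SuperpixelProfile, spmap: SuperpixelMap,
                     k_range=range(2, 7), seed: int = 0,
                     texture_weight: float = 0.1,
                     location_weight: float = 0.25,
                     n_restarts: int = 10):
    """Cluster superpixel profiles into habitats with CH model selection.

    Profile columns are z-scored; mean intensity carries full weight (it
    is the echogenicity phenotype), while the secondary texture columns
    (SD, entropy, contrast) are down-weighted by ``texture_weight`` and
    the centroid coordinates by ``location_weight`` — enough for spatial
    coherence to contribute without splintering habitats on speckle
    statistics. K-means (``n_restarts`` restarts, k-means++ seeding from
    ``seed``, tol 1e-6, 300 iterations) is run for every k in ``k_range``;
    the k maximizing the Calinski-Harabasz index is kept, with ties broken
    toward the smallest k.

    Returns ``(habitat_map, ch_scores)`` where ``ch_scores`` maps each
    candidate k to its CH score. Pass a single-element ``k_range`` to pin
    K (e.g. ``[4]`` for the four-habitat ultrasound convention).
    """
    x = profiles.values.copy()
    n = x.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > 8:
        raise ValueError("k_range must lie within [2, 8]")
    if n <= ks[-1]:
        raise ValueError("too few superpixels for the requested k_range")

    sd = x.std(axis=0)
    x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    is_coord = np.array([c.startswith("c") for c in profiles.columns])
    is_texture = np.array([c in ("sd", "entropy", "contrast")
                           for c in profiles.columns])
    x[:, is_texture] *= texture_weight
    x[:, is_coord] *= location_weight

    ch_scores = {}
    labelings = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, tol=1e-6, max_iter=300,
                    random_state=seed, init="k-means++")
        lab = km.fit_predict(x)
        if len(np.unique(lab)) < 2 or k >= n:
            ch_scores[k] = -np.inf
        else:
            ch_scores[k] = calinski_harabasz(x, lab)
        labelings[k] = lab
    # argmax CH; ties (within exact equality) resolve to the smallest k
    # because iteration is ascending and strict inequality is required.
    best_k = ks[0]
    for k in ks[1:]:
        if ch_scores[k] > ch_scores[best_k]:
            best_k = k
    habmap = _order_by_intensity(labelings[best_k], profiles, spmap)
    return habmap, ch_scores


def habitats_from_image(image: AnnotatedImage, n_superpixels: int = 100,
                        compactness: float = 0.2, k_range=range(2, 7),
                        seed: int = 0, despeckle_size: int = 3):
    """Convenience pipeline: despeckle, over-segment, profile, cluster.

    A small median filter (edge-preserving) suppresses multiplicative
    speckle before over-segmentation so superpixels adhere to echotexture
    boundaries; set ``despeckle_size=0`` to skip it. Per-patient
    clustering is the default operating mode.

    Returns ``(habitat_map, ch_scores)``.
    """
    if despeckle_size and despeckle_size > 1:
        image = AnnotatedImage(
            ndimage.median_filter(image.image, size=despeckle_size),
            image.mask, image.spacing)
    spmap = superpixel_oversegment(image, n_superpixels, compactness, seed)
    profiles = profile_superpixels(image, spmap)
    return cluster_habitats(profiles, spmap, k_range=k_range, seed=seed)
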