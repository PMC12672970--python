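"""CT habitat discovery in 3D: supervoxels and two-stage clustering.

Each lesion is over-segmented into supervoxels (K-means in joint
HU/millimetre-coordinate space honouring anisotropic spacing). Habitats are
then found cohort-wide by two-stage clustering: stage 1 clusters each
patient's supervoxel profiles into a small number of local clusters; stage 2
pools all local-cluster centroids (weighted by member volume) and clusters
them into K population habitats shared by every patient. The resulting
palette is ordered by descending mean HU so habitat i has the same
density-rank meaning in all patients.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.segmentation import slic, relabel_sequential
from sklearn.cluster import KMeans

from ._types import AnnotatedImage, EmptyInputError, HabitatMap, HabitatPalette
from .habitat_us import _entropy_bits, calinski_harabasz

__all__ = [
    "supervoxel_oversegment",
    "profile_supervoxels",
    "two_stage_cluster",
    "select_k_final",
    "HU_WINDOW",
]

log = logging.getLogger(__name__)

#: Soft-tissue HU window applied before supervoxel segmentation; robust to
#: calcification outliers in thyroid lesions.
HU_WINDOW = (-100.0, 200.0)

PROFILE_COLUMNS_3D = ("mean_hu", "sd", "entropy")


def supervoxel_oversegment(volume: AnnotatedImage, n_supervoxels: int = 150,
                           compactness: float = 0.2, seed: int = 0):
    """Over-segment a 3D ROI into connected supervoxels.

    HU values are clipped to the soft-tissue window and min-max scaled;
    K-means runs in (HU, compactness-scaled x/y/z in mm) with grid seeding
    and connectivity enforcement, so anisotropic spacing is honoured via
    millimetre coordinates. Deterministic; ``seed`` kept for interface
    uniformity.

    Returns ``(supervoxel_map, profile)`` where the profile holds one row
    per supervoxel: mean HU (window-clipped), SD, 32-bin entropy.
    """
    from ._types import SuperpixelMap, SuperpixelProfile

    if volume.ndim != 3:
        raise ValueError("supervoxel segmentation expects a 3D volume")
    mask = volume.mask
    roi = int(mask.sum())
    if roi == 0:
        raise EmptyInputError("ROI mask is empty")
    if n_supervoxels < 2:
        raise ValueError("n_supervoxels must be >= 2")
    if n_supervoxels > roi:
        raise ValueError("n_supervoxels exceeds ROI voxel count")

    lo, hi = HU_WINDOW
    clipped = np.clip(volume.image.astype(float), lo, hi)
    norm = (clipped - lo) / (hi - lo)
    labels = slic(
        norm,
        n_segments=n_supervoxels,
        compactness=compactness,
        mask=mask,
        start_label=1,
        channel_axis=None,
        # relative spacing: only anisotropy matters to the joint space
        spacing=tuple(s / min(volume.spacing) for s in volume.spacing),
        enforce_connectivity=True,
    )
    labels, _, _ = relabel_sequential(labels)
    s = int(labels.max())
    spmap = SuperpixelMap(labels=labels.astype(np.int64), n_superpixels=s)

    idx = range(1, s + 1)
    means = ndimage.mean(clipped, labels, idx)
    sds = np.sqrt(ndimage.variance(clipped, labels, idx))
    ents = np.array([_entropy_bits(clipped[labels == i]) for i in idx])
    profile = SuperpixelProfile(values=np.column_stack([means, sds, ents]),
                                columns=PROFILE_COLUMNS_3D)
    return spmap, profile


def profile_supervoxels(volume: AnnotatedImage, spmap):
    """Recompute the (mean HU, SD, entropy) profile for an existing map."""
    lo, hi = HU_WINDOW
    clipped = np.clip(volume.image.astype(float), lo, hi)
    labels = spmap.labels
    idx = range(1, spmap.n_superpixels + 1)
    means = ndimage.mean(clipped, labels, idx)
    sds = np.sqrt(ndimage.variance(clipped, labels, idx))
    ents = np.array([_entropy_bits(clipped[labels == i]) for i in idx])
    from ._types import SuperpixelProfile
    return SuperpixelProfile(values=np.column_stack([means, sds, ents]),
                             columns=PROFILE_COLUMNS_3D)


#: Weight applied to the z-scored secondary profile columns (SD, entropy).
#: Mean HU is the density phenotype; near-constant secondary columns would
#: otherwise have their noise amplified to full scale by the z-scoring.
SECONDARY_WEIGHT = 0.1


def _cohort_zscore(profiles, secondary_weight=SECONDARY_WEIGHT):
    """Pool all patients' profile rows; return per-column mean/SD/weights."""
    pooled = np.vstack([p.values for p in profiles])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    w = np.full(pooled.shape[1], secondary_weight)
    w[0] = 1.0
    return mu, sd, w


def two_stage_cluster(maps, profiles, k_stage1: int = 6, k_final: int = 5,
                      seed: int = 0):
    """Cohort-consistent habitat discovery by two-stage K-means.

    Stage 1 clusters each patient's supervoxel profiles (cohort z-scored)
    into ``k_stage1`` local clusters; a patient with fewer supervoxels than
    ``k_stage1`` is clustered with k equal to its supervoxel count and a
    warning is logged. Stage 2 pools every local-cluster centroid, weighted
    by its member voxel volume, and K-means them into ``k_final``
    population habitats. Each supervoxel inherits the population habitat of
    its local cluster. Pooling order follows patient index, so the result
    is a pure function of the inputs and ``seed``.

    Parameters
    ----------
    maps, profiles : lists
        Per-patient supervoxel maps and aligned profiles.
    k_stage1 : int
        Local cluster count per patient (> k_final recommended so stage 2
        can merge).
    k_final : int
        Population habitat count (the five-habitat CT convention by
        default).

    Returns
    -------
    palette : HabitatPalette
        ``k_final`` stage-2 centroids in profile space, ordered by
        descending mean HU.
    habitat_maps : list of HabitatMap
        Per-patient habitat labelling, ids consistent with the palette.
    """
    if len(maps) == 0:
        raise ValueError("cohort is empty")
    if len(maps) != len(profiles):
        raise ValueError("maps and profiles must be aligned")
    mu, sd, w = _cohort_zscore(profiles)

    centroids = []          # stage-2 input points (z-scored profile space)
    weights = []            # voxel volume per local cluster
    member_of = []          # per patient: local-cluster id per supervoxel
    offsets = []            # start index of each patient's local clusters
    for pi, (m, p) in enumerate(zip(maps, profiles)):
        z = (p.values - mu) / sd * w
        n_sv = z.shape[0]
        k1 = min(k_stage1, n_sv)
        if k1 < k_stage1:
            log.warning("patient %d has %d supervoxels < k_stage1=%d; "
                        "clustering with k=%d", pi, n_sv, k_stage1, k1)
        if k1 == n_sv:
            local = np.arange(n_sv)
        else:
            km = KMeans(n_clusters=k1, n_init=10, tol=1e-6, max_iter=300,
                        random_state=seed)
            local = km.fit_predict(z)
        sizes = np.bincount(m.labels.ravel())[1:].astype(float)
        offsets.append(len(centroids))
        for c in range(local.max() + 1):
            in_c = local == c
            centroids.append(np.average(z[in_c], axis=0, weights=sizes[in_c]))
            weights.append(sizes[in_c].sum())
        member_of.append(local)

    pts = np.asarray(centroids)
    wts = np.asarray(weights)
    if pts.shape[0] < k_final:
        raise ValueError("fewer pooled local clusters than k_final")
    km2 = KMeans(n_clusters=k_final, n_init=10, tol=1e-6, max_iter=300,
                 random_state=seed)
    km2.fit(pts, sample_weight=wts)
    pop_of_local = km2.labels_

    # Order population habitats by descending mean HU (first profile column,
    # un-z-scored for interpretability).
    centers = km2.cluster_centers_ / w * sd + mu
    order = np.argsort(-centers[:, 0])
    rank_of = np.empty(k_final, dtype=np.int64)
    rank_of[order] = np.arange(1, k_final + 1)

    palette = HabitatPalette(centroids=centers[order],
                             columns=profiles[0].columns)

    habitat_maps = []
    for pi, (m, local) in enumerate(zip(maps, member_of)):
        hab_of_sv = rank_of[pop_of_local[offsets[pi] + local]]
        lab = m.labels
        painted = np.zeros_like(lab)
        inside = lab > 0
        painted[inside] = hab_of_sv[lab[inside] - 1]
        counts = np.bincount(painted[inside], minlength=k_final + 1)[1:]
        habitat_maps.append(HabitatMap(labels=painted, n_habitats=k_final,
                                       fractions=counts / counts.sum()))
    return palette, habitat_maps


def _inherited_labels(maps, habitat_maps):
    """Population habitat id per supervoxel, pooled over patients."""
    labs = []
    for hm, m in zip(habitat_maps, maps):
        lab = np.zeros(m.n_superpixels, dtype=np.int64)
        flat_sv = m.labels.ravel()
        flat_h = hm.labels.ravel()
        sel = flat_sv > 0
        lab[flat_sv[sel] - 1] = flat_h[sel]
        labs.append(lab)
    return np.concatenate(labs)


def select_k_final(maps, profiles, k_range=range(2, 9), k_stage1: int = 6,
                   seed: int = 0, flat_tolerance: float = 0.15):
    """Choose the population habitat count by the Calinski-Harabasz index.

    For each k in ``k_range`` the two-stage clustering is run; the CH
    index is scored on the pooled (z-scored, weighted) supervoxel profiles
    labelled by their inherited population habitat, i.e. on the same
    points the habitats ultimately partition. Returns
    ``(best_k, ch_scores, low_confidence)`` where ``low_confidence`` flags
    a CH curve flat to within ``flat_tolerance`` (relative spread), the
    signature of a cohort with no planted structure; ties break toward the
    smallest k.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > 8:
        raise ValueError("k_range must lie within [2, 8]")
    mu, sd, w = _cohort_zscore(profiles)
    pooled = np.vstack([(p.values - mu) / sd * w for p in profiles])

    ch_scores = {}
    for k in ks:
        if pooled.shape[0] <= k:
            ch_scores[k] = -np.inf
            continue
        _, hms = two_stage_cluster(maps, profiles, k_stage1=k_stage1,
                                   k_final=k, seed=seed)
        lab = _inherited_labels(maps, hms)
        if len(np.unique(lab)) < 2:
            ch_scores[k] = -np.inf
        else:
            ch_scores[k] = calinski_harabasz(pooled, lab)
    best_k = ks[0]
    for k in ks[1:]:
        if ch_scores[k] > ch_scores[best_k]:
            best_k = k
    finite = np.array([v for v in ch_scores.values() if np.isfinite(v)])
    low_confidence = False
    if len(finite) >= 2 and finite.mean() > 0:
        # flat CH curve (relative dispersion below tolerance): no evidence
        # for any particular habitat count
        low_confidence = float(finite.std() / finite.mean()) < flat_tolerance
    return best_k, ch_scores, low_confidence
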