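"""Multi-Scale Index (MSI): a 120-feature spatial-heterogeneity catalog.

Given a CT intensity volume, its tumor mask and a five-habitat map, the
extractor emits a fixed, ordered 120-element vector quantifying habitat
composition and spatial architecture:

====================  =========================================================
MSI 1-4               GLCM statistics of the habitat label texture
                      (contrast, correlation, energy, homogeneity)
MSI 5-9               habitat volumes Vol(H1)..Vol(H5), voxel counts
MSI 10-14             habitat-boundary interactions Hi ∩ Border
MSI 15-24             pairwise co-occurrences H1H2..H4H5 (face adjacency)
MSI 25-29             volumes normalized by total tumor volume
MSI 30-44             border + pair interactions normalized by total volume
MSI 45-59             Gabor mean magnitude, Haar wavelet detail-energy
                      fraction, LBP histogram entropy (per habitat)
MSI 60-74             surface area, convexity, sphericity (per habitat)
MSI 75-94             intensity mean, SD, skewness, excess kurtosis
MSI 95-114            intensity entropy, box-counting fractal dimension,
                      connectivity, eccentricity (per habitat)
MSI 115-120           global descriptors (entropy, multiscale variance,
                      pattern complexity, architectural index, tumor
                      signature, integrated heterogeneity)
====================  =========================================================

All interactions use face (6-) adjacency. Absent habitats contribute 0 to
count/volume features and 0 with a missing flag to intensity statistics, so
the vector length is always exactly 120.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage, stats
from scipy.spatial import ConvexHull, QhullError
from skimage.feature import local_binary_pattern
from skimage.filters import gabor
from skimage.measure import marching_cubes, mesh_surface_area

from ._types import FeatureBlock, HabitatMap

__all__ = [
    "MSIVector",
    "MSI_NAMES",
    "MSI_GROUP_SIZES",
    "msi_glcm_stats",
    "msi_volumes_and_interactions",
    "msi_normalized_interactions",
    "msi_texture_bank",
    "msi_morphology",
    "msi_intensity_moments",
    "msi_complexity",
    "msi_global",
    "msi_extract",
    "extract_msi_cohort",
    "fscore_rank",
    "PAIR_ORDER",
]

N_HABITATS = 5
#: Habitat pair ordering for MSI 15-24 / 39-44 blocks.
PAIR_ORDER = [(1, 2), (1, 3), (1, 4), (1, 5), (2, 3), (2, 4), (2, 5),
              (3, 4), (3, 5), (4, 5)]
#: Group sizes, in catalog order.
MSI_GROUP_SIZES = (4, 5, 5, 10, 5, 15, 15, 15, 20, 20, 6)
MSI_NAMES = tuple(f"MSI_{i}" for i in range(1, 121))

#: Gabor filter defaults: one frequency, four orientations collapsed to the
#: per-habitat mean magnitude (slice-wise).
GABOR_FREQUENCY = 0.15
GABOR_ORIENTATIONS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

_EPS = 1e-12


@dataclass(frozen=True)
class MSIVector:
    """Ordered 120-element named MSI feature vector for one tumor."""

    values: np.ndarray
    names: tuple = MSI_NAMES
    missing_habitats: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (120,):
            raise ValueError("MSI vector must have exactly 120 entries")
        if not np.all(np.isfinite(v)):
            raise ValueError("MSI entries must be finite")
        object.__setattr__(self, "values", v)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def _check_labels(habmap: HabitatMap):
    lab = np.asarray(habmap.labels)
    inside = lab[lab > 0]
    if inside.size and inside.max() > N_HABITATS:
        raise ValueError("habitat labels must lie in 1..5")
    return lab


def _axis_offsets(ndim: int, full: bool):
    """Unique displacement vectors at Chebyshev distance 1.

    ``full=True`` gives the 13 unique 3D directions (half of the 26
    neighbors) used for the GLCM; ``full=False`` gives the 3 face
    directions used for adjacency counting.
    """
    if not full:
        return [tuple(1 if i == a else 0 for i in range(ndim))
                for a in range(ndim)]
    offs = []
    for d in np.ndindex(*([3] * ndim)):
        v = tuple(x - 1 for x in d)
        if all(x == 0 for x in v):
            continue
        if v < tuple(-x for x in v):
            continue
        offs.append(v)
    return offs


def _pair_counts(lab, offsets):
    """Accumulate co-occurrence counts of (label_a, label_b) over offsets.

    Only pairs with both voxels inside the ROI (label > 0) count. Returns
    a (K+1)x(K+1) matrix indexed by raw label; row/col 0 unused.
    """
    k = N_HABITATS
    counts = np.zeros((k + 1, k + 1), dtype=np.int64)
    for off in offsets:
        src = tuple(slice(None, -o) if o > 0 else slice(-o, None)
                    for o in off)
        dst = tuple(slice(o, None) if o > 0 else slice(None, o or None)
                    for o in off)
        a = lab[src]
        b = lab[dst]
        ok = (a > 0) & (b > 0)
        np.add.at(counts, (a[ok], b[ok]), 1)
    return counts


def msi_glcm_stats(habmap: HabitatMap):
    """MSI 1-4: Haralick statistics of the habitat-label co-occurrence.

    A symmetric, normalized gray-level co-occurrence matrix is built over
    habitat labels at distance 1, accumulated over the 13 unique 3D
    directions (restricted to voxel pairs inside the ROI), then reduced to
    contrast, correlation, energy and homogeneity.
    """
    lab = _check_labels(habmap)
    offsets = _axis_offsets(lab.ndim, full=True)
    counts = _pair_counts(lab, offsets)
    sym = counts + counts.T
    total = sym.sum()
    if total == 0:
        raise ValueError("single-voxel ROI: no voxel pairs for the GLCM")
    p = sym[1:, 1:] / total
    i = np.arange(1, N_HABITATS + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float((p * (ii - jj) ** 2).sum())
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())
    if var > _EPS:
        correlation = float((p * (ii - mu) * (jj - mu)).sum() / var)
    else:
        correlation = 1.0      # single occupied level: degenerate, perfectly correlated
    energy = float((p ** 2).sum())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    return np.array([contrast, correlation, energy, homogeneity])


def msi_volumes_and_interactions(habmap: HabitatMap, mask: np.ndarray):
    """MSI 5-29 raw material: volumes, border and pair interactions.

    Returns ``(volumes, border, pairs, norm_volumes)``:

    * ``volumes[i]`` — voxel count of habitat i+1;
    * ``border[i]`` — habitat-(i+1) voxels with at least one face neighbor
      outside the tumor mask (array boundary counts as outside);
    * ``pairs`` — the 10 unordered face-adjacent voxel-pair counts in
      :data:`PAIR_ORDER`, each adjacent pair counted once;
    * ``norm_volumes`` — volumes divided by the total ROI volume.
    """
    lab = _check_labels(habmap)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != lab.shape:
        raise ValueError("mask and habitat map are not aligned")
    volumes = np.bincount(lab[lab > 0], minlength=N_HABITATS + 1)[1:].astype(float)
    total = volumes.sum()
    if total == 0:
        raise ValueError("empty habitat map")

    # Border voxels: any face neighbor outside the mask.
    outside_touch = np.zeros(lab.shape, dtype=bool)
    for ax in range(lab.ndim):
        for side in (1, -1):
            shifted = np.roll(mask, side, axis=ax)
            # Voxels rolled in from the far edge are outside by definition.
            edge = [slice(None)] * lab.ndim
            edge[ax] = 0 if side == 1 else -1
            shifted[tuple(edge)] = False
            outside_touch |= mask & ~shifted
    border = np.array([
        float(np.count_nonzero(outside_touch & (lab == h)))
        for h in range(1, N_HABITATS + 1)
    ])

    counts = _pair_counts(lab, _axis_offsets(lab.ndim, full=False))
    sym = counts + counts.T
    pairs = np.array([float(sym[i, j]) for i, j in PAIR_ORDER])
    return volumes, border, pairs, volumes / total


def msi_normalized_interactions(border: np.ndarray, pairs: np.ndarray,
                                total_volume: float):
    """MSI 30-44: the 5 border and 10 pair counts divided by total volume."""
    if total_volume <= 0:
        raise ZeroDivisionError("total tumor volume must be positive")
    return np.concatenate([np.asarray(border, float) / total_volume,
                           np.asarray(pairs, float) / total_volume])


def _gabor_magnitude(image2d: np.ndarray, frequency: float, theta: float):
    real, imag = gabor(image2d, frequency=frequency, theta=theta)
    return np.hypot(real, imag)


def msi_texture_bank(volume: np.ndarray, habmap: HabitatMap):
    """MSI 45-59: Gabor, wavelet and LBP texture per habitat.

    * Gabor (45-49): mean response magnitude over the habitat's voxels of a
      slice-wise 2D Gabor bank (one frequency, four orientations averaged).
    * Wavelet (50-54): single-level 3D Haar detail-energy fraction computed
      on the habitat's bounding box (non-member voxels filled with the
      habitat mean so edges do not leak in).
    * LBP (55-59): Shannon entropy (bits) of the uniform 8-neighbor LBP
      pattern histogram over the habitat's voxels, slice-wise.

    Returns ``(values, missing)``: 15 features and the per-habitat missing
    flags.
    """
    lab = _check_labels(habmap)
    vol = np.asarray(volume, dtype=float)
    if vol.shape != lab.shape:
        raise ValueError("volume and habitat map are not aligned")
    roi = lab > 0
    vmin, vmax = vol[roi].min(), vol[roi].max()
    norm = (vol - vmin) / (vmax - vmin) if vmax > vmin else np.zeros_like(vol)

    # Slice-wise filter responses, computed once for the full volume.
    gmag = np.zeros_like(norm)
    lbp = np.zeros_like(norm)
    for z in range(norm.shape[0]):
        sl = norm[z]
        acc = np.zeros_like(sl)
        for th in GABOR_ORIENTATIONS:
            acc += _gabor_magnitude(sl, GABOR_FREQUENCY, th)
        gmag[z] = acc / len(GABOR_ORIENTATIONS)
        # 8-bit quantization: LBP on floats is sensitive to rounding noise
        lbp[z] = local_binary_pattern(np.round(sl * 255).astype(np.int32),
                                      P=8, R=1.0, method="uniform")

    gabor_f = np.zeros(N_HABITATS)
    wave_f = np.zeros(N_HABITATS)
    lbp_f = np.zeros(N_HABITATS)
    missing = np.zeros(N_HABITATS, dtype=bool)
    for h in range(1, N_HABITATS + 1):
        sel = lab == h
        if not sel.any():
            missing[h - 1] = True
            continue
        gabor_f[h - 1] = float(gmag[sel].mean())

        # Haar detail-energy fraction on the habitat bounding box.
        idx = np.argwhere(sel)
        lo = idx.min(axis=0)
        hi = idx.max(axis=0) + 1
        sub = vol[tuple(slice(a, b) for a, b in zip(lo, hi))].copy()
        subsel = sel[tuple(slice(a, b) for a, b in zip(lo, hi))]
        sub[~subsel] = vol[sel].mean()
        coeffs = pywt.dwtn(sub, "haar")
        approx_key = "a" * sub.ndim
        detail = sum(float((c ** 2).sum()) for k, c in coeffs.items()
                     if k != approx_key)
        total = detail + float((coeffs[approx_key] ** 2).sum())
        wave_f[h - 1] = detail / total if total > _EPS else 0.0

        counts = np.bincount(lbp[sel].astype(np.int64), minlength=10)
        pr = counts[counts > 0] / counts.sum()
        lbp_f[h - 1] = float(-(pr * np.log2(pr)).sum())
    return np.concatenate([gabor_f, wave_f, lbp_f]), missing


def _face_area_surface(sel: np.ndarray, spacing):
    """Exposed-face surface area in mm^2 (neighbor outside the habitat)."""
    areas = []
    sp = np.asarray(spacing, dtype=float)
    face_area = [np.prod(np.delete(sp, ax)) for ax in range(sel.ndim)]
    total = 0.0
    for ax in range(sel.ndim):
        for side in (1, -1):
            shifted = np.roll(sel, side, axis=ax)
            edge = [slice(None)] * sel.ndim
            edge[ax] = 0 if side == 1 else -1
            shifted[tuple(edge)] = False
            total += float(np.count_nonzero(sel & ~shifted)) * face_area[ax]
    return total


def _mesh_area(sel: np.ndarray, spacing):
    """Marching-cubes surface area (mm^2); converges to the smooth limit."""
    padded = np.pad(sel.astype(float), 1)
    try:
        verts, faces, _, _ = marching_cubes(padded, level=0.5,
                                            spacing=tuple(spacing))
        return float(mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        return _face_area_surface(sel, spacing)


def msi_morphology(habmap: HabitatMap, spacing=(1.0, 1.0, 1.0)):
    """MSI 60-74: surface area, convexity, sphericity per habitat.

    Surface area (60-64) is the exposed-face count weighted by physical
    face areas (exact for boxes). Convexity (65-69) is habitat volume over
    convex-hull volume of the voxel corner lattice. Sphericity (70-74) is
    pi^(1/3) (6V)^(2/3) / A with A taken from a marching-cubes mesh, whose
    area converges to the smooth-surface limit (a staircase face count
    would bias sphericity low by ~1/3 for a ball).

    Returns ``(values, missing)``.
    """
    lab = _check_labels(habmap)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    sp = np.asarray(spacing, dtype=float)
    voxel_vol = float(np.prod(sp))
    surf = np.zeros(N_HABITATS)
    conv = np.zeros(N_HABITATS)
    spher = np.zeros(N_HABITATS)
    missing = np.zeros(N_HABITATS, dtype=bool)
    corner_offsets = np.array(list(np.ndindex(*([2] * lab.ndim))), dtype=float)
    for h in range(1, N_HABITATS + 1):
        sel = lab == h
        n = int(sel.sum())
        if n == 0:
            missing[h - 1] = True
            continue
        v = n * voxel_vol
        surf[h - 1] = _face_area_surface(sel, sp)
        # Convex hull over voxel corner points, exact for solid boxes.
        idx = np.argwhere(sel).astype(float)
        pts = (idx[:, None, :] + corner_offsets[None, :, :]).reshape(-1, lab.ndim)
        pts = np.unique(pts, axis=0) * sp
        try:
            hull_vol = ConvexHull(pts).volume
            conv[h - 1] = min(1.0, v / hull_vol) if hull_vol > _EPS else 1.0
        except QhullError:
            conv[h - 1] = 1.0          # degenerate (coplanar) habitat is convex
        area = _mesh_area(sel, sp)
        spher[h - 1] = (np.pi ** (1 / 3) * (6.0 * v) ** (2 / 3)) / area \
            if area > _EPS else 0.0
    return np.concatenate([surf, conv, spher]), missing


def msi_intensity_moments(volume: np.ndarray, habmap: HabitatMap):
    """MSI 75-94: mean, population SD, skewness g1, excess kurtosis g2.

    Habitats with fewer than two voxels, or with zero variance, report 0
    for the undefined statistics and are flagged.
    """
    lab = _check_labels(habmap)
    vol = np.asarray(volume, dtype=float)
    mean = np.zeros(N_HABITATS)
    sd = np.zeros(N_HABITATS)
    skew = np.zeros(N_HABITATS)
    kurt = np.zeros(N_HABITATS)
    missing = np.zeros(N_HABITATS, dtype=bool)
    for h in range(1, N_HABITATS + 1):
        x = vol[lab == h]
        if x.size == 0:
            missing[h - 1] = True
            continue
        mean[h - 1] = float(x.mean())
        if x.size < 2:
            missing[h - 1] = True
            continue
        s = float(x.std())
        sd[h - 1] = s
        if s > _EPS:
            skew[h - 1] = float(stats.skew(x))
            kurt[h - 1] = float(stats.kurtosis(x))    # excess, Gaussian -> 0
        else:
            missing[h - 1] = True
    return np.concatenate([mean, sd, skew, kurt]), missing


def _box_count_dimension(sel: np.ndarray) -> float:
    """Box-counting fractal dimension of a binary mask.

    The mask is cropped to its bounding box and padded to a power-of-two
    cube; occupied boxes are counted at sizes 1, 2, 4, ... up to half the
    cube, and the dimension is the least-squares slope of log N against
    log(1/s).
    """
    idx = np.argwhere(sel)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sub = sel[tuple(slice(a, b) for a, b in zip(lo, hi))]
    size = int(2 ** np.ceil(np.log2(max(sub.shape))))
    size = max(size, 2)
    cube = np.zeros([size] * sel.ndim, dtype=bool)
    cube[tuple(slice(0, s) for s in sub.shape)] = sub
    sizes, counts = [], []
    s = 1
    while s <= size // 2 or s == 1:
        # Reduce by max-pooling blocks of side s along every axis.
        red = cube
        for ax in range(cube.ndim):
            shp = list(red.shape)
            shp[ax] = shp[ax] // s
            red = red.reshape(shp[:ax] + [shp[ax], s] + shp[ax + 1:]).any(axis=ax + 1)
        sizes.append(s)
        counts.append(int(red.sum()))
        if s >= size // 2:
            break
        s *= 2
    if len(sizes) < 2:
        return float(sel.ndim)       # too small to fit a slope
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, float)),
                       np.log(np.asarray(counts, float)), 1)[0]
    return float(slope)


def msi_complexity(volume: np.ndarray, habmap: HabitatMap):
    """MSI 95-114: entropy, fractal dimension, connectivity, eccentricity.

    Per habitat: Shannon entropy (bits) of a 64-bin histogram of member
    intensities; box-counting fractal dimension of the habitat's binary
    mask; connectivity = 1 / (number of 26-connected components);
    eccentricity = sqrt(1 - lambda_min / lambda_max) of the voxel
    coordinate covariance.
    """
    lab = _check_labels(habmap)
    vol = np.asarray(volume, dtype=float)
    ent = np.zeros(N_HABITATS)
    frac = np.zeros(N_HABITATS)
    conn = np.zeros(N_HABITATS)
    ecc = np.zeros(N_HABITATS)
    missing = np.zeros(N_HABITATS, dtype=bool)
    full = np.ones([3] * lab.ndim, dtype=bool)     # 26-connectivity
    for h in range(1, N_HABITATS + 1):
        sel = lab == h
        if not sel.any():
            missing[h - 1] = True
            continue
        x = vol[sel]
        counts, _ = np.histogram(x, bins=64)
        pr = counts[counts > 0] / counts.sum()
        ent[h - 1] = float(-(pr * np.log2(pr)).sum())
        frac[h - 1] = _box_count_dimension(sel)
        _, ncomp = ndimage.label(sel, structure=full)
        conn[h - 1] = 1.0 / ncomp
        coords = np.argwhere(sel).astype(float)
        if len(coords) < 2:
            ecc[h - 1] = 0.0
        else:
            cov = np.cov(coords.T)
            ev = np.linalg.eigvalsh(np.atleast_2d(cov))
            lmax = ev[-1]
            ecc[h - 1] = float(np.sqrt(max(0.0, 1.0 - ev[0] / lmax))) \
                if lmax > _EPS else 0.0
    return np.concatenate([ent, frac, conn, ecc]), missing


def msi_global(habmap: HabitatMap, mask: np.ndarray, border: np.ndarray,
               pairs: np.ndarray, norm_volumes: np.ndarray,
               window_sizes=(3, 5, 9)):
    """MSI 115-120: global tumor-architecture descriptors.

    * global entropy — Shannon entropy (bits) of the habitat fractions;
    * multiscale variance — mean over ``window_sizes`` of the variance
      (over ROI voxels) of the local majority-habitat fraction;
    * pattern complexity — fraction of the 10 habitat pairs with a
      nonzero co-occurrence;
    * architectural index — total border interaction / total volume;
    * tumor signature — L2 norm of the normalized-volume vector;
    * integrated heterogeneity — mean of the three heterogeneity terms
      after scaling each to [0, 1] by its attainable range (entropy by
      log2(5), multiscale variance by 1/4, pattern complexity as-is).
    """
    lab = _check_labels(habmap)
    mask = np.asarray(mask, dtype=bool)
    fr = norm_volumes[norm_volumes > 0]
    g_entropy = float(-(fr * np.log2(fr)).sum())

    msvs = []
    mask_f = mask.astype(float)
    for w in window_sizes:
        denom = ndimage.uniform_filter(mask_f, size=w)
        best = np.zeros(lab.shape)
        for h in range(1, N_HABITATS + 1):
            f_h = ndimage.uniform_filter((lab == h).astype(float), size=w)
            with np.errstate(invalid="ignore", divide="ignore"):
                f_h = np.where(denom > _EPS, f_h / denom, 0.0)
            best = np.maximum(best, f_h)
        msvs.append(float(best[mask].var()))
    ms_var = float(np.mean(msvs))

    pattern = float(np.count_nonzero(np.asarray(pairs) > 0)) / len(PAIR_ORDER)
    total = float(mask.sum())
    arch = float(np.asarray(border).sum()) / total
    signature = float(np.linalg.norm(norm_volumes))
    scaled = [g_entropy / np.log2(N_HABITATS), ms_var / 0.25, pattern]
    integrated = float(np.mean(scaled))
    return np.array([g_entropy, ms_var, pattern, arch, signature, integrated])


def _validate_palette_order(volume, habmap, tol=0.0):
    """Habitat mean intensities must be non-increasing in habitat id."""
    lab = habmap.labels
    means = []
    for h in range(1, N_HABITATS + 1):
        sel = lab == h
        if sel.any():
            means.append(np.asarray(volume, float)[sel].mean())
    means = np.asarray(means)
    if np.any(np.diff(means) > tol):
        raise ValueError(
            "habitat ids are not ordered by descending mean intensity; "
            "renumber the habitat map against the cohort palette first"
        )


def msi_extract(volume: np.ndarray, mask: np.ndarray, habmap: HabitatMap,
                spacing=(1.0, 1.0, 1.0), order_tol: float = 0.0) -> MSIVector:
    """Compute the full 120-element MSI vector for one tumor.

    ``volume`` is the intensity array, ``mask`` the tumor ROI and
    ``habmap`` a palette-ordered five-habitat labelling. Raises if habitat
    ids violate the descending-mean-intensity palette convention.
    """
    _validate_palette_order(volume, habmap, tol=order_tol)
    glcm = msi_glcm_stats(habmap)
    volumes, border, pairs, norm_vol = msi_volumes_and_interactions(habmap, mask)
    norm_inter = msi_normalized_interactions(border, pairs, volumes.sum())
    texture, miss_t = msi_texture_bank(volume, habmap)
    morph, miss_m = msi_morphology(habmap, spacing)
    moments, miss_i = msi_intensity_moments(volume, habmap)
    cmplx, miss_c = msi_complexity(volume, habmap)
    glob = msi_global(habmap, mask, border, pairs, norm_vol)
    values = np.concatenate([glcm, volumes, border, pairs, norm_vol,
                             norm_inter, texture, morph, moments, cmplx,
                             glob])
    missing = tuple(int(h) for h in range(1, N_HABITATS + 1)
                    if volumes[h - 1] == 0)
    return MSIVector(values=values, missing_habitats=missing)


def extract_msi_cohort(volumes, masks, habmaps, spacing=(1.0, 1.0, 1.0),
                       subject_ids=None, order_tol: float = 0.0) -> FeatureBlock:
    """Extract MSI vectors for a cohort into a ``ct_msi`` feature block."""
    rows = [msi_extract(v, m, h, spacing, order_tol).values
            for v, m, h in zip(volumes, masks, habmaps)]
    df = pd.DataFrame(np.asarray(rows), columns=list(MSI_NAMES))
    if subject_ids is not None:
        df.index = list(subject_ids)
    return FeatureBlock(df, modality="ct_msi")


def fscore_rank(block: FeatureBlock, labels, threshold: float = 1.0):
    """Rank features by the Fisher score and keep those above ``threshold``.

    F = [(mean+ - mean)^2 + (mean- - mean)^2] / (var+ + var- + eps), where
    +/- are the two label classes and ``mean`` the pooled mean. Returns
    ``(selected_block, scores)`` with ``scores`` a descending Series over
    all features.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("fscore_rank requires binary labels")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least 2 subjects")
    x = block.data.to_numpy(dtype=float)
    pos = x[y == classes[1]]
    neg = x[y == classes[0]]
    grand = x.mean(axis=0)
    num = (pos.mean(axis=0) - grand) ** 2 + (neg.mean(axis=0) - grand) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1) + _EPS
    f = num / den
    scores = pd.Series(f, index=block.data.columns).sort_values(ascending=False)
    kept = scores[scores > threshold].index
    return block.subset(kept), scores
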