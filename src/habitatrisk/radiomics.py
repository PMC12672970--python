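"""Habitat radiomics: a pinned 635-feature 2D extraction bank.

Features are computed per habitat region of a grayscale ultrasound image,
after normalizing intensities to [0, 255] over the region. The bank is:

* **original** image: 19 first-order + 10 shape(2D) + 24 GLCM + 16 GLRLM +
  16 GLSZM + 14 GLDM + 5 NGTDM = 104 features;
* **nine derived images** — single-level Haar wavelet sub-bands (LL, LH,
  HL, HH), Laplacian-of-Gaussian at sigma 1, 2 and 3 pixels, gradient
  magnitude, and squared intensity — each with 19 first-order + 24 GLCM +
  16 GLRLM = 59 features,

for a total of 104 + 9 x 59 = 635 named features. Texture matrices use a
fixed bin width (25) on the original image and a fixed bin count (32) on
derived images, distance 1, with the four unique 2D directions merged.

The configuration is hashed into the provenance of every emitted block;
blocks with different extractor configs refuse to merge downstream.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage, stats
from skimage.measure import label as cc_label, regionprops

from ._types import AnnotatedImage, EmptyInputError, FeatureBlock

__all__ = [
    "RadiomicsConfig",
    "extract_radiomics",
    "extract_radiomics_block",
    "EXPECTED_FEATURE_COUNT",
]

EXPECTED_FEATURE_COUNT = 635
_EPS = 1e-12

_DIRECTIONS_2D = [(0, 1), (1, 0), (1, 1), (1, -1)]


@dataclass(frozen=True)
class RadiomicsConfig:
    """Pinned extractor settings; the default emits exactly 635 features."""

    bin_width: float = 25.0          # original-image discretization
    derived_bin_count: int = 32      # derived-image discretization
    log_sigmas: tuple = (1.0, 2.0, 3.0)
    wavelet: str = "haar"
    gradient_sigma: float = 1.0
    normalize_range: tuple = (0.0, 255.0)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# discretization and derived images

def _discretize(values: np.ndarray, bin_width=None, bin_count=None):
    """Map intensities to integer gray levels 1..N."""
    v = np.asarray(values, dtype=float)
    if bin_width is not None:
        lev = np.floor((v - v.min()) / bin_width).astype(np.int64) + 1
    else:
        lo, hi = v.min(), v.max()
        if hi - lo < _EPS:
            return np.ones_like(v, dtype=np.int64), 1
        edges = np.linspace(lo, hi, bin_count + 1)
        lev = np.clip(np.digitize(v, edges[1:-1]) + 1, 1, bin_count)
    return lev, int(lev.max())


def _derived_images(img: np.ndarray, cfg: RadiomicsConfig) -> dict:
    """The nine derived images of the pinned filter bank."""
    out = {}
    # Stationary (undecimated) single-level 2D wavelet: same-size sub-bands.
    pad = [(0, img.shape[0] % 2), (0, img.shape[1] % 2)]
    padded = np.pad(img, pad, mode="symmetric")
    [(ll, (lh, hl, hh))] = pywt.swt2(padded, cfg.wavelet, level=1,
                                     norm=True, trim_approx=False)
    sl = tuple(slice(0, s) for s in img.shape)
    out["wavelet-LL"] = ll[sl]
    out["wavelet-LH"] = lh[sl]
    out["wavelet-HL"] = hl[sl]
    out["wavelet-HH"] = hh[sl]
    for s in cfg.log_sigmas:
        out[f"log-sigma-{s:g}"] = ndimage.gaussian_laplace(img, sigma=s)
    out["gradient"] = ndimage.gaussian_gradient_magnitude(
        img, sigma=cfg.gradient_sigma)
    out["square"] = img ** 2
    return out


# ---------------------------------------------------------------------------
# feature classes

_FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "StandardDeviation", "Skewness", "Kurtosis",
    "Variance", "Uniformity",
)


def _firstorder(values: np.ndarray, pixel_area: float, bin_width=None,
                bin_count=32) -> dict:
    x = np.asarray(values, dtype=float)
    lev, _ = _discretize(x, bin_width=bin_width,
                         bin_count=None if bin_width else bin_count)
    counts = np.bincount(lev)[1:]
    p = counts[counts > 0] / counts.sum()
    p10, p90 = np.percentile(x, [10, 90])
    robust = x[(x >= p10) & (x <= p90)]
    sd = float(x.std())
    out = {
        "Energy": float((x ** 2).sum()),
        "TotalEnergy": float((x ** 2).sum() * pixel_area),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(x.mean()),
        "Median": float(np.median(x)),
        "InterquartileRange": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - x.mean()).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "StandardDeviation": sd,
        "Skewness": float(stats.skew(x)) if sd > _EPS else 0.0,
        "Kurtosis": float(stats.kurtosis(x, fisher=False)) if sd > _EPS else 0.0,
        "Variance": float(x.var()),
        "Uniformity": float((p ** 2).sum()),
    }
    return out


_SHAPE_NAMES = (
    "PixelSurface", "Perimeter", "PerimeterSurfaceRatio", "Circularity",
    "MaximumDiameter", "MajorAxisLength", "MinorAxisLength", "Elongation",
    "Eccentricity", "Extent",
)


def _shape2d(mask: np.ndarray, spacing) -> dict:
    px = float(spacing[0]) * float(spacing[1])
    props = regionprops(mask.astype(np.int64))[0]
    area = props.area * px
    # Perimeter in physical units assumes near-isotropic in-plane spacing.
    perim = props.perimeter * float(np.sqrt(px))
    coords = np.argwhere(mask).astype(float) * np.asarray(spacing, float)
    if len(coords) > 1:
        from scipy.spatial.distance import pdist
        hullpts = coords
        if len(coords) > 400:
            try:
                from scipy.spatial import ConvexHull
                hullpts = coords[ConvexHull(coords).vertices]
            except Exception:
                hullpts = coords[:: max(1, len(coords) // 400)]
        maxdiam = float(pdist(hullpts).max())
    else:
        maxdiam = 0.0
    major = props.axis_major_length * float(np.sqrt(px))
    minor = props.axis_minor_length * float(np.sqrt(px))
    return {
        "PixelSurface": area,
        "Perimeter": perim,
        "PerimeterSurfaceRatio": perim / area if area > 0 else 0.0,
        "Circularity": float(4 * np.pi * area / perim ** 2) if perim > 0 else 0.0,
        "MaximumDiameter": maxdiam,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Elongation": minor / major if major > 0 else 1.0,
        "Eccentricity": float(props.eccentricity),
        "Extent": float(props.extent),
    }


_GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)


def _glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    lab = np.where(mask, levels, 0)
    for off in _DIRECTIONS_2D:
        src = tuple(slice(None, -o) if o > 0 else slice(-o, None) for o in off)
        dst = tuple(slice(o, None) if o > 0 else slice(None, o or None)
                    for o in off)
        a, b = lab[src], lab[dst]
        ok = (a > 0) & (b > 0)
        np.add.at(counts, (a[ok] - 1, b[ok] - 1), 1)
    sym = counts + counts.T
    total = sym.sum()
    return sym / total if total > 0 else sym.astype(float)


def _glcm_features(p: np.ndarray) -> dict:
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sig2 = float(((i - mu) ** 2 * px).sum())
    sig = np.sqrt(sig2)

    k_diff = np.arange(0, n, dtype=float)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * n + 1, dtype=float)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    nz = p[p > 0]
    hxy = float(-(nz * np.log2(nz)).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    pxy = np.outer(px, px)
    ok = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[ok] * np.log2(pxy[ok])).sum())
    okk = pxy > 0
    hxy2 = float(-(pxy[okk] * np.log2(pxy[okk])).sum())

    da = float((k_diff * p_diff).sum())
    nzd = p_diff[p_diff > 0]
    nzs = p_sum[p_sum > 0]

    if sig2 > _EPS:
        corr = float(((p * ii * jj).sum() - mu * mu) / sig2)
        # MCC: sqrt of the second-largest eigenvalue of Q.
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.zeros((n, n))
            valid = px > 0
            for a in range(n):
                if not valid[a]:
                    continue
                q[a, valid] = (p[a, :][None, :] * p[valid, :]
                               / (px[a] * px[None, :].T[valid])).sum(axis=1)
            ev = np.sort(np.real(np.linalg.eigvals(q)))
            mcc = float(np.sqrt(max(0.0, ev[-2]))) if len(ev) > 1 else 1.0
    else:
        corr, mcc = 1.0, 1.0

    # symmetric matrix: HX == HY, so max(HX, HY) == HX
    imc1 = (hxy - hxy1) / hx if hx > _EPS else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    off_diag = np.abs(ii - jj) > 0
    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "JointAverage": mu,
        "ClusterProminence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(nzd * np.log2(nzd)).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / n) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / n)).sum()),
        "InverseVariance": float((p[off_diag]
                                  / (ii - jj)[off_diag] ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(nzs * np.log2(nzs)).sum()),
        "SumSquares": sig2,
        "MCC": mcc,
    }


_GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def _rle_1d(seq: np.ndarray):
    """Runs of equal nonzero values: yields (value, length)."""
    if seq.size == 0:
        return
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.r_[0, change + 1]
    ends = np.r_[change, seq.size - 1]
    for s, e in zip(starts, ends):
        if seq[s] != 0:
            yield int(seq[s]), int(e - s + 1)


def _glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    lab = np.where(mask, levels, 0)
    maxrun = max(lab.shape)
    r = np.zeros((n_levels, maxrun), dtype=np.int64)

    def add_lines(arr2d, axis):
        seqs = arr2d if axis == 0 else arr2d.T
        for row in seqs:
            for v, ln in _rle_1d(row):
                r[v - 1, ln - 1] += 1

    add_lines(lab, 1)       # rows -> direction (0,1)
    add_lines(lab, 0)       # cols -> direction (1,0)
    for src in (lab, lab[:, ::-1]):     # two diagonal directions
        h, w = src.shape
        for off in range(-h + 1, w):
            diag = np.diagonal(src, offset=off)
            for v, ln in _rle_1d(diag):
                r[v - 1, ln - 1] += 1
    return r


def _glrlm_features(r: np.ndarray, n_pixels: int) -> dict:
    nr = r.sum()
    if nr == 0:
        return {k: 0.0 for k in _GLRLM_NAMES}
    p = r / nr
    i = np.arange(1, r.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, r.shape[1] + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    pr = p.sum(axis=0)
    mu_i = float((i[:, 0] * pg).sum())
    mu_j = float((j[0, :] * pr).sum())
    nz = p[p > 0]
    return {
        "ShortRunEmphasis": float((p / j ** 2).sum()),
        "LongRunEmphasis": float((p * j ** 2).sum()),
        "GrayLevelNonUniformity": float((r.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum()),
        "RunLengthNonUniformity": float((r.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pr ** 2).sum()),
        "RunPercentage": float(nr / n_pixels),
        "GrayLevelVariance": float((((i[:, 0] - mu_i) ** 2) * pg).sum()),
        "RunVariance": float((((j[0, :] - mu_j) ** 2) * pr).sum()),
        "RunEntropy": float(-(nz * np.log2(nz)).sum()),
        "LowGrayLevelRunEmphasis": float((p / i ** 2).sum()),
        "HighGrayLevelRunEmphasis": float((p * i ** 2).sum()),
        "ShortRunLowGrayLevelEmphasis": float((p / (i ** 2 * j ** 2)).sum()),
        "ShortRunHighGrayLevelEmphasis": float((p * i ** 2 / j ** 2).sum()),
        "LongRunLowGrayLevelEmphasis": float((p * j ** 2 / i ** 2).sum()),
        "LongRunHighGrayLevelEmphasis": float((p * i ** 2 * j ** 2).sum()),
    }


_GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)


def _glszm_features(levels, mask, n_levels, n_pixels) -> dict:
    lab = np.where(mask, levels, 0)
    zones = {}
    max_size = 1
    for v in range(1, n_levels + 1):
        comp = cc_label(lab == v, connectivity=2)
        if comp.max() == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        zones[v] = sizes
        max_size = max(max_size, int(sizes.max()))
    z = np.zeros((n_levels, max_size), dtype=np.int64)
    for v, sizes in zones.items():
        for s_ in sizes:
            z[v - 1, s_ - 1] += 1
    nz_total = z.sum()
    if nz_total == 0:
        return {k: 0.0 for k in _GLSZM_NAMES}
    p = z / nz_total
    i = np.arange(1, z.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, z.shape[1] + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float((i[:, 0] * pg).sum())
    mu_j = float((j[0, :] * ps).sum())
    nzp = p[p > 0]
    return {
        "SmallAreaEmphasis": float((p / j ** 2).sum()),
        "LargeAreaEmphasis": float((p * j ** 2).sum()),
        "GrayLevelNonUniformity": float((z.sum(axis=1) ** 2).sum() / nz_total),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum()),
        "SizeZoneNonUniformity": float((z.sum(axis=0) ** 2).sum() / nz_total),
        "SizeZoneNonUniformityNormalized": float((ps ** 2).sum()),
        "ZonePercentage": float(nz_total / n_pixels),
        "GrayLevelVariance": float((((i[:, 0] - mu_i) ** 2) * pg).sum()),
        "ZoneVariance": float((((j[0, :] - mu_j) ** 2) * ps).sum()),
        "ZoneEntropy": float(-(nzp * np.log2(nzp)).sum()),
        "LowGrayLevelZoneEmphasis": float((p / i ** 2).sum()),
        "HighGrayLevelZoneEmphasis": float((p * i ** 2).sum()),
        "SmallAreaLowGrayLevelEmphasis": float((p / (i ** 2 * j ** 2)).sum()),
        "SmallAreaHighGrayLevelEmphasis": float((p * i ** 2 / j ** 2).sum()),
        "LargeAreaLowGrayLevelEmphasis": float((p * j ** 2 / i ** 2).sum()),
        "LargeAreaHighGrayLevelEmphasis": float((p * i ** 2 * j ** 2).sum()),
    }


_GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

_NEIGH_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _gldm_features(levels, mask, n_levels) -> dict:
    lab = np.where(mask, levels, 0)
    dep = np.zeros(lab.shape, dtype=np.int64)
    for off in _NEIGH_8:
        shifted = np.roll(lab, off, axis=(0, 1))
        edge0 = slice(0, 1) if off[0] == 1 else (slice(-1, None) if off[0] == -1 else None)
        edge1 = slice(0, 1) if off[1] == 1 else (slice(-1, None) if off[1] == -1 else None)
        sh = shifted.copy()
        if edge0 is not None:
            sh[edge0, :] = 0
        if edge1 is not None:
            sh[:, edge1] = 0
        dep += ((sh == lab) & (lab > 0) & (sh > 0)).astype(np.int64)
    inside = lab > 0
    d = dep[inside] + 1           # dependence index j >= 1
    g = lab[inside]
    m = np.zeros((n_levels, 9), dtype=np.int64)
    np.add.at(m, (g - 1, d - 1), 1)
    n = m.sum()
    p = m / n
    i = np.arange(1, n_levels + 1, dtype=float)[:, None]
    j = np.arange(1, 10, dtype=float)[None, :]
    pg = p.sum(axis=1)
    pd_ = p.sum(axis=0)
    mu_j = float((j[0, :] * pd_).sum())
    mu_i = float((i[:, 0] * pg).sum())
    nzp = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((p / j ** 2).sum()),
        "LargeDependenceEmphasis": float((p * j ** 2).sum()),
        "GrayLevelNonUniformity": float((m.sum(axis=1) ** 2).sum() / n),
        "DependenceNonUniformity": float((m.sum(axis=0) ** 2).sum() / n),
        "DependenceNonUniformityNormalized": float((pd_ ** 2).sum()),
        "GrayLevelVariance": float((((i[:, 0] - mu_i) ** 2) * pg).sum()),
        "DependenceVariance": float((((j[0, :] - mu_j) ** 2) * pd_).sum()),
        "DependenceEntropy": float(-(nzp * np.log2(nzp)).sum()),
        "LowGrayLevelEmphasis": float((p / i ** 2).sum()),
        "HighGrayLevelEmphasis": float((p * i ** 2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (i ** 2 * j ** 2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * i ** 2 / j ** 2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * j ** 2 / i ** 2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * i ** 2 * j ** 2).sum()),
    }


_NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def _ngtdm_features(levels, mask, n_levels) -> dict:
    lab = np.where(mask, levels, 0).astype(float)
    inside = lab > 0
    nsum = np.zeros(lab.shape)
    ncount = np.zeros(lab.shape)
    for off in _NEIGH_8:
        sh = np.roll(lab, off, axis=(0, 1))
        if off[0] == 1:
            sh[0, :] = 0
        elif off[0] == -1:
            sh[-1, :] = 0
        if off[1] == 1:
            sh[:, 0] = 0
        elif off[1] == -1:
            sh[:, -1] = 0
        nsum += sh
        ncount += (sh > 0).astype(float)
    valid = inside & (ncount > 0)
    avg = np.zeros(lab.shape)
    avg[valid] = nsum[valid] / ncount[valid]
    g = lab[valid].astype(np.int64)
    diff = np.abs(lab[valid] - avg[valid])
    s = np.zeros(n_levels)
    np.add.at(s, g - 1, diff)
    ni = np.bincount(g - 1, minlength=n_levels).astype(float)
    n = ni.sum()
    p = ni / n
    i = np.arange(1, n_levels + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    coarse = 1.0 / max((p * s).sum(), _EPS)
    if ngp > 1:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        both = (pi > 0) & (pj > 0)
        contrast = ((pi * pj * (ii - jj) ** 2)[both].sum()
                    / (ngp * (ngp - 1))) * (s.sum() / n)
        busy_den = np.abs((i * p)[:, None] - (i * p)[None, :])[both].sum()
        busy = (p * s).sum() / busy_den if busy_den > _EPS else 0.0
        si, sj = np.meshgrid(s, s, indexing="ij")
        cplx = (np.abs(ii - jj) * (pi * si + pj * sj)
                / (pi + pj + _EPS))[both].sum() / n
        strength = ((pi + pj) * (ii - jj) ** 2)[both].sum() / max(s.sum(), _EPS)
    else:
        contrast, busy, cplx, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Coarseness": float(coarse),
        "Contrast": float(contrast),
        "Busyness": float(busy),
        "Complexity": float(cplx),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# the pinned bank

def extract_radiomics(image, habitat_mask: np.ndarray,
                      config: RadiomicsConfig | None = None) -> pd.Series:
    """Extract the pinned 635-feature vector for one habitat region.

    Parameters
    ----------
    image : AnnotatedImage or 2D ndarray
        Grayscale ultrasound image; intensities are min-max normalized to
        the configured range over the habitat region before extraction.
    habitat_mask : 2D bool ndarray
        The habitat region to profile (nonempty).
    config : RadiomicsConfig
        Pinned extractor settings; the default emits exactly 635 features.

    Returns a named Series; the name set and order are a pure function of
    the config.
    """
    cfg = config or RadiomicsConfig()
    if isinstance(image, AnnotatedImage):
        img = image.image.astype(float)
        spacing = image.spacing
    else:
        img = np.asarray(image, dtype=float)
        spacing = (1.0, 1.0)
    msk = np.asarray(habitat_mask, dtype=bool)
    if img.ndim != 2:
        raise ValueError("radiomics bank operates on 2D images")
    if msk.shape != img.shape:
        raise ValueError("habitat mask is not aligned to the image")
    if not msk.any():
        raise EmptyInputError("habitat mask is empty")

    lo, hi = cfg.normalize_range
    vals = img[msk]
    rng = vals.max() - vals.min()
    norm = np.zeros_like(img) if rng < _EPS else \
        (img - vals.min()) / rng * (hi - lo) + lo
    pixel_area = float(spacing[0]) * float(spacing[1])
    n_pixels = int(msk.sum())

    feats: dict[str, float] = {}

    def texture_suite(arr, prefix, bin_width, bin_count, full):
        lev_in, _ = _discretize(arr[msk], bin_width=bin_width,
                                bin_count=bin_count)
        lev = np.zeros(arr.shape, dtype=np.int64)
        lev[msk] = lev_in
        nl = int(lev_in.max())
        for k, v in _glcm_features(_glcm_matrix(lev, msk, nl)).items():
            feats[f"{prefix}_glcm_{k}"] = v
        for k, v in _glrlm_features(_glrlm_matrix(lev, msk, nl),
                                    n_pixels).items():
            feats[f"{prefix}_glrlm_{k}"] = v
        if full:
            for k, v in _glszm_features(lev, msk, nl, n_pixels).items():
                feats[f"{prefix}_glszm_{k}"] = v
            for k, v in _gldm_features(lev, msk, nl).items():
                feats[f"{prefix}_gldm_{k}"] = v
            for k, v in _ngtdm_features(lev, msk, nl).items():
                feats[f"{prefix}_ngtdm_{k}"] = v

    # original image: all classes + shape
    for k, v in _firstorder(norm[msk], pixel_area,
                            bin_width=cfg.bin_width).items():
        feats[f"original_firstorder_{k}"] = v
    for k, v in _shape2d(msk, spacing).items():
        feats[f"original_shape2D_{k}"] = v
    texture_suite(norm, "original", cfg.bin_width, None, full=True)

    # derived images: first-order + GLCM + GLRLM
    for name, arr in _derived_images(norm, cfg).items():
        for k, v in _firstorder(arr[msk], pixel_area,
                                bin_count=cfg.derived_bin_count).items():
            feats[f"{name}_firstorder_{k}"] = v
        texture_suite(arr, name, None, cfg.derived_bin_count, full=False)

    out = pd.Series(feats, dtype=float)
    if len(out) != EXPECTED_FEATURE_COUNT:
        raise RuntimeError(
            f"extractor emitted {len(out)} features, expected "
            f"{EXPECTED_FEATURE_COUNT}; config drift?")
    return out


def extract_radiomics_block(images, habitat_masks, subject_ids=None,
                            habitat_id=None,
                            config: RadiomicsConfig | None = None) -> FeatureBlock:
    """Extract the 635-feature bank for a cohort of habitat regions."""
    cfg = config or RadiomicsConfig()
    rows = [extract_radiomics(im, mk, cfg)
            for im, mk in zip(images, habitat_masks)]
    df = pd.DataFrame(rows)
    if subject_ids is not None:
        df.index = list(subject_ids)
    prov = {"config_hash": cfg.hash()}
    if habitat_id is not None:
        prov["habitat_id"] = int(habitat_id)
    return FeatureBlock(df, modality="us_radiomic", provenance=prov)
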