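"""Core containers shared across the habitat-imaging pipeline.

The unit of imaging input is an :class:`AnnotatedImage` (intensity array +
voxel spacing + binary region-of-interest mask). Habitat discovery produces a
:class:`HabitatMap` (integer subregion labelling of the ROI), feature
extraction produces named tables wrapped in :class:`FeatureBlock`, and the
evaluation layer reports an :class:`EvalReport`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnnotatedImage",
    "SuperpixelMap",
    "SuperpixelProfile",
    "HabitatMap",
    "HabitatPalette",
    "FeatureBlock",
    "EvalReport",
    "NetBenefitCurve",
]


class EmptyInputError(ValueError):
    """Raised when a required image region or table is empty."""


@dataclass(frozen=True)
class AnnotatedImage:
    """Intensity array (2D or 3D) with voxel spacing and a binary ROI mask.

    Parameters
    ----------
    image : ndarray
        Grayscale intensities; 2D for ultrasound, 3D (Hounsfield units)
        for CT.
    mask : ndarray of bool
        Binary region of interest, same shape as ``image``.
    spacing : tuple of float
        Physical size of one pixel/voxel along each axis, in mm.
    """

    image: np.ndarray
    mask: np.ndarray
    spacing: tuple

    def __post_init__(self):
        img = np.asarray(self.image)
        msk = np.asarray(self.mask, dtype=bool)
        if img.shape != msk.shape:
            raise ValueError(
                f"image shape {img.shape} != mask shape {msk.shape}"
            )
        if img.ndim not in (2, 3):
            raise ValueError("image must be 2D or 3D")
        if len(self.spacing) != img.ndim:
            raise ValueError("spacing length must match image dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "image", img)
        object.__setattr__(self, "mask", msk)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def ndim(self) -> int:
        return self.image.ndim

    @property
    def roi_size(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SuperpixelMap:
    """Connected over-segmentation of the ROI.

    ``labels`` is aligned to the source image: 0 outside the ROI, 1..S
    inside. Each superpixel (or supervoxel in 3D) is spatially connected
    and the superpixels partition the ROI exactly.
    """

    labels: np.ndarray
    n_superpixels: int

    def pixel_lists(self):
        """Indices of member pixels per superpixel label (1-based keys)."""
        out = {}
        for s in range(1, self.n_superpixels + 1):
            out[s] = np.flatnonzero(self.labels.ravel() == s)
        return out


@dataclass(frozen=True)
class SuperpixelProfile:
    """Per-superpixel feature rows used for habitat clustering.

    Columns: mean intensity, intensity SD, local entropy, local contrast,
    then centroid coordinates (pixels, one per image axis).
    """

    values: np.ndarray
    columns: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("profile entries must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class HabitatMap:
    """Integer habitat labelling of the ROI: 0 outside, 1..K inside.

    Habitat ids are ordered by descending mean intensity (ultrasound) or
    descending mean HU (CT), so "habitat 2" has a reproducible meaning as a
    rank rather than an arbitrary cluster id.
    """

    labels: np.ndarray
    n_habitats: int
    fractions: np.ndarray

    def __post_init__(self):
        fr = np.asarray(self.fractions, dtype=float)
        if fr.shape != (self.n_habitats,):
            raise ValueError("fractions must have one entry per habitat")
        if abs(fr.sum() - 1.0) > 1e-8:
            raise ValueError("habitat fractions must sum to 1 over the ROI")
        object.__setattr__(self, "fractions", fr)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass(frozen=True)
class HabitatPalette:
    """Cohort-shared habitat centroids in profile space.

    Centroids are ordered by descending mean intensity so habitat i carries
    the same rank meaning in every patient.
    """

    centroids: np.ndarray
    columns: tuple

    @property
    def n_habitats(self) -> int:
        return self.centroids.shape[0]


@dataclass
class FeatureBlock:
    """Named numeric feature table with a modality tag.

    Rows are subjects, columns are features; this is the currency passed
    between extraction, selection and fusion. ``modality`` is one of
    ``us_radiomic``, ``ct_msi``, ``clinical`` (free-form tags accepted).
    """

    data: pd.DataFrame
    modality: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.data.isna().any().any():
            raise ValueError("feature block contains missing values")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset(self, columns) -> "FeatureBlock":
        return FeatureBlock(self.data[list(columns)].copy(), self.modality,
                            dict(self.provenance))


@dataclass(frozen=True)
class EvalReport:
    """Threshold metrics + ranking/calibration scores for a prediction set."""

    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    brier: float
    threshold: float
    n_positive: int
    n_negative: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
            "brier": self.brier,
            "threshold": self.threshold,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


@dataclass(frozen=True)
class NetBenefitCurve:
    """Decision-curve analysis output over a threshold-probability grid."""

    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "net_benefit": self.net_benefit,
                "treat_all": self.treat_all,
                "treat_none": self.treat_none,
            }
        )
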