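"""Reading and writing the pipeline's on-disk formats.

Images and masks travel as NIfTI (via nibabel, affine built from voxel
spacing) or PNG (2D, via imageio); habitat maps carry a JSON sidecar with
the habitat count, fractions and model-selection scores; feature tables
are CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from ._types import AnnotatedImage, FeatureBlock, HabitatMap

__all__ = [
    "save_nifti", "load_nifti", "save_png", "load_png",
    "load_annotated", "save_habitat_map", "load_habitat_map",
    "save_feature_block", "load_feature_block",
]


def _affine(spacing):
    aff = np.eye(4)
    for i, s in enumerate(spacing):
        aff[i, i] = s
    return aff


def save_nifti(path, array, spacing):
    img = nib.Nifti1Image(np.asarray(array).astype(np.float32),
                          _affine(spacing))
    nib.save(img, str(path))


def load_nifti(path):
    """Returns ``(array, spacing)``."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:img.ndim])
    return np.asarray(img.get_fdata()), spacing


def save_png(path, array):
    iio.imwrite(str(path), np.clip(np.asarray(array), 0, 255).astype(np.uint8))


def load_png(path):
    arr = np.asarray(iio.imread(str(path)), dtype=float)
    if arr.ndim == 3:          # collapse RGB(A) to grayscale
        arr = arr[..., :3].mean(axis=-1)
    return arr


def load_annotated(image_path, mask_path, spacing=None) -> AnnotatedImage:
    """Load an image + binary mask pair (NIfTI or PNG by extension)."""
    image_path, mask_path = str(image_path), str(mask_path)
    if image_path.endswith((".nii", ".nii.gz")):
        img, sp = load_nifti(image_path)
        msk, _ = load_nifti(mask_path)
    else:
        img = load_png(image_path)
        msk = load_png(mask_path)
        sp = spacing or (1.0,) * img.ndim
    return AnnotatedImage(img, msk > 0.5, spacing or sp)


def save_habitat_map(path, habmap: HabitatMap, spacing, extra=None):
    """Write the label image plus a JSON sidecar (K, fractions, scores)."""
    path = Path(path)
    if path.suffix == ".png":
        save_png(path, habmap.labels * (250 // max(habmap.n_habitats, 1)))
    else:
        save_nifti(path, habmap.labels, spacing)
    sidecar = {
        "n_habitats": int(habmap.n_habitats),
        "fractions": [float(f) for f in habmap.fractions],
    }
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_habitat_map(path) -> HabitatMap:
    path = Path(path)
    labels, _ = load_nifti(path)
    labels = labels.astype(np.int64)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return HabitatMap(labels=labels, n_habitats=sidecar["n_habitats"],
                      fractions=np.asarray(sidecar["fractions"]))


def save_feature_block(path, block: FeatureBlock):
    block.data.to_csv(path, index_label="subject_id")
    meta = {"modality": block.modality, "provenance": block.provenance}
    Path(path).with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def load_feature_block(path) -> FeatureBlock:
    df = pd.read_csv(path, index_col="subject_id")
    meta_path = Path(path).with_suffix(".meta.json")
    modality, prov = "unknown", {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        modality = meta.get("modality", "unknown")
        prov = meta.get("provenance", {})
    return FeatureBlock(df, modality=modality, provenance=prov)
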