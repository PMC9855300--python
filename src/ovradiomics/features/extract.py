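"""Per-patient feature extraction over the catalog's image types."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..volume import ImageVolume, SegmentationMask
from .catalog import FeatureCatalog
from .filters import discretize, log_filter, wavelet_decompose
from .firstorder import first_order_features
from .shape import shape_features
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["extract_features", "extract_cohort"]

_FAMILY_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "gldm": gldm_features,
    "ngtdm": ngtdm_features,
}


def _crop_to_mask(img: np.ndarray, mask: np.ndarray, margin: int = 1):
    """Bounding-box crop (with margin) — texture matrices only need the ROI."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return img[sl], mask[sl]


def _image_stack(img: ImageVolume, catalog: FeatureCatalog) -> dict[str, ImageVolume]:
    stack: dict[str, ImageVolume] = {}
    need_wavelet = any(t.startswith("wavelet") for t in catalog.image_types)
    wavelets = wavelet_decompose(img, catalog.wavelet) if need_wavelet else {}
    for itype in catalog.image_types:
        if itype == "original":
            stack[itype] = img
        elif itype.startswith("log-sigma-"):
            sigma = float(itype.rsplit("-", 1)[1])
            stack[itype] = log_filter(img, sigma)
        else:
            stack[itype] = wavelets[itype]
    return stack


def extract_features(
    img: ImageVolume, mask: SegmentationMask, catalog: FeatureCatalog | None = None
) -> pd.Series:
    """Extract every catalog feature for one image/mask pair.

    Shape features are computed once from the original-geometry mask;
    intensity and texture families are computed per image type on the
    fixed-bin-width discretized ROI.  Returns a Series indexed by
    ``<imagetype>_<family>_<feature>`` with one finite value per entry.

    Raises
    ------
    ValueError
        On an empty mask or non-finite voxels, naming the failing stage.
    """
    catalog = catalog or FeatureCatalog()
    mask.check_aligned(img)
    if mask.n_foreground == 0:
        raise ValueError("feature extraction: mask is empty")
    if not np.all(np.isfinite(img.voxels)):
        raise ValueError("feature extraction: image contains non-finite voxels")

    out: dict[str, float] = {}
    if catalog.include_shape:
        for name, val in shape_features(mask).items():
            out[f"original_shape_{name}"] = val

    sz, sy, sx = img.spacing_mm
    voxel_vol = sz * sy * sx
    for itype, vol in _image_stack(img, catalog).items():
        cropped, mcrop = _crop_to_mask(vol.voxels, mask.voxels)
        binned, n_levels = discretize(cropped, mcrop, catalog.bin_width)
        values = cropped[mcrop]
        for fam in catalog.families:
            if fam == "firstorder":
                feats = first_order_features(values, binned[mcrop], voxel_vol)
            else:
                feats = _FAMILY_FUNCS[fam](binned, n_levels)
            for name, val in feats.items():
                key = f"{itype}_{fam}_{name}"
                if not np.isfinite(val):
                    raise ValueError(
                        f"feature extraction: non-finite value at {key}"
                    )
                out[key] = float(val)

    return pd.Series(out, name="features").reindex(catalog.feature_names)


def extract_cohort(
    pairs: dict[str, tuple[ImageVolume, SegmentationMask]],
    catalog: FeatureCatalog | None = None,
    labels: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Extract the catalog for every patient; rows indexed by patient id.

    If ``labels`` is given a ``label`` column (0 = non-HGSC, 1 = HGSC) is
    prepended.
    """
    catalog = catalog or FeatureCatalog()
    rows = {
        pid: extract_features(img, mask, catalog)
        for pid, (img, mask) in pairs.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    if labels is not None:
        df.insert(0, "label", pd.Series(labels))
    return df
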