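"""Image transforms feeding the texture families: fixed-bin-width
discretization, Laplacian-of-Gaussian filtering, and a single-level
stationary 3-D wavelet decomposition."""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from ..volume import ImageVolume, SegmentationMask

__all__ = ["discretize", "log_filter", "wavelet_decompose", "WAVELET_LABELS"]

#: Subband labels, one low/high-pass choice per axis in (x, y, z) order.
WAVELET_LABELS = ["LLL", "HLL", "LHL", "HHL", "LLH", "HLH", "LHH", "HHH"]


def discretize(
    img: ImageVolume | np.ndarray,
    mask: SegmentationMask | np.ndarray,
    bin_width: float,
) -> tuple[np.ndarray, int]:
    """Fixed-bin-width gray-level discretization inside the mask.

    Bin index of a voxel with value x is ``floor((x - min) / w) + 1`` where
    ``min`` is the in-mask minimum, so the lowest occupied bin is 1.  The
    returned grid is int32 with 0 outside the mask; the second element is
    the number of gray levels (the index of the brightest voxel).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = img.voxels if isinstance(img, ImageVolume) else np.asarray(img, float)
    m = mask.voxels if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    if x.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if not m.any():
        raise ValueError("mask is empty")
    lo = x[m].min()
    binned = np.zeros(x.shape, dtype=np.int32)
    binned[m] = np.floor((x[m] - lo) / bin_width).astype(np.int32) + 1
    return binned, int(binned.max())


def log_filter(img: ImageVolume, sigma_mm: float) -> ImageVolume:
    """Scale-normalized Laplacian-of-Gaussian response.

    σ is in millimeters and is converted to per-axis voxel units through
    the image spacing; the response is multiplied by σ² (γ = 2 scale
    normalization) so that blob responses are comparable across the σ bank.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    sigma_vox = [sigma_mm / s for s in img.spacing_mm]
    sm = ndimage.gaussian_filter(img.voxels, sigma=sigma_vox, mode="reflect")
    out = np.zeros_like(sm)
    # exact discrete Laplacian (zero on constants), per-axis spacing weights
    for axis, sp in enumerate(img.spacing_mm):
        out += ndimage.correlate1d(
            sm, np.array([1.0, -2.0, 1.0]), axis=axis, mode="reflect"
        ) / sp**2
    return ImageVolume(out * sigma_mm**2, img.spacing_mm, img.origin_mm)


def log_bank(img: ImageVolume, sigmas_mm=(1.0, 2.0, 3.0, 4.0, 5.0)):
    """The five-σ LoG filter bank as ``{label: ImageVolume}``."""
    return {
        f"log-sigma-{int(s) if float(s).is_integer() else s}": log_filter(img, s)
        for s in sigmas_mm
    }


def wavelet_decompose(
    img: ImageVolume, wavelet: str = "coif1"
) -> dict[str, ImageVolume]:
    """Single-level stationary (undecimated) 3-D wavelet decomposition.

    Returns exactly 8 size-preserving subbands labeled by the low/high-pass
    choice per axis in (x, y, z) order: LLL, HLL, ..., HHH.  The stationary
    transform keeps every subband on the input grid so masks remain
    aligned.  Axes are edge-padded to even length for the transform and
    cropped back afterwards.
    """
    w = pywt.Wavelet(wavelet)
    data = img.voxels
    if min(data.shape) < w.dec_len:
        raise ValueError(
            f"grid {data.shape} smaller than the '{wavelet}' filter length "
            f"{w.dec_len} on some axis"
        )
    pad = [(0, s % 2) for s in data.shape]
    padded = np.pad(data, pad, mode="edge")
    coeffs = pywt.swtn(padded, w, level=1, start_level=0)[0]

    out: dict[str, ImageVolume] = {}
    nz, ny, nx = data.shape
    for key, arr in coeffs.items():
        # swtn keys are per array axis (z, y, x); report labels in (x, y, z)
        label = "".join("L" if c == "a" else "H" for c in reversed(key))
        out[f"wavelet-{label}"] = ImageVolume(
            arr[:nz, :ny, :nx], img.spacing_mm, img.origin_mm
        )
    assert len(out) == 8
    return {f"wavelet-{lab}": out[f"wavelet-{lab}"] for lab in WAVELET_LABELS}
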