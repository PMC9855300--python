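"""In-memory containers for 3-D image volumes and binary segmentation masks.

Arrays are indexed ``(z, y, x)`` — slice axis first, the natural order for a
CT stack — and ``spacing_mm`` / ``origin_mm`` are triples aligned with the
array axes, i.e. ``spacing_mm[0]`` is the through-plane section thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "SegmentationMask"]


def _as_triple(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected a length-3 sequence, got {v!r}")
    return t


@dataclass
class ImageVolume:
    """A 3-D intensity grid (HU-like units) with physical geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Finite intensities.
    spacing_mm : triple
        Voxel spacing per array axis ``(z, y, x)``; all positive.
    origin_mm : triple, optional
        Physical position of the center of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.voxels.copy(), self.spacing_mm, self.origin_mm)


@dataclass
class SegmentationMask:
    """A binary mask on the same grid as its paired image.

    ``voxels`` is stored as a boolean array; inputs must contain only
    values in {0, 1}.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError("mask voxels must be a 3-D array")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(
                    f"mask must be binary; found values {uniq[:10]!r}"
                )
            arr = arr.astype(bool)
        self.voxels = arr
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def check_aligned(self, img: ImageVolume) -> None:
        """Raise if this mask is not on the identical grid as ``img``."""
        if self.shape != img.shape:
            raise ValueError(
                f"mask shape {self.shape} != image shape {img.shape}"
            )
        if not np.allclose(self.spacing_mm, img.spacing_mm):
            raise ValueError(
                f"mask spacing {self.spacing_mm} != image spacing "
                f"{img.spacing_mm}"
            )

    def copy(self) -> "SegmentationMask":
        return SegmentationMask(self.voxels.copy(), self.spacing_mm, self.origin_mm)
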