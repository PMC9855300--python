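"""Volume I/O (NRRD / NIfTI via SimpleITK) and pipeline configuration."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

from .preprocess import PreprocessConfig
from .selection import FilterConfig, ResamplePlan
from .volume import ImageVolume, SegmentationMask

__all__ = ["read_volume", "write_volume", "PipelineConfig"]

_EXTENSIONS = (".nrrd", ".nii", ".nii.gz")


def _check_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(e) for e in _EXTENSIONS):
        raise ValueError(
            f"unsupported volume format {path.name!r}; expected one of "
            f"{_EXTENSIONS}"
        )


def write_volume(vol: ImageVolume | SegmentationMask, path: str | Path) -> None:
    """Write a volume or mask as NRRD or NIfTI-1 (by extension).

    Geometry is recorded in the header; masks are stored as uint8 {0,1}.
    """
    path = Path(path)
    _check_path(path)
    is_mask = isinstance(vol, SegmentationMask)
    arr = vol.voxels.astype(np.uint8) if is_mask else vol.voxels
    img = sitk.GetImageFromArray(arr)
    # SimpleITK orders spacing/origin (x, y, z); arrays are (z, y, x)
    img.SetSpacing(tuple(reversed(vol.spacing_mm)))
    img.SetOrigin(tuple(reversed(vol.origin_mm)))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_volume(path: str | Path, as_mask: bool = False):
    """Read an NRRD or NIfTI volume.

    Returns a :class:`SegmentationMask` (validating binarity) when
    ``as_mask`` is set, else an :class:`ImageVolume`.
    """
    path = Path(path)
    _check_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3-D volume, got {arr.ndim}-D")
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if as_mask:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(
                f"{path.name}: mask file is not binary (values "
                f"{uniq[:8].tolist()}...)"
            )
        return SegmentationMask(arr.astype(bool), spacing, origin)
    return ImageVolume(arr.astype(np.float64), spacing, origin)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration, loadable from YAML/JSON.

    The config hash and the global seed are embedded in every output
    artifact for provenance.
    """

    seed: int = 0
    n_patients: int = 60
    grid_shape: tuple[int, int, int] = (40, 48, 48)
    spacing_mm: tuple[float, float, float] = (2.5, 1.0, 1.0)
    prevalence: float = 0.656
    normalize_scale: float = 100.0
    clip_sigma: float = 3.0
    target_thickness_mm: float = 5.0
    bin_width: float = 25.0
    image_types: list[str] | None = None
    n_resamples: int = 100
    train_fraction: float = 0.8
    filter_alpha: float = 0.05
    target_fraction: float = 0.10
    target_k: int = 20
    cv_folds: int = 10

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            clip_sigma=self.clip_sigma,
            target_thickness_mm=self.target_thickness_mm,
            scale=self.normalize_scale,
        )

    def resample_plan(self) -> ResamplePlan:
        return ResamplePlan(
            n_resamples=self.n_resamples,
            train_fraction=self.train_fraction,
            base_seed=self.seed,
        )

    def filter_config(self) -> FilterConfig:
        return FilterConfig(alpha=self.filter_alpha)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        cfg = cls(**doc)
        cfg.grid_shape = tuple(cfg.grid_shape)
        cfg.spacing_mm = tuple(cfg.spacing_mm)
        return cfg

    def config_hash(self) -> str:
        doc = asdict(self)
        blob = json.dumps(doc, sort_keys=True, default=list).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"seed": self.seed, "config_hash": self.config_hash()}
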