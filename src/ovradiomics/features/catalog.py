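"""The feature catalog: which image types and families to extract.

The full catalog is 14 shape features (original-geometry mask only) plus
91 intensity/texture features (18 first-order + 22 GLCM + 16 GLRLM +
16 GLSZM + 14 GLDM + 5 NGTDM) on each of 14 image types (original, five
LoG responses, eight wavelet subbands): 14 + 14 × 91 = 1288.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .filters import WAVELET_LABELS
from .firstorder import FIRST_ORDER_NAMES
from .shape import SHAPE_NAMES
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
)

__all__ = ["FeatureCatalog", "FAMILY_NAMES", "ALL_IMAGE_TYPES"]

FAMILY_NAMES = {
    "firstorder": FIRST_ORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

LOG_IMAGE_TYPES = [f"log-sigma-{s}" for s in (1, 2, 3, 4, 5)]
WAVELET_IMAGE_TYPES = [f"wavelet-{lab}" for lab in WAVELET_LABELS]
ALL_IMAGE_TYPES = ["original"] + LOG_IMAGE_TYPES + WAVELET_IMAGE_TYPES


@dataclass
class FeatureCatalog:
    """Defines the extraction: image types, families, and bin width.

    The default configuration is the full 1288-feature catalog.
    """

    image_types: list[str] = field(default_factory=lambda: list(ALL_IMAGE_TYPES))
    families: list[str] = field(default_factory=lambda: list(FAMILY_NAMES))
    include_shape: bool = True
    bin_width: float = 25.0
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    wavelet: str = "coif1"

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        unknown = set(self.image_types) - set(ALL_IMAGE_TYPES)
        if unknown:
            raise ValueError(f"unknown image types: {sorted(unknown)}")
        unknown = set(self.families) - set(FAMILY_NAMES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")

    @property
    def feature_names(self) -> list[str]:
        """All feature names, ``<imagetype>_<family>_<feature>`` order."""
        names = []
        if self.include_shape:
            names += [f"original_shape_{n}" for n in SHAPE_NAMES]
        for itype in self.image_types:
            for fam in self.families:
                names += [f"{itype}_{fam}_{n}" for n in FAMILY_NAMES[fam]]
        return names

    def __len__(self) -> int:
        per_type = sum(len(FAMILY_NAMES[f]) for f in self.families)
        return (len(SHAPE_NAMES) if self.include_shape else 0) + len(
            self.image_types
        ) * per_type

    @classmethod
    def original_only(cls) -> "FeatureCatalog":
        """Shape + the 91 original-image features (105 total)."""
        return cls(image_types=["original"])

    def to_json(self, path: str | Path) -> None:
        doc = {
            "image_types": self.image_types,
            "families": self.families,
            "include_shape": self.include_shape,
            "bin_width": self.bin_width,
            "log_sigmas_mm": list(self.log_sigmas_mm),
            "wavelet": self.wavelet,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureCatalog":
        doc = json.loads(Path(path).read_text())
        doc["log_sigmas_mm"] = tuple(doc.get("log_sigmas_mm", (1, 2, 3, 4, 5)))
        return cls(**doc)
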