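"""Dice-based intra-/interobserver segmentation-agreement analysis.

Agreement between repeated tumor delineations is summarised by the Dice
similarity coefficient, DSC = 2|A∩B| / (|A| + |B|).  A mean DSC above 0.80
is the conventional bar for satisfactory reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import SegmentationMask

__all__ = ["dice", "AgreementReport", "agreement_study"]

SATISFACTORY_DSC = 0.80


def dice(a: SegmentationMask | np.ndarray, b: SegmentationMask | np.ndarray) -> float:
    """Dice similarity coefficient between two binary masks.

    Symmetric in its arguments.  If exactly one mask is empty the overlap
    is a total miss and the DSC is 0; two empty masks leave the
    coefficient undefined and raise ``ValueError``.
    """
    va = a.voxels if isinstance(a, SegmentationMask) else np.asarray(a, dtype=bool)
    vb = b.voxels if isinstance(b, SegmentationMask) else np.asarray(b, dtype=bool)
    if va.shape != vb.shape:
        raise ValueError(f"mask shapes differ: {va.shape} vs {vb.shape}")
    na = int(va.sum())
    nb = int(vb.sum())
    if na == 0 and nb == 0:
        raise ValueError("DSC is undefined for two empty masks")
    inter = int(np.logical_and(va, vb).sum())
    return 2.0 * inter / (na + nb)


@dataclass
class AgreementReport:
    """Per-comparison DSC summary of an observer-agreement study.

    ``table`` has one row per (comparison, case) with the DSC value;
    ``summary`` aggregates to mean (SD) per comparison with a
    satisfactory-reproducibility flag at the 0.80 threshold.
    """

    table: pd.DataFrame
    satisfactory_threshold: float = SATISFACTORY_DSC
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self):
        g = self.table.groupby("comparison")["dsc"]
        self.summary = pd.DataFrame(
            {
                "mean_dsc": g.mean(),
                "sd_dsc": g.std(ddof=1).fillna(0.0),
                "n_cases": g.size(),
            }
        )
        self.summary["satisfactory"] = (
            self.summary["mean_dsc"] > self.satisfactory_threshold
        )


def agreement_study(
    segmentations: dict[str, dict[str, SegmentationMask]],
    pairing_plan: list[tuple[str, str, str]],
    satisfactory_threshold: float = SATISFACTORY_DSC,
) -> AgreementReport:
    """Run a pairwise DSC study over repeated segmentations.

    Parameters
    ----------
    segmentations
        ``{case_id: {reading_key: mask}}`` where a reading key identifies
        an observer/repeat, e.g. ``"R1a"``, ``"R1b"``, ``"R3"``.
    pairing_plan
        List of ``(comparison_name, key_a, key_b)``, e.g.
        ``[("intra_R1", "R1a", "R1b"), ("inter_R1_R3", "R1a", "R3")]``.
        The study cohort design (which cases, which observers) lives
        entirely in this plan.

    Raises
    ------
    KeyError
        If any case lacks a reading required by the plan; the message
        lists the missing (case, key) pairs.
    """
    missing = [
        (case, key)
        for case, readings in segmentations.items()
        for _, ka, kb in pairing_plan
        for key in (ka, kb)
        if key not in readings
    ]
    if missing:
        raise KeyError(f"missing readings for cases: {sorted(set(missing))}")

    rows = []
    for name, ka, kb in pairing_plan:
        for case, readings in segmentations.items():
            rows.append(
                {
                    "comparison": name,
                    "case": case,
                    "dsc": dice(readings[ka], readings[kb]),
                }
            )
    return AgreementReport(pd.DataFrame(rows), satisfactory_threshold)
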