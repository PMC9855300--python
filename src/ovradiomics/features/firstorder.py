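"""First-order (intensity histogram) features — 18 scalars.

All statistics are computed over the in-mask voxel intensities; Entropy and
Uniformity use the fixed-bin-width discretized gray levels.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FIRST_ORDER_NAMES", "first_order_features"]

FIRST_ORDER_NAMES = [
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
]

_EPS = np.spacing(1.0)


def first_order_features(
    values: np.ndarray, binned: np.ndarray, voxel_volume_mm3: float
) -> dict[str, float]:
    """Compute the 18 first-order features.

    Parameters
    ----------
    values : in-mask intensities (1-D)
    binned : in-mask discretized gray levels (1-D, from :func:`discretize`)
    voxel_volume_mm3 : physical volume of one voxel (for TotalEnergy)
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty value array")
    n = x.size
    mean = x.mean()
    centered = x - mean
    var = float(np.mean(centered**2))  # population variance
    sd = np.sqrt(var)

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if sd > 0:
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / var**2)  # Pearson, not excess
    else:
        skew, kurt = 0.0, 0.0

    counts = np.bincount(np.asarray(binned, dtype=np.int64))[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p + _EPS)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume_mm3,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(centered).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
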