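"""Gray-level texture-matrix families on a discretized volume.

All five families operate on the int32 gray-level grid produced by
:func:`~ovradiomics.features.filters.discretize` (0 outside the mask,
levels 1..Ng inside) and use 3-D 26-connectivity: the 13 unique
unit-distance direction offsets (each counted with its negative).

Aggregation over directions: GLCM normalized co-occurrence matrices are
averaged over the 13 directions; GLRLM run matrices are summed (merged)
over directions before feature computation.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage

__all__ = [
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

_EPS = np.spacing(1.0)

#: The 13 unique 3-D direction offsets at Chebyshev distance 1.
DIRECTIONS = [
    (0, 0, 1),
    (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]

GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumEntropy", "SumSquares",
]

GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]

NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


def _offset_slices(off):
    """Paired slice tuples (src, dst) so that src voxel + off == dst voxel."""
    src, dst = [], []
    for o in off:
        if o == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif o > 0:
            src.append(slice(None, -o))
            dst.append(slice(o, None))
        else:
            src.append(slice(-o, None))
            dst.append(slice(None, o))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------- GLCM


def glcm_matrix(binned: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence matrix, normalized per direction and
    averaged over the 13 unit-distance directions."""
    acc = np.zeros((n_levels, n_levels), dtype=np.float64)
    n_dirs = 0
    for off in DIRECTIONS:
        s_src, s_dst = _offset_slices(off)
        a = binned[s_src].ravel()
        b = binned[s_dst].ravel()
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        idx = (a[valid] - 1) * n_levels + (b[valid] - 1)
        m = np.bincount(idx, minlength=n_levels * n_levels).reshape(
            n_levels, n_levels
        ).astype(np.float64)
        m = m + m.T  # symmetric pairs
        acc += m / m.sum()
        n_dirs += 1
    if n_dirs == 0:
        raise ValueError("no co-occurring voxel pairs inside the mask")
    return acc / n_dirs


def glcm_features(binned: np.ndarray, n_levels: int) -> dict[str, float]:
    """The 22 co-occurrence features from the direction-averaged matrix."""
    P = glcm_matrix(binned, n_levels)
    Ng = n_levels
    i = np.arange(1, Ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=1)  # == py by symmetry
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    k_sum = np.arange(2, 2 * Ng + 1, dtype=np.float64)
    p_sum = np.array([P[ii + jj == k].sum() for k in k_sum])
    k_diff = np.arange(0, Ng, dtype=np.float64)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in k_diff])

    da = float((k_diff * p_diff).sum())
    hx = float(-(px * np.log2(px + _EPS)).sum())
    hxy = float(-(P * np.log2(P + _EPS)).sum())
    pxpy = np.outer(px, px)
    hxy1 = float(-(P * np.log2(pxpy + _EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + _EPS)).sum())

    if sigma2 > 0:
        corr = float(((ii * jj * P).sum() - mu * mu) / sigma2)
    else:
        corr = 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    off_diag = np.abs(ii - jj) > 0
    inv_var = float((P[off_diag] / (ii - jj)[off_diag] ** 2).sum()) if off_diag.any() else 0.0

    return {
        "Autocorrelation": float((ii * jj * P).sum()),
        "JointAverage": mu,
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * P).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * P).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * P).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff * np.log2(p_diff + _EPS)).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((P / (1.0 + ((ii - jj) / Ng) ** 2)).sum()),
        "Id": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((P / (1.0 + np.abs(ii - jj) / Ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(P.max()),
        "SumEntropy": float(-(p_sum * np.log2(p_sum + _EPS)).sum()),
        "SumSquares": sigma2,
    }


# ---------------------------------------------------------------- GLRLM


@njit(cache=True)
def _run_length_matrix(binned, n_levels, max_run, dirs):  # pragma: no cover
    nz, ny, nx = binned.shape
    out = np.zeros((n_levels, max_run), dtype=np.float64)
    for d in range(dirs.shape[0]):
        dz, dy, dx = dirs[d, 0], dirs[d, 1], dirs[d, 2]
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    g = binned[z, y, x]
                    if g == 0:
                        continue
                    pz, py, px = z - dz, y - dy, x - dx
                    if (
                        0 <= pz < nz
                        and 0 <= py < ny
                        and 0 <= px < nx
                        and binned[pz, py, px] == g
                    ):
                        continue  # not a run start
                    length = 1
                    cz, cy, cx = z + dz, y + dy, x + dx
                    while (
                        0 <= cz < nz
                        and 0 <= cy < ny
                        and 0 <= cx < nx
                        and binned[cz, cy, cx] == g
                    ):
                        length += 1
                        cz += dz
                        cy += dy
                        cx += dx
                    out[g - 1, length - 1] += 1.0
    return out


def glrlm_matrix(binned: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length matrix R[level, length-1] summed over the 13 directions."""
    dirs = np.asarray(DIRECTIONS, dtype=np.int64)
    max_run = max(binned.shape)
    return _run_length_matrix(
        np.ascontiguousarray(binned), n_levels, max_run, dirs
    )


def _sre_family(M, n_voxels, n_dirs_or_zones, names, axis1_values):
    """Shared emphasis/non-uniformity feature math for run/zone/dependence
    matrices.  ``M[i, k]`` counts entities of gray level i+1 with size/
    length/dependence ``axis1_values[k]``."""
    Ns = M.sum()
    if Ns == 0:
        raise ValueError("empty texture matrix")
    i = np.arange(1, M.shape[0] + 1, dtype=np.float64)
    j = np.asarray(axis1_values, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = M / Ns
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())

    vals = {
        "small": float((M / jj**2).sum() / Ns),
        "large": float((M * jj**2).sum() / Ns),
        "gln": float((M.sum(axis=1) ** 2).sum() / Ns),
        "glnn": float((M.sum(axis=1) ** 2).sum() / Ns**2),
        "sn": float((M.sum(axis=0) ** 2).sum() / Ns),
        "snn": float((M.sum(axis=0) ** 2).sum() / Ns**2),
        "pct": float(Ns / n_voxels / n_dirs_or_zones),
        "glv": float(((ii - mu_i) ** 2 * p).sum()),
        "sv": float(((jj - mu_j) ** 2 * p).sum()),
        "ent": float(-(p * np.log2(p + _EPS)).sum()),
        "lgl": float((M / ii**2).sum() / Ns),
        "hgl": float((M * ii**2).sum() / Ns),
        "slgl": float((M / (ii**2 * jj**2)).sum() / Ns),
        "shgl": float((M * ii**2 / jj**2).sum() / Ns),
        "llgl": float((M * jj**2 / ii**2).sum() / Ns),
        "lhgl": float((M * ii**2 * jj**2).sum() / Ns),
    }
    order = [
        "small", "large", "gln", "glnn", "sn", "snn", "pct", "glv", "sv",
        "ent", "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl",
    ]
    return dict(zip(names, (vals[k] for k in order)))


def glrlm_features(binned: np.ndarray, n_levels: int) -> dict[str, float]:
    """The 16 run-length features from the direction-merged matrix."""
    R = glrlm_matrix(binned, n_levels)
    n_voxels = int((binned > 0).sum())
    lengths = np.arange(1, R.shape[1] + 1)
    return _sre_family(R, n_voxels, len(DIRECTIONS), GLRLM_NAMES, lengths)


# ---------------------------------------------------------------- GLSZM


def glszm_matrix(binned: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Size-zone matrix S[level, k] and the zone sizes for column k.

    A zone is a 26-connected component of equal gray level.  Only occupied
    size columns are kept (sizes returned alongside the matrix)."""
    structure = np.ones((3, 3, 3), dtype=bool)
    counts: dict[int, dict[int, int]] = {}
    sizes_seen: set[int] = set()
    for g in range(1, n_levels + 1):
        level_mask = binned == g
        if not level_mask.any():
            continue
        labeled, n_zones = ndimage.label(level_mask, structure=structure)
        zone_sizes = np.bincount(labeled.ravel())[1:]
        row: dict[int, int] = {}
        for s in zone_sizes:
            row[int(s)] = row.get(int(s), 0) + 1
            sizes_seen.add(int(s))
        counts[g] = row
    if not sizes_seen:
        raise ValueError("no zones found inside the mask")
    sizes = np.array(sorted(sizes_seen))
    S = np.zeros((n_levels, len(sizes)), dtype=np.float64)
    col = {s: k for k, s in enumerate(sizes)}
    for g, row in counts.items():
        for s, c in row.items():
            S[g - 1, col[s]] = c
    return S, sizes


def glszm_features(binned: np.ndarray, n_levels: int) -> dict[str, float]:
    """The 16 size-zone features."""
    S, sizes = glszm_matrix(binned, n_levels)
    n_voxels = int((binned > 0).sum())
    return _sre_family(S, n_voxels, 1, GLSZM_NAMES, sizes)


# ---------------------------------------------------------------- GLDM


def gldm_matrix(binned: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence matrix D[level, d-1]: d = 1 + number of 26-neighbors
    (in-mask) whose gray level differs from the center by at most alpha."""
    mask = binned > 0
    dep = np.zeros(binned.shape, dtype=np.int32)
    for off in DIRECTIONS:
        for sign in (1, -1):
            o = tuple(sign * c for c in off)
            s_src, s_dst = _offset_slices(o)
            same = (
                mask[s_src]
                & mask[s_dst]
                & (np.abs(binned[s_src] - binned[s_dst]) <= alpha)
            )
            dep[s_src] += same
    dep_in = dep[mask] + 1  # the center voxel always depends on itself
    levels = binned[mask]
    max_dep = int(dep_in.max())
    D = np.zeros((n_levels, max_dep), dtype=np.float64)
    np.add.at(D, (levels - 1, dep_in - 1), 1.0)
    return D


def gldm_features(binned: np.ndarray, n_levels: int, alpha: int = 0) -> dict[str, float]:
    """The 14 gray-level dependence features."""
    D = gldm_matrix(binned, n_levels, alpha)
    n_voxels = int((binned > 0).sum())
    deps = np.arange(1, D.shape[1] + 1)
    full = _sre_family(D, n_voxels, 1, GLSZM_NAMES, deps)
    # the GLDM set drops the two size-nonuniformity-normalized/percentage
    # style entries that are constant (every voxel contributes one entry)
    order = [
        "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
        "SizeZoneNonUniformity", "SizeZoneNonUniformityNormalized",
        "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
        "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
        "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
        "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
    ]
    return dict(zip(GLDM_NAMES, (full[k] for k in order)))


# ---------------------------------------------------------------- NGTDM


def ngtdm_features(binned: np.ndarray, n_levels: int) -> dict[str, float]:
    """The 5 neighboring-gray-tone-difference features."""
    mask = binned > 0
    n_voxels = int(mask.sum())
    if n_voxels == 0:
        raise ValueError("mask is empty")

    kernel = np.ones((3, 3, 3), dtype=np.float64)
    kernel[1, 1, 1] = 0.0
    vals = np.where(mask, binned.astype(np.float64), 0.0)
    nb_sum = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mask.astype(np.float64), kernel, mode="constant")

    has_nb = mask & (nb_cnt > 0)
    avg = np.zeros(binned.shape)
    avg[has_nb] = nb_sum[has_nb] / nb_cnt[has_nb]

    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    lv = binned[has_nb]
    np.add.at(n_i, lv - 1, 1.0)
    np.add.at(s_i, lv - 1, np.abs(lv - avg[has_nb]))

    N = n_i.sum()
    p_i = n_i / N
    i = np.arange(1, n_levels + 1, dtype=np.float64)
    nz = p_i > 0
    Ngp = int(nz.sum())

    ii, jj = np.meshgrid(i[nz], i[nz], indexing="ij")
    pi, pj = np.meshgrid(p_i[nz], p_i[nz], indexing="ij")
    si, sj = np.meshgrid(s_i[nz], s_i[nz], indexing="ij")

    coars_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coars_den if coars_den > 0 else 1e6

    if Ngp > 1:
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum()
            / (Ngp * (Ngp - 1))
            * (s_i.sum() / N)
        )
    else:
        contrast = 0.0

    busy_den = float(np.abs(ii * pi - jj * pj).sum())
    busyness = coars_den / busy_den if busy_den > 0 else 0.0

    complexity = float(
        (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / N
    )

    s_sum = float(s_i.sum())
    strength = (
        float(((pi + pj) * (ii - jj) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
    )

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
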