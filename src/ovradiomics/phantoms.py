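"""Synthetic 3-D tumor phantoms with controllable sphericity and texture.

Real multicenter CT data cannot be redistributed, so the pipeline is
exercised on phantoms.  Each phantom is a star-convex solid: an ellipsoid
whose radius is modulated by a smooth random angular field (lobulation)
and which may additionally be stretched along a random axis (elongation).
A single irregularity parameter drives both, and is tuned per phantom by
bisection until the measured mesh sphericity hits a target drawn from the
class distribution — HGSC tumors are less spherical (mean 0.608, SD
0.082) than non-HGSC (mean 0.669, SD 0.066).  If a drawn angular field
cannot reach the target at any irregularity, the field is redrawn
(accept/adjust).  Intensities are smoothed Gaussian fields in
Hounsfield-like units with class-specific heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .features.shape import _mesh_volume, mask_mesh, sphericity
from .volume import ImageVolume, SegmentationMask

__all__ = ["PhantomConfig", "generate_phantom", "measured_sphericity"]

#: Class sphericity distributions (mean, SD) on the full data set.
CLASS_SPHERICITY = {"HGSC": (0.608, 0.082), "nonHGSC": (0.669, 0.066)}

#: Class texture heterogeneity (in-mask intensity SD, HU).  The source
#: study reports only the shape difference between classes; this texture
#: contrast is a free parameter of the generator, not an empirical claim.
CLASS_TEXTURE_SD = {"HGSC": 45.0, "nonHGSC": 30.0}

_MAX_IRREGULARITY = 1.6
_MAX_FIELD_AMPLITUDE = 1.1
_FIELD_REDRAWS = 10


@dataclass
class PhantomConfig:
    """Configuration of one phantom draw.

    ``lobulation_amplitude=None`` (the default) engages per-phantom
    bisection on an irregularity parameter (radial lobulation plus
    elongation) so the measured sphericity matches a target drawn from
    ``N(sphericity_mean, sphericity_sd)``; a fixed value (e.g. 0 for a
    plain ellipsoid) applies that radial-field amplitude directly with no
    elongation.  ``axis_ratios=None`` draws mild random base-axis ratios;
    pass ``(1, 1, 1)`` for an equal-axis base.
    """

    class_label: str = "HGSC"
    sphericity_mean: float | None = None
    sphericity_sd: float | None = None
    grid_shape: tuple[int, int, int] = (56, 56, 56)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    texture_mean_hu: float = 50.0
    texture_sd_hu: float | None = None
    lobulation_amplitude: float | None = None
    lobulation_order: int = 8
    radius_fraction: float = 0.24
    axis_ratios: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_SPHERICITY:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.sphericity_mean is None:
            self.sphericity_mean = CLASS_SPHERICITY[self.class_label][0]
        if self.sphericity_sd is None:
            self.sphericity_sd = CLASS_SPHERICITY[self.class_label][1]
        if self.texture_sd_hu is None:
            self.texture_sd_hu = CLASS_TEXTURE_SD[self.class_label]
        if not 0.0 < self.sphericity_mean < 1.0:
            raise ValueError("sphericity_mean must be in (0, 1)")
        if self.sphericity_sd < 0 or self.texture_sd_hu < 0:
            raise ValueError("SD parameters must be nonnegative")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.lobulation_order < 1:
            raise ValueError("lobulation_order must be >= 1")


def measured_sphericity(mask: SegmentationMask) -> float:
    """Mesh-based sphericity of a mask (marching-cubes V and A)."""
    verts, faces = mask_mesh(mask)
    vol = _mesh_volume(verts, faces)
    area = float(measure.mesh_surface_area(verts, faces))
    return sphericity(vol, area)


class _Geometry:
    """Precomputed voxel-center coordinates and angles for one grid."""

    def __init__(self, shape, spacing):
        zc, yc, xc = [
            (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
        ]
        self.Z, self.Y, self.X = np.meshgrid(zc, yc, xc, indexing="ij")
        r = np.sqrt(self.Z**2 + self.Y**2 + self.X**2)
        self.theta = np.arccos(
            np.clip(self.Z / np.maximum(r, 1e-12), -1.0, 1.0)
        )
        self.phi = np.arctan2(self.Y, self.X)
        self.half_extent = min(n * s for n, s in zip(shape, spacing)) / 2.0


def _angular_field(rng: np.random.Generator, order: int, geo: _Geometry):
    """Smooth random field on the sphere: trigonometric series up to the
    given order, azimuthal terms damped toward the poles; standardized to
    zero mean / unit SD over the grid directions."""
    p = np.zeros_like(geo.theta)
    sin_t = np.sin(geo.theta)
    for k in range(1, order + 1):
        a, b, c = rng.normal(0.0, 1.0 / np.sqrt(k), size=3)
        d = rng.uniform(0, 2 * np.pi)
        p += sin_t**k * (a * np.cos(k * geo.phi) + b * np.sin(k * geo.phi))
        p += c * np.cos(k * geo.theta + d)
    return (p - p.mean()) / max(p.std(), 1e-12)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = np.bincount(labeled.ravel())[1:]
    return labeled == (int(sizes.argmax()) + 1)


def _build_mask(geo, r0, ratios, stretch_axis, u, amplitude, pvox):
    """Voxelize the solid at irregularity ``u`` / field amplitude given.

    The base ellipsoid is stretched 1+2u along one axis and compressed
    1/(1+0.5u) along another; axes are rescaled if the stretched solid
    would leave the grid.  The radius multiplier 1 + amplitude·field is
    clipped (to [0.5, 1.5] for u ≤ 1, deepening slightly beyond) to keep
    the solid star-convex and connected.
    """
    stretch = np.ones(3)
    stretch[stretch_axis] = 1.0 + 2.0 * u
    stretch[(stretch_axis + 1) % 3] = 1.0 / (1.0 + 0.5 * u)
    axes = r0 * np.asarray(ratios) * stretch
    scale = min(1.0, 0.95 * geo.half_extent / (axes.max() * 1.2))
    axes = axes * scale
    rho = np.sqrt(
        (geo.Z / axes[0]) ** 2 + (geo.Y / axes[1]) ** 2 + (geo.X / axes[2]) ** 2
    )
    lo_clip = 0.5 - 0.12 * max(u - 1.0, 0.0)
    mult = np.clip(1.0 + amplitude * pvox, lo_clip, 1.5)
    return _largest_component(rho <= mult)


def generate_phantom(cfg: PhantomConfig) -> tuple[ImageVolume, SegmentationMask]:
    """Draw one phantom image/mask pair.

    Deterministic for identical configs (all randomness flows from
    ``cfg.seed``).  Raises a sizing error when the grid is too small for
    the requested tumor radius.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(int(s) for s in cfg.grid_shape)
    spacing = np.asarray(cfg.spacing_mm, dtype=float)

    geo = _Geometry(shape, spacing)
    r0 = cfg.radius_fraction * 2.0 * geo.half_extent
    if r0 < 4.0 * spacing.max() or min(shape) < 12:
        raise ValueError(
            f"grid {shape} at spacing {cfg.spacing_mm} too small for a "
            f"phantom of radius {r0:.1f} mm"
        )

    if cfg.axis_ratios is not None:
        ratios = np.asarray(cfg.axis_ratios, dtype=float)
        rng.uniform(0.9, 1.12, size=3)  # keep the stream position fixed
    else:
        ratios = rng.uniform(0.9, 1.12, size=3)
        ratios /= np.prod(ratios) ** (1 / 3)
    stretch_axis = int(rng.integers(0, 3))
    pvox = _angular_field(rng, cfg.lobulation_order, geo)

    if cfg.lobulation_amplitude is not None:
        mask_arr = _build_mask(
            geo, r0, ratios, stretch_axis, 0.0, cfg.lobulation_amplitude, pvox
        )
    else:
        target = float(
            np.clip(
                rng.normal(cfg.sphericity_mean, cfg.sphericity_sd), 0.42, 0.92
            )
        )
        mask_arr = _target_sphericity(
            geo, r0, ratios, stretch_axis, pvox, target, cfg, rng
        )

    if not mask_arr.any():
        raise ValueError("phantom mask came out empty; enlarge the grid")
    mask = SegmentationMask(mask_arr, cfg.spacing_mm)

    # intensity texture: smoothed Gaussian fields, variance restored
    def _field(mean, sd, smooth):
        noise = rng.standard_normal(shape)
        sm = ndimage.gaussian_filter(noise, smooth)
        sm /= max(sm.std(), 1e-12)
        return mean + sd * sm

    background = _field(20.0, 10.0, 1.5)
    interior = _field(cfg.texture_mean_hu, cfg.texture_sd_hu, 1.0)
    voxels = np.where(mask_arr, interior, background)
    return ImageVolume(voxels, cfg.spacing_mm), mask


def _target_sphericity(
    geo, r0, ratios, stretch_axis, pvox, target, cfg, rng, tol=0.01, max_iter=14
):
    """Bisection on the irregularity parameter until the measured mesh
    sphericity is within ``tol`` of the target.  Sphericity decreases as
    irregularity grows; a field whose reachable range misses the target
    is redrawn with fresh randomness."""

    def measure_at(u, field):
        amp = _MAX_FIELD_AMPLITUDE * min(u, 1.0) + 0.45 * max(u - 1.0, 0.0)
        m = _build_mask(geo, r0, ratios, stretch_axis, u, amp, field)
        if not m.any():
            return m, -1.0
        return m, measured_sphericity(SegmentationMask(m, cfg.spacing_mm))

    field = pvox
    best_mask, best_err = None, np.inf
    for _ in range(_FIELD_REDRAWS):
        lo, hi = 0.0, _MAX_IRREGULARITY
        m_lo, s_lo = measure_at(lo, field)
        if s_lo <= target + tol:  # base ellipsoid already at/below target
            return m_lo
        m_hi, s_hi = measure_at(hi, field)
        if s_hi > target:  # floor of this field is above the target
            if abs(s_hi - target) < best_err:
                best_mask, best_err = m_hi, abs(s_hi - target)
            field = _angular_field(rng, cfg.lobulation_order, geo)
            continue
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            m_mid, s_mid = measure_at(mid, field)
            err = abs(s_mid - target)
            if err < best_err:
                best_mask, best_err = m_mid, err
            if err <= tol:
                return m_mid
            if s_mid > target:
                lo = mid
            else:
                hi = mid
        if best_err <= 2 * tol:
            return best_mask
        field = _angular_field(rng, cfg.lobulation_order, geo)
    return best_mask
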