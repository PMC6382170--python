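"""Interpolation, re-segmentation, outlier exclusion and grey-level discretization.

The fixed pipeline order is: interpolate -> re-segment -> exclude outliers ->
discretize.  Morphology, first-order statistics and local-intensity features
read the un-discretized ROI; histogram and texture families read the
discretized one.  Re-segmentation and outlier exclusion shrink only the
*intensity* mask; the *morphological* mask keeps the original VOI shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy import ndimage

from .io_core import EmptyVOIError, ImageVolume, MaskVolume

__all__ = [
    "ROI",
    "DiscretizationMethod",
    "DiscretizationRule",
    "DiscretizedROI",
    "extract_roi",
    "interpolate_image",
    "interpolate_mask",
    "resegment_range",
    "exclude_outliers",
    "discretize",
    "discretize_ivh",
    "IVH_FALLBACK_BINS",
]

IVH_FALLBACK_BINS = 1000  # fraction curves on continuous data use a fine FBN grid


# ---------------------------------------------------------------------------
# ROI container


@dataclass(frozen=True)
class ROI:
    """Paired intensity and morphological voxel sets on a common grid.

    ``image`` holds the full intensity grid; ``intensity_mask`` marks voxels
    whose intensities enter statistics/texture; ``morph_mask`` marks the VOI
    shape used for meshes and zone distances.  Invariant:
    ``intensity_mask <= morph_mask`` and both nonempty.
    """

    image: np.ndarray
    intensity_mask: np.ndarray
    morph_mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        im = np.asarray(self.image, dtype=float)
        imask = np.asarray(self.intensity_mask, dtype=bool)
        mmask = np.asarray(self.morph_mask, dtype=bool)
        if im.shape != imask.shape or im.shape != mmask.shape:
            raise ValueError("image and masks must share one shape")
        if not imask.any():
            raise EmptyVOIError("intensity mask is empty")
        if np.any(imask & ~mmask):
            raise ValueError("intensity mask must be a subset of the morphological mask")
        object.__setattr__(self, "image", im)
        object.__setattr__(self, "intensity_mask", imask)
        object.__setattr__(self, "morph_mask", mmask)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def intensities(self) -> np.ndarray:
        """Flat array of ROI intensity values."""
        return self.image[self.intensity_mask]

    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


def extract_roi(image: ImageVolume, mask: MaskVolume) -> ROI:
    """Pair an image with its aligned binary mask."""
    mask.check_aligned(image)
    m = mask.values.astype(bool)
    if not m.any():
        raise EmptyVOIError("mask holds no voxels")
    return ROI(image.values, m, m, image.spacing, image.origin)


# ---------------------------------------------------------------------------
# Interpolation

_ORDER = {"nearest": 0, "trilinear": 1, "cubic_spline": 3}


def _axis_grid(n_in: int, s_in: float, s_out: float) -> tuple[int, np.ndarray]:
    """Output sample positions along one axis, in input index units.

    The output grid is centered on the input physical center ("align by
    center"), so resampling commutes with rigid translation of the origin.
    """
    n_out = max(1, int(math.ceil(n_in * s_in / s_out)))
    shift = ((n_in - 1) * s_in - (n_out - 1) * s_out) / 2.0
    return n_out, (shift + np.arange(n_out) * s_out) / s_in


def interpolate_image(
    image: ImageVolume,
    target_spacing: tuple[float, float, float],
    method: str = "trilinear",
    mode: str = "full_3d",
) -> ImageVolume:
    """Resample to a new voxel spacing (mm, world order dx, dy, dz).

    ``slicewise_2d`` resamples in-plane only, leaving dz and the slice count
    unchanged.  Cubic splines use mirror extension at the boundary; nearest
    and trilinear clamp to the edge value.
    """
    if method not in _ORDER:
        raise ValueError(f"unknown interpolation method {method!r}")
    ts = tuple(float(s) for s in target_spacing)
    if len(ts) != 3 or not all(np.isfinite(ts)) or any(s <= 0 for s in ts):
        raise ValueError(f"target spacing must be finite and positive, got {target_spacing}")
    if mode not in ("full_3d", "slicewise_2d"):
        raise ValueError(f"unknown interpolation mode {mode!r}")

    dx, dy, dz = image.spacing
    nz, ny, nx = image.shape
    tx, ty, tz = ts
    if mode == "slicewise_2d":
        tz = dz  # slice geometry untouched

    nxo, cx = _axis_grid(nx, dx, tx)
    nyo, cy = _axis_grid(ny, dy, ty)
    if mode == "slicewise_2d":
        nzo, cz = nz, np.arange(nz, dtype=float)
    else:
        nzo, cz = _axis_grid(nz, dz, tz)

    kz, jy, ix = np.meshgrid(cz, cy, cx, indexing="ij")
    order = _ORDER[method]
    bmode = "mirror" if order == 3 else "nearest"
    out = ndimage.map_coordinates(
        image.values, [kz, jy, ix], order=order, mode=bmode, prefilter=(order == 3)
    )
    x0, y0, z0 = image.origin
    new_origin = (x0 + cx[0] * dx, y0 + cy[0] * dy, z0 + cz[0] * dz)
    return ImageVolume(out, (tx, ty, tz), new_origin, image.modality)


def interpolate_mask(
    mask: MaskVolume,
    target_spacing: tuple[float, float, float],
    method: str = "trilinear",
    mode: str = "full_3d",
    threshold: float = 0.5,
) -> MaskVolume:
    """Resample the mask as a scalar field, then re-binarize at ``threshold``
    (inclusive)."""
    as_img = ImageVolume(mask.values.astype(float), mask.spacing, mask.origin)
    interp = interpolate_image(as_img, target_spacing, method, mode)
    binary = (interp.values >= threshold).astype(np.uint8)
    if binary.sum() == 0:
        raise EmptyVOIError("mask vanished after interpolation and re-binarization")
    return MaskVolume(binary, interp.spacing, interp.origin)


# ---------------------------------------------------------------------------
# Re-segmentation and outlier exclusion


def resegment_range(
    roi: ROI, min_val: Optional[float] = None, max_val: Optional[float] = None
) -> ROI:
    """Keep only intensities in the closed interval [min_val, max_val] in the
    intensity mask; the morphological mask is untouched."""
    if min_val is not None and max_val is not None and min_val > max_val:
        raise ValueError("min_val must not exceed max_val")
    keep = roi.intensity_mask.copy()
    if min_val is not None:
        keep &= roi.image >= min_val
    if max_val is not None:
        keep &= roi.image <= max_val
    if not keep.any():
        raise EmptyVOIError("re-segmentation removed every ROI voxel")
    return ROI(roi.image, keep, roi.morph_mask, roi.spacing, roi.origin)


def exclude_outliers(roi: ROI, n_sigma: float = 3.0) -> ROI:
    """Drop intensities outside mu +/- n_sigma * sigma (population sigma, one pass)."""
    vals = roi.intensities
    mu = float(vals.mean())
    sigma = float(vals.std())  # population
    if sigma == 0:
        return roi
    keep = roi.intensity_mask & (roi.image >= mu - n_sigma * sigma) & (
        roi.image <= mu + n_sigma * sigma
    )
    if not keep.any():
        raise EmptyVOIError("outlier exclusion removed every ROI voxel")
    return ROI(roi.image, keep, roi.morph_mask, roi.spacing, roi.origin)


# ---------------------------------------------------------------------------
# Discretization


class DiscretizationMethod(str, Enum):
    FBN = "FBN"  # fixed bin number
    FBS = "FBS"  # fixed bin size


@dataclass(frozen=True)
class DiscretizationRule:
    method: DiscretizationMethod
    n_bins: Optional[int] = None
    bin_width: Optional[float] = None
    lower_bound: Optional[float] = None  # FBS anchor; defaults to ROI minimum

    def __post_init__(self):
        m = DiscretizationMethod(self.method)
        object.__setattr__(self, "method", m)
        if m is DiscretizationMethod.FBN:
            if self.n_bins is None or int(self.n_bins) < 1:
                raise ValueError("FBN requires n_bins >= 1")
            object.__setattr__(self, "n_bins", int(self.n_bins))
        else:
            if self.bin_width is None or not self.bin_width > 0:
                raise ValueError("FBS requires bin_width > 0")


@dataclass(frozen=True)
class DiscretizedROI:
    """ROI with integer grey levels 1..Ng (0 outside the intensity mask)."""

    levels: np.ndarray
    ng: int
    rule: DiscretizationRule
    intensity_mask: np.ndarray
    morph_mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source_image: Optional[np.ndarray] = None  # original intensities, for IVH back-mapping

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=np.int64)
        imask = np.asarray(self.intensity_mask, dtype=bool)
        inside = lv[imask]
        if inside.size == 0:
            raise EmptyVOIError("discretized ROI is empty")
        if inside.min() < 1 or inside.max() > self.ng or self.ng < 1:
            raise ValueError("levels must lie in 1..Ng")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "intensity_mask", imask)
        object.__setattr__(self, "morph_mask", np.asarray(self.morph_mask, dtype=bool))

    @property
    def roi_levels(self) -> np.ndarray:
        """Flat array of grey levels inside the ROI."""
        return self.levels[self.intensity_mask]

    def n_voxels(self) -> int:
        return int(self.intensity_mask.sum())


def _apply_rule(values: np.ndarray, rule: DiscretizationRule) -> tuple[np.ndarray, int]:
    if rule.method is DiscretizationMethod.FBN:
        nb = rule.n_bins
        vmin, vmax = values.min(), values.max()
        if vmax == vmin:
            return np.ones_like(values, dtype=np.int64), 1
        lv = np.floor(nb * (values - vmin) / (vmax - vmin)).astype(np.int64) + 1
        np.minimum(lv, nb, out=lv)  # top bin closed
        return lv, int(nb)
    w = rule.bin_width
    b0 = rule.lower_bound if rule.lower_bound is not None else float(values.min())
    lv = np.floor((values - b0) / w).astype(np.int64) + 1
    lv = np.maximum(lv, 1)
    return lv, int(lv.max())


def discretize(roi: ROI, rule: DiscretizationRule) -> DiscretizedROI:
    """Map ROI intensities to integer grey levels 1..Ng.

    FBN: level = min(floor(Nb*(x - xmin)/(xmax - xmin)) + 1, Nb), Ng = Nb;
    a constant ROI maps to level 1 with Ng = 1.  FBS: level =
    floor((x - b0)/w) + 1 with anchor b0 = lower_bound (the re-segmentation
    lower bound when present) or else the ROI minimum; Ng = max level.
    Bins are half-open [b0+(k-1)w, b0+kw) except the closed top FBN bin.
    """
    vals = roi.intensities
    lv, ng = _apply_rule(vals, rule)
    grid = np.zeros(roi.image.shape, dtype=np.int64)
    grid[roi.intensity_mask] = lv
    return DiscretizedROI(
        grid, ng, rule, roi.intensity_mask, roi.morph_mask, roi.spacing, roi.origin,
        source_image=roi.image,
    )


def discretize_ivh(roi: ROI, rule: Optional[DiscretizationRule] = None) -> DiscretizedROI:
    """Discretization for the intensity-volume-histogram family, configured
    independently of the texture discretization.  When no rule is given,
    continuous intensities are kept effectively continuous through a fine
    fixed-bin-number grid (:data:`IVH_FALLBACK_BINS` bins)."""
    if rule is None:
        rule = DiscretizationRule(DiscretizationMethod.FBN, n_bins=IVH_FALLBACK_BINS)
    return discretize(roi, rule)
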