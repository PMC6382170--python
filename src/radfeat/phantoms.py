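"""Synthetic test inputs: voxelized spheres, seeded integer grids, and a small
hand-checkable digital phantom.

The sphere generator reproduces the geometry of the NEMA image-quality
phantom's fillable spheres (diameters 37, 28, 21, 17, 13, 10 mm) voxelized at
the PET reconstruction spacing 3.1819 x 3.1819 x 2 mm, with a default
foreground:background intensity ratio of 10:1.  Masks include a voxel iff its
*center* lies inside the sphere, matching the mask semantics used everywhere
else in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_core import GeometryError, ImageVolume, MaskVolume
from .preprocess import (
    ROI,
    DiscretizationMethod,
    DiscretizationRule,
    DiscretizedROI,
)

__all__ = [
    "SphereSpec",
    "NEMA_SPACING",
    "NEMA_DIAMETERS",
    "make_sphere",
    "make_grid",
    "make_digital_phantom",
]

NEMA_SPACING: tuple[float, float, float] = (3.1819, 3.1819, 2.0)
NEMA_DIAMETERS: tuple[float, ...] = (37.0, 28.0, 21.0, 17.0, 13.0, 10.0)


@dataclass(frozen=True)
class SphereSpec:
    """Geometry of one voxelized sphere.

    ``center_offset`` shifts the sphere center off the central voxel center,
    in fractions of a voxel per axis (x, y, z); ``margin`` is the number of
    background voxels padded around the sphere's bounding extent.
    """

    diameter: float
    spacing: tuple[float, float, float] = NEMA_SPACING
    center_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    margin: int = 2
    foreground: float = 10.0
    background: float = 1.0

    def __post_init__(self):
        if self.diameter <= max(self.spacing):
            raise GeometryError("sphere diameter must exceed the largest voxel spacing")
        if self.margin < 1:
            raise GeometryError("at least one voxel of background padding is required")


def make_sphere(spec: SphereSpec) -> tuple[ImageVolume, MaskVolume]:
    """Voxelize a sphere: mask voxels are those whose centers lie within
    diameter/2 of the sphere center; the image is foreground inside,
    background outside (default 10:1)."""
    r = spec.diameter / 2.0
    dx, dy, dz = spec.spacing
    half = [int(math.ceil(r / s)) + spec.margin for s in (dx, dy, dz)]
    nx, ny, nz = (2 * h + 1 for h in half)
    cx = half[0] * dx + spec.center_offset[0] * dx
    cy = half[1] * dy + spec.center_offset[1] * dy
    cz = half[2] * dz + spec.center_offset[2] * dz
    zc, yc, xc = np.meshgrid(
        np.arange(nz) * dz, np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij"
    )
    inside = (xc - cx) ** 2 + (yc - cy) ** 2 + (zc - cz) ** 2 <= r**2
    if not inside.any():
        raise GeometryError("sphere encloses no voxel centers")
    img = np.where(inside, spec.foreground, spec.background)
    image = ImageVolume(img, spec.spacing)
    mask = MaskVolume(inside.astype(np.uint8), spec.spacing)
    return image, mask


def make_grid(
    shape: tuple[int, int, int], ng: int, seed: int, spacing=(1.0, 1.0, 1.0)
) -> DiscretizedROI:
    """Reproducible integer grid with levels uniform over 1..Ng and a full mask."""
    rng = np.random.default_rng(seed)
    levels = rng.integers(1, ng + 1, size=shape)
    mask = np.ones(shape, dtype=bool)
    rule = DiscretizationRule(DiscretizationMethod.FBN, n_bins=ng)
    return DiscretizedROI(levels, ng, rule, mask, mask, spacing)


# A fixed 4x4x5 grid with small integer levels and an irregular mask.  The
# values are arbitrary but frozen; oracle tests hand-compute features on it.
_PHANTOM_VALUES = np.array(
    [
        [[1, 4, 4, 1, 1], [1, 4, 6, 1, 1], [4, 1, 6, 4, 1], [4, 4, 6, 4, 1]],
        [[1, 4, 6, 1, 1], [1, 1, 6, 1, 1], [1, 1, 3, 1, 1], [4, 4, 6, 1, 1]],
        [[1, 4, 6, 4, 1], [1, 1, 1, 1, 1], [1, 1, 1, 1, 1], [1, 1, 6, 1, 1]],
        [[1, 4, 4, 1, 1], [1, 1, 1, 1, 1], [1, 1, 1, 1, 1], [1, 1, 6, 1, 1]],
    ],
    dtype=float,
)

_PHANTOM_MASK = np.ones_like(_PHANTOM_VALUES, dtype=bool)
_PHANTOM_MASK[0, 0, 4] = False
_PHANTOM_MASK[1, 0, 4] = False
_PHANTOM_MASK[3, 2, 4] = False
_PHANTOM_MASK[3, 3, 2] = False


def make_digital_phantom() -> tuple[ImageVolume, MaskVolume]:
    """Small synthetic digital phantom (4 slices of 4x5 voxels, levels 1..6,
    irregular mask) used as a hand-checkable regression fixture.  Deterministic:
    repeated calls return identical volumes."""
    image = ImageVolume(_PHANTOM_VALUES.copy(), (2.0, 2.0, 2.0))
    mask = MaskVolume(_PHANTOM_MASK.astype(np.uint8), (2.0, 2.0, 2.0))
    return image, mask


def phantom_roi() -> ROI:
    img, mask = make_digital_phantom()
    m = mask.values.astype(bool)
    return ROI(img.values, m, m, img.spacing, img.origin)
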