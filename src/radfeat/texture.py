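"""Texture matrices (GLCM, GLRLM, GLSZM, GLDZM, NGTDM, NGLDM) and their features.

All matrices are built from the discretized ROI at neighbourhood distance 1
(Chebyshev), in 2D (slice by slice; 4 unique in-plane directions, 8-connected
neighbourhoods) or 3D (13 unique directions, 26-connected neighbourhoods).

Six aggregation schemes combine per-slice/per-direction matrices:

========================  =====================================================
AVG_2D                    features per (slice, direction), averaged over all
SLICE_MERGED_2D           directions merged per slice, features averaged over slices
DIR_MERGED_2D             slices merged per direction, features averaged over directions
MERGED_2D                 every 2D matrix merged into one
AVG_3D                    features per 3D direction, averaged (directional families)
MERGED_3D                 all 3D matrices merged into one
========================  =====================================================

Merging always sums *count* matrices (and their voxel scopes) before
normalization.  GLSZM/GLDZM/NGTDM/NGLDM have no directions, so their schemes
reduce to {AVG_2D, MERGED_2D, MERGED_3D}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Optional

import numpy as np
from scipy import ndimage

from .preprocess import DiscretizedROI

__all__ = [
    "AggregationScheme",
    "TextureMatrix",
    "DIRECTIONS_2D",
    "DIRECTIONS_3D",
    "glcm",
    "glcm_features",
    "glrlm",
    "glrlm_features",
    "glszm",
    "glszm_features",
    "gldzm",
    "gldzm_features",
    "ngtdm",
    "ngtdm_features",
    "ngldm",
    "ngldm_features",
    "aggregate",
    "DIRECTIONAL_FAMILIES",
    "TEXTURE_FAMILIES",
    "COARSENESS_CAP",
]

COARSENESS_CAP = 1e6

# Unique displacement vectors (dz, dy, dx), one per +/- pair, Chebyshev norm 1.
DIRECTIONS_2D: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (0, 1, 1),
    (0, 1, -1),
)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

DIRECTIONAL_FAMILIES = ("GLCM", "GLRLM")
TEXTURE_FAMILIES = ("GLCM", "GLRLM", "GLSZM", "GLDZM", "NGTDM", "NGLDM")


class AggregationScheme(str, Enum):
    AVG_2D = "2Davg"
    SLICE_MERGED_2D = "2Dmrg"
    DIR_MERGED_2D = "2DDmrg"
    MERGED_2D = "2Dvmrg"
    AVG_3D = "3Davg"
    MERGED_3D = "3Dmrg"


@dataclass(frozen=True)
class TextureMatrix:
    """A count matrix plus the voxel scope it was built from.

    ``counts`` is indexed ``(grey level - 1, second axis)``; for NGTDM the
    second axis holds ``[n_i, s_i]``.  ``nv`` is the number of ROI voxels in
    the matrix scope (a slice or the volume); merging matrices sums both
    counts and scopes.
    """

    family: str
    counts: np.ndarray
    nv: int
    context: tuple = ()

    def total(self) -> float:
        if self.family == "NGTDM":
            return float(self.counts[:, 0].sum())
        return float(self.counts.sum())


def _merge(matrices: list[TextureMatrix]) -> TextureMatrix:
    ncols = max(m.counts.shape[1] for m in matrices)
    nrows = max(m.counts.shape[0] for m in matrices)
    out = np.zeros((nrows, ncols))
    for m in matrices:
        r, c = m.counts.shape
        out[:r, :c] += m.counts
    # Scope voxels: directional matrices over the same voxels are counted per
    # direction (IBSI merged-Nv convention) so ratios like run percentage stay in (0, 1].
    return TextureMatrix(matrices[0].family, out, sum(m.nv for m in matrices))


# ---------------------------------------------------------------------------
# Matrix builders.  `levels` is the integer grid with 0 outside the ROI.


def _shifted_pairs(levels: np.ndarray, offset: tuple[int, int, int]):
    """Views of (voxel, voxel+offset) level pairs fully inside the grid."""
    sl_a, sl_b = [], []
    for n, o in zip(levels.shape, offset):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return levels[tuple(sl_a)], levels[tuple(sl_b)]


def glcm(droi: DiscretizedROI, offset: tuple[int, int, int], slice_index: Optional[int] = None) -> TextureMatrix:
    """Symmetrized grey-level co-occurrence counts for one displacement."""
    levels, nv = _scope(droi, slice_index)
    ng = droi.ng
    a, b = _shifted_pairs(levels, offset)
    valid = (a > 0) & (b > 0)
    counts = np.zeros((ng, ng))
    np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    counts = counts + counts.T
    return TextureMatrix("GLCM", counts, nv, (slice_index, offset))


def _scope(droi: DiscretizedROI, slice_index: Optional[int]) -> tuple[np.ndarray, int]:
    levels = droi.levels * droi.intensity_mask
    if slice_index is not None:
        levels = levels[slice_index : slice_index + 1]
    return levels, int((levels > 0).sum())


def glrlm(droi: DiscretizedROI, offset: tuple[int, int, int], slice_index: Optional[int] = None) -> TextureMatrix:
    """Maximal-run-length counts along one displacement direction."""
    levels, nv = _scope(droi, slice_index)
    ng = droi.ng
    shape = levels.shape
    oz, oy, ox = offset
    runs: dict[tuple[int, int], float] = {}
    max_len = 1
    # Start voxels are those whose predecessor along the offset is outside the grid.
    starts = []
    for k in range(shape[0]):
        for j in range(shape[1]):
            for i in range(shape[2]):
                pk, pj, pi = k - oz, j - oy, i - ox
                if not (0 <= pk < shape[0] and 0 <= pj < shape[1] and 0 <= pi < shape[2]):
                    starts.append((k, j, i))
    for k0, j0, i0 in starts:
        k, j, i = k0, j0, i0
        cur_level, cur_len = 0, 0
        while 0 <= k < shape[0] and 0 <= j < shape[1] and 0 <= i < shape[2]:
            g = levels[k, j, i]
            if g == cur_level and g > 0:
                cur_len += 1
            else:
                if cur_level > 0:
                    runs[(cur_level, cur_len)] = runs.get((cur_level, cur_len), 0.0) + 1.0
                    max_len = max(max_len, cur_len)
                cur_level, cur_len = g, (1 if g > 0 else 0)
            k, j, i = k + oz, j + oy, i + ox
        if cur_level > 0:
            runs[(cur_level, cur_len)] = runs.get((cur_level, cur_len), 0.0) + 1.0
            max_len = max(max_len, cur_len)
    counts = np.zeros((ng, max_len))
    for (g, length), c in runs.items():
        counts[g - 1, length - 1] = c
    return TextureMatrix("GLRLM", counts, nv, (slice_index, offset))


def _zones(levels: np.ndarray, ng: int, two_d: bool) -> list[tuple[int, np.ndarray]]:
    """Connected same-level zones (26-connectivity in 3D, 8 in 2D) as
    (level, boolean zone mask) pairs."""
    if two_d:
        structure = np.zeros((3, 3, 3))
        structure[1] = 1  # 8-connectivity within the slice plane
    else:
        structure = np.ones((3, 3, 3))
    out = []
    for g in range(1, ng + 1):
        lab, nlab = ndimage.label(levels == g, structure=structure)
        for z in range(1, nlab + 1):
            out.append((g, lab == z))
    return out


def glszm(droi: DiscretizedROI, slice_index: Optional[int] = None) -> TextureMatrix:
    """Grey-level size-zone counts: matrix of (level, zone size)."""
    levels, nv = _scope(droi, slice_index)
    zones = _zones(levels, droi.ng, two_d=slice_index is not None)
    sizes = [int(z.sum()) for _, z in zones]
    counts = np.zeros((droi.ng, max(sizes) if sizes else 1))
    for (g, _), s in zip(zones, sizes):
        counts[g - 1, s - 1] += 1.0
    return TextureMatrix("GLSZM", counts, nv, (slice_index,))


def _distance_map(morph: np.ndarray, two_d: bool) -> np.ndarray:
    """City-block steps to outside the morphological mask; boundary voxels = 1.
    Voxels beyond the image border count as outside."""
    padded = np.pad(morph.astype(np.uint8), 1)
    if two_d:
        dist = np.stack(
            [ndimage.distance_transform_cdt(padded[k], metric="taxicab") for k in range(padded.shape[0])]
        )
    else:
        dist = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return np.asarray(dist)[1:-1, 1:-1, 1:-1]


def gldzm(droi: DiscretizedROI, slice_index: Optional[int] = None) -> TextureMatrix:
    """Grey-level distance-zone counts: matrix of (level, zone distance).

    Zone distance is the minimum over the zone of the 4-/6-connected step
    distance to the first voxel outside the *morphological* mask.
    """
    levels, nv = _scope(droi, slice_index)
    morph = droi.morph_mask
    if slice_index is not None:
        morph = morph[slice_index : slice_index + 1]
    two_d = slice_index is not None
    dmap = _distance_map(morph, two_d)
    zones = _zones(levels, droi.ng, two_d)
    entries = [(g, int(dmap[z].min())) for g, z in zones]
    max_d = max((d for _, d in entries), default=1)
    counts = np.zeros((droi.ng, max(max_d, 1)))
    for g, d in entries:
        counts[g - 1, d - 1] += 1.0
    return TextureMatrix("GLDZM", counts, nv, (slice_index,))


def _neighbour_sums(levels: np.ndarray, two_d: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel sum and count of in-ROI neighbour levels (center excluded)."""
    kern = np.ones((1, 3, 3)) if two_d else np.ones((3, 3, 3))
    mask = (levels > 0).astype(float)
    tot = ndimage.convolve(levels.astype(float), kern, mode="constant", cval=0.0)
    cnt = ndimage.convolve(mask, kern, mode="constant", cval=0.0)
    return tot - levels, cnt - mask


def ngtdm(droi: DiscretizedROI, slice_index: Optional[int] = None) -> TextureMatrix:
    """Neighbourhood grey-tone difference matrix: rows hold [n_i, s_i].

    s_i sums |i - mean of valid neighbours| over ROI voxels of level i; the
    neighbourhood (8 in 2D, 26 in 3D) is restricted to ROI voxels and clipped
    at borders; voxels with no valid neighbour do not contribute.
    """
    levels, _ = _scope(droi, slice_index)
    nv = int((levels > 0).sum())
    nsum, ncnt = _neighbour_sums(levels, two_d=slice_index is not None)
    valid = (levels > 0) & (ncnt > 0)
    counts = np.zeros((droi.ng, 2))
    g = levels[valid]
    diff = np.abs(g - nsum[valid] / ncnt[valid])
    np.add.at(counts[:, 0], g - 1, 1.0)
    np.add.at(counts[:, 1], g - 1, diff)
    return TextureMatrix("NGTDM", counts, nv, (slice_index,))


def ngldm(droi: DiscretizedROI, slice_index: Optional[int] = None, alpha: int = 0) -> TextureMatrix:
    """Neighbouring grey-level dependence counts: matrix of (level, k + 1)
    where k is the number of neighbours within ``alpha`` of the center level.

    Incomplete neighbourhoods at ROI/image borders are allowed, so every ROI
    voxel contributes and the dependence count percentage is identically 1.
    """
    levels, nv = _scope(droi, slice_index)
    offsets = []
    rng = (0,) if slice_index is not None else (-1, 0, 1)
    for oz in rng:
        for oy in (-1, 0, 1):
            for ox in (-1, 0, 1):
                if (oz, oy, ox) != (0, 0, 0):
                    offsets.append((oz, oy, ox))
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in offsets:
        a, b = _shifted_pairs(levels, off)
        sl_a = tuple(
            slice(0, n - o) if o >= 0 else slice(-o, n) for n, o in zip(levels.shape, off)
        )
        match = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        dep[sl_a] += match
    in_roi = levels > 0
    kmax = int(dep[in_roi].max()) if in_roi.any() else 0
    counts = np.zeros((droi.ng, kmax + 1))
    np.add.at(counts, (levels[in_roi] - 1, dep[in_roi]), 1.0)
    return TextureMatrix("NGLDM", counts, nv, (slice_index,))


# ---------------------------------------------------------------------------
# Feature maps

GLCM_FEATURES = (
    "joint maximum", "joint average", "joint variance", "joint entropy",
    "difference average", "difference variance", "difference entropy",
    "sum average", "sum variance", "sum entropy", "angular second moment",
    "contrast", "dissimilarity", "inverse difference",
    "inverse difference normalised", "inverse difference moment",
    "inverse difference moment normalised", "inverse variance", "correlation",
    "autocorrelation", "cluster tendency", "cluster shade",
    "cluster prominence", "first measure of information correlation",
    "second measure of information correlation",
)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_features(matrix: TextureMatrix) -> dict[str, float]:
    """Haralick-style features on the normalized symmetric co-occurrence matrix."""
    counts = matrix.counts
    total = counts.sum()
    if total == 0:
        warnings.warn("empty GLCM; features skipped", stacklevel=2)
        return {k: float("nan") for k in GLCM_FEATURES}
    p = counts / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float(np.sum(ii * p))  # symmetric: mu_x == mu_y
    var = float(np.sum((ii - mu) ** 2 * p))
    # diagonal |i-j| and cross-diagonal i+j distributions
    pdiff = np.zeros(ng)
    np.add.at(pdiff, np.abs(ii - jj).ravel(), p.ravel())
    psum = np.zeros(2 * ng + 1)
    np.add.at(psum, (ii + jj).ravel(), p.ravel())
    kd = np.arange(ng)
    ks = np.arange(2 * ng + 1)
    davg = float(np.sum(kd * pdiff))
    savg = float(np.sum(ks * psum))
    adiff = np.abs(ii - jj)
    sigma = np.sqrt(var)
    hxy = _entropy(p.ravel())
    pxpy = np.outer(px, px)
    with np.errstate(divide="ignore"):
        lg = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-np.sum(p * lg))
    hxy2 = _entropy(pxpy.ravel())
    hx = _entropy(px)
    ic1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = -2.0 * (hxy2 - hxy)
    ic2 = float(np.sqrt(1.0 - np.exp(arg))) if arg < 0 else 0.0
    inv_var_mask = adiff > 0
    out = {
        "joint maximum": float(p.max()),
        "joint average": mu,
        "joint variance": var,
        "joint entropy": hxy,
        "difference average": davg,
        "difference variance": float(np.sum((kd - davg) ** 2 * pdiff)),
        "difference entropy": _entropy(pdiff),
        "sum average": savg,
        "sum variance": float(np.sum((ks - savg) ** 2 * psum)),
        "sum entropy": _entropy(psum),
        "angular second moment": float(np.sum(p**2)),
        "contrast": float(np.sum((ii - jj) ** 2 * p)),
        "dissimilarity": float(np.sum(adiff * p)),
        "inverse difference": float(np.sum(p / (1.0 + adiff))),
        "inverse difference normalised": float(np.sum(p / (1.0 + adiff / ng))),
        "inverse difference moment": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "inverse difference moment normalised": float(np.sum(p / (1.0 + (ii - jj) ** 2 / ng**2))),
        "inverse variance": float(np.sum(p[inv_var_mask] / (ii - jj)[inv_var_mask] ** 2)),
        "correlation": float(np.sum((ii - mu) * (jj - mu) * p) / var) if var > 0 else 0.0,
        "autocorrelation": float(np.sum(ii * jj * p)),
        "cluster tendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "cluster shade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "cluster prominence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "first measure of information correlation": ic1,
        "second measure of information correlation": ic2,
    }
    return out


def _rl_style(matrix: TextureMatrix, names: dict[str, str]) -> dict[str, float]:
    """Shared run-length-style features over a (grey level, j) count matrix."""
    counts = matrix.counts
    ns = counts.sum()
    if ns == 0:
        warnings.warn(f"empty {matrix.family}; features skipped", stacklevel=2)
        keys = list(names.values()) + [names.get("percentage", "percentage")]
        return {k: float("nan") for k in keys}
    p = counts / ns
    ng, nj = counts.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nj + 1)[None, :]
    ri = counts.sum(axis=1)  # grey-level marginal
    rj = counts.sum(axis=0)  # j marginal
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    out = {
        names["sje"]: float(np.sum(p / j**2)),
        names["lje"]: float(np.sum(p * j**2)),
        names["lgle"]: float(np.sum(p / i**2)),
        names["hgle"]: float(np.sum(p * i**2)),
        names["sjlge"]: float(np.sum(p / (i**2 * j**2))),
        names["sjhge"]: float(np.sum(p * i**2 / j**2)),
        names["ljlge"]: float(np.sum(p * j**2 / i**2)),
        names["ljhge"]: float(np.sum(p * i**2 * j**2)),
        names["gln"]: float(np.sum(ri**2) / ns),
        names["glnn"]: float(np.sum(ri**2) / ns**2),
        names["jn"]: float(np.sum(rj**2) / ns),
        names["jnn"]: float(np.sum(rj**2) / ns**2),
        names["percentage"]: float(ns / matrix.nv),
        names["glvar"]: float(np.sum(p * (i - mu_i) ** 2)),
        names["jvar"]: float(np.sum(p * (j - mu_j) ** 2)),
        names["jentropy"]: _entropy(p.ravel()),
    }
    return out


GLRLM_NAMES = {
    "sje": "short run emphasis", "lje": "long runs emphasis",
    "lgle": "Low grey level run emphasis", "hgle": "High grey level run emphasis",
    "sjlge": "Short run low grey level emphasis", "sjhge": "Short run high grey level emphasis",
    "ljlge": "Long run low grey level emphasis", "ljhge": "Long run high grey level emphasis",
    "gln": "Grey level non uniformity", "glnn": "Grey level non uniformity normalized",
    "jn": "Run length non uniformity", "jnn": "Run length non uniformity normalized",
    "percentage": "Run percentage", "glvar": "Grey level variance",
    "jvar": "Run length variance", "jentropy": "Run entropy",
}

GLSZM_NAMES = {
    "sje": "small zone emphasis", "lje": "Large zone emphasis",
    "lgle": "Low grey level zone emphasis", "hgle": "High grey level zone emphasis",
    "sjlge": "Small zone low grey level emphasis", "sjhge": "Small zone high grey level emphasis",
    "ljlge": "Large zone low grey level emphasis", "ljhge": "Large zone high grey level emphasis",
    "gln": "Grey level non uniformity GLSZM", "glnn": "Grey level non uniformity normalized GLSZM",
    "jn": "Zone size non uniformity", "jnn": "Zone size non uniformity normalized",
    "percentage": "Zone percentage GLSZM", "glvar": "Grey level variance GLSZM",
    "jvar": "Zone size variance", "jentropy": "Zone size entropy",
}

GLDZM_NAMES = {
    "sje": "small distance emphasis GLDZM", "lje": "Large distance emphasis GLDZM",
    "lgle": "Low grey level zone emphasis GLDZM", "hgle": "High grey level zone emphasis GLDZM",
    "sjlge": "Small distance low grey level emphasis GLDZM",
    "sjhge": "Small distance high grey level emphasis GLDZM",
    "ljlge": "Large distance low grey level emphasis GLDZM",
    "ljhge": "Large distance high grey level emphasis GLDZM",
    "gln": "Grey level non uniformity GLDZM", "glnn": "Grey level non uniformity normalized GLDZM",
    "jn": "Zone distance non uniformity GLDZM",
    "jnn": "Zone distance non uniformity normalized GLDZM",
    "percentage": "Zone percentage GLDZM", "glvar": "Grey level variance GLDZM",
    "jvar": "Zone distance variance GLDZM", "jentropy": "Zone distance entropy GLDZM",
}

NGLDM_NAMES = {
    "sje": "Low dependence emphasis", "lje": "High dependence emphasis",
    "lgle": "Low grey level count emphasis", "hgle": "High grey level count emphasis",
    "sjlge": "Low dependence low grey level emphasis",
    "sjhge": "Low dependence high grey level emphasis",
    "ljlge": "High dependence low grey level emphasis",
    "ljhge": "High dependence high grey level emphasis",
    "gln": "Grey level non uniformity", "glnn": "Grey level non uniformity normalized",
    "jn": "Dependence count non uniformity", "jnn": "Dependence count non uniformity normalized",
    "percentage": "Dependence count percentage", "glvar": "Grey level variance",
    "jvar": "Dependence count variance", "jentropy": "Dependence count entropy",
}


def glrlm_features(matrix: TextureMatrix) -> dict[str, float]:
    return _rl_style(matrix, GLRLM_NAMES)


def glszm_features(matrix: TextureMatrix) -> dict[str, float]:
    return _rl_style(matrix, GLSZM_NAMES)


def gldzm_features(matrix: TextureMatrix) -> dict[str, float]:
    return _rl_style(matrix, GLDZM_NAMES)


def ngldm_features(matrix: TextureMatrix) -> dict[str, float]:
    out = _rl_style(matrix, NGLDM_NAMES)
    ns = matrix.counts.sum()
    out["dependence Count Energy"] = (
        float(np.sum((matrix.counts / ns) ** 2)) if ns > 0 else float("nan")
    )
    return out


NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")


def ngtdm_features(matrix: TextureMatrix) -> dict[str, float]:
    """Amadasun-King features from the [n_i, s_i] columns."""
    n = matrix.counts[:, 0]
    s = matrix.counts[:, 1]
    ntot = n.sum()
    if ntot == 0:
        warnings.warn("empty NGTDM; features skipped", stacklevel=2)
        return {k: float("nan") for k in NGTDM_FEATURES}
    p = n / ntot
    occ = np.flatnonzero(p > 0)
    i = occ + 1.0
    pi, si = p[occ], s[occ]
    ngp = occ.size
    ps = float(np.sum(pi * si))
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP
    ii, jj = np.meshgrid(i, i, indexing="ij")
    ppi, ppj = np.meshgrid(pi, pi, indexing="ij")
    if ngp > 1:
        contrast = float(np.sum(ppi * ppj * (ii - jj) ** 2)) / (ngp * (ngp - 1)) * float(s.sum()) / ntot
        denom_busy = float(np.sum(np.abs(ii * ppi - jj * ppj)[ii != jj]))
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    sis = np.meshgrid(si, si, indexing="ij")
    complexity = float(
        np.sum(np.abs(ii - jj) * (ppi * sis[0] + ppj * sis[1]) / (ppi + ppj))
    ) / ntot
    ssum = float(s.sum())
    strength = float(np.sum((ppi + ppj) * (ii - jj) ** 2)) / ssum if ssum > 0 else 0.0
    return {
        "coarseness": min(coarseness, COARSENESS_CAP),
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# Aggregation

_BUILDERS: dict[str, Callable] = {}
_FEATURES: dict[str, Callable[[TextureMatrix], dict[str, float]]] = {
    "GLCM": glcm_features,
    "GLRLM": glrlm_features,
    "GLSZM": glszm_features,
    "GLDZM": gldzm_features,
    "NGTDM": ngtdm_features,
    "NGLDM": ngldm_features,
}


def _slices_with_roi(droi: DiscretizedROI) -> list[int]:
    return [k for k in range(droi.levels.shape[0]) if droi.intensity_mask[k].any()]


def _build(family: str, droi: DiscretizedROI, slice_index, offset, **kw) -> TextureMatrix:
    if family == "GLCM":
        return glcm(droi, offset, slice_index)
    if family == "GLRLM":
        return glrlm(droi, offset, slice_index)
    if family == "GLSZM":
        return glszm(droi, slice_index)
    if family == "GLDZM":
        return gldzm(droi, slice_index)
    if family == "NGTDM":
        return ngtdm(droi, slice_index)
    if family == "NGLDM":
        return ngldm(droi, slice_index, alpha=kw.get("alpha", 0))
    raise ValueError(f"unknown texture family {family!r}")


def _mean_features(feature_maps: list[dict[str, float]]) -> dict[str, float]:
    usable = [f for f in feature_maps if not all(np.isnan(v) for v in f.values())]
    if not usable:
        return feature_maps[0]
    keys = usable[0].keys()
    return {k: float(np.mean([f[k] for f in usable])) for k in keys}


def aggregate(
    family: str,
    droi: DiscretizedROI,
    scheme: AggregationScheme | str,
    **kw,
) -> dict[str, float]:
    """Compute one texture family's features under one aggregation scheme.

    Raises a configuration error for scheme/family mismatches: AVG_3D only
    exists for the directional families (GLCM, GLRLM).  For the other families
    each slice holds exactly one matrix, so the direction-resolved 2D merge
    schemes collapse onto MERGED_2D and the distinct schemes are
    AVG_2D / MERGED_2D / MERGED_3D.
    """
    scheme = AggregationScheme(scheme)
    feat = _FEATURES[family]
    directional = family in DIRECTIONAL_FAMILIES
    if not directional:
        if scheme is AggregationScheme.AVG_3D:
            raise ValueError(f"scheme {scheme.value} is not defined for {family}")
        # one matrix per slice: both merge-style 2D schemes reduce to
        # "merge the per-slice matrices"
        if scheme in (AggregationScheme.SLICE_MERGED_2D, AggregationScheme.DIR_MERGED_2D):
            scheme = AggregationScheme.MERGED_2D

    if scheme is AggregationScheme.MERGED_3D:
        if directional:
            mats = [_build(family, droi, None, off, **kw) for off in DIRECTIONS_3D]
            return feat(_merge(mats))
        return feat(_build(family, droi, None, None, **kw))
    if scheme is AggregationScheme.AVG_3D:
        mats = [_build(family, droi, None, off, **kw) for off in DIRECTIONS_3D]
        return _mean_features([feat(m) for m in mats])

    slices = _slices_with_roi(droi)
    if directional:
        per_slice = {
            k: [_build(family, droi, k, off, **kw) for off in DIRECTIONS_2D] for k in slices
        }
        if scheme is AggregationScheme.AVG_2D:
            return _mean_features([feat(m) for mats in per_slice.values() for m in mats])
        if scheme is AggregationScheme.SLICE_MERGED_2D:
            return _mean_features([feat(_merge(mats)) for mats in per_slice.values()])
        if scheme is AggregationScheme.DIR_MERGED_2D:
            per_dir = [
                _merge([per_slice[k][d] for k in slices]) for d in range(len(DIRECTIONS_2D))
            ]
            return _mean_features([feat(m) for m in per_dir])
        return feat(_merge([m for mats in per_slice.values() for m in mats]))

    mats = [_build(family, droi, k, None, **kw) for k in slices]
    if scheme is AggregationScheme.AVG_2D:
        return _mean_features([feat(m) for m in mats])
    return feat(_merge(mats))
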