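"""Reading and writing image/mask volumes, VOI derivation and PET intensity scaling.

Arrays are indexed ``(z, y, x)`` with ``z`` the slice axis and ``x`` fastest.
``spacing`` and ``origin`` are given in world order ``(dx, dy, dz)`` /
``(x0, y0, z0)`` in millimetres.  The voxel with index ``(k, j, i)`` has its
*center* at ``origin + (i*dx, j*dy, k*dz)``; voxel extents are the half-open
boxes around the centers.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Modality",
    "ImageVolume",
    "MaskVolume",
    "PatientInfo",
    "FormatError",
    "MultiplicityError",
    "EmptyVOIError",
    "GeometryError",
    "PlacementError",
    "ScalingError",
    "load_volume",
    "save_volume",
    "derive_mask",
    "rasterize_rtstruct",
    "load_rtstruct_contours",
    "suv_convert",
    "F18_HALF_LIFE_S",
]

F18_HALF_LIFE_S = 6586.2  # fluorine-18


class Modality(str, Enum):
    PET = "PET"
    CT = "CT"
    MR = "MR"
    OTHER = "OTHER"


class FormatError(ValueError):
    """Unreadable or ambiguous image format."""


class MultiplicityError(FormatError):
    """DICOM directory holds more than one image series."""


class EmptyVOIError(ValueError):
    """A mask operation produced (or received) a VOI with no voxels."""


class GeometryError(ValueError):
    """Degenerate geometry (e.g. polygon with <3 vertices)."""


class PlacementError(ValueError):
    """Contour z-plane matches no image slice."""


class ScalingError(ValueError):
    """SUV/SUL scaling impossible with the given patient data."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with physical metadata.

    ``values`` is ``(nz, ny, nx)``; ``spacing`` is ``(dx, dy, dz)`` mm > 0.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.OTHER

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """World (x, y, z) mm coordinates of voxel centers for (k, j, i) index rows."""
        idx = np.atleast_2d(np.asarray(indices))
        dx, dy, dz = self.spacing
        x0, y0, z0 = self.origin
        out = np.empty((idx.shape[0], 3), dtype=float)
        out[:, 0] = x0 + idx[:, 2] * dx
        out[:, 1] = y0 + idx[:, 1] * dy
        out[:, 2] = z0 + idx[:, 0] * dz
        return out


@dataclass(frozen=True)
class MaskVolume:
    """Binary VOI grid aligned with an :class:`ImageVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={v.ndim}")
        vals = np.unique(v)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "values", v.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())

    def check_aligned(self, image: ImageVolume) -> None:
        if self.shape != image.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match image shape {image.shape}"
            )
        if not np.allclose(self.spacing, image.spacing):
            raise ValueError(
                f"mask spacing {self.spacing} does not match image spacing {image.spacing}"
            )


@dataclass(frozen=True)
class PatientInfo:
    """Patient demographics and scan timing needed for SUV/SUL scaling.

    ``injected_activity`` is in Bq and is assumed to be given at injection
    time unless ``activity_pre_decayed`` is set (DICOM sources differ).
    """

    weight_kg: Optional[float] = None
    height_cm: Optional[float] = None
    sex: Optional[str] = None  # "M" | "F"
    injected_activity_bq: Optional[float] = None
    injection_time: Optional[datetime] = None
    scan_start_time: Optional[datetime] = None
    half_life_s: float = F18_HALF_LIFE_S
    scaling_override: Optional[float] = None
    activity_pre_decayed: bool = False

    def decay_interval_s(self) -> float:
        if self.injection_time is None or self.scan_start_time is None:
            raise ScalingError("injection and scan start times are required")
        dt = (self.scan_start_time - self.injection_time).total_seconds()
        if dt < 0:
            raise ScalingError("scan start precedes injection time")
        return dt


# ---------------------------------------------------------------------------
# Volume loading

_EXT_FORMATS = {
    ".nii": "nifti",
    ".nii.gz": "nifti",
    ".nrrd": "nrrd",
    ".nhdr": "nrrd",
    ".hdr": "analyze",
    ".img": "analyze",
    ".mhd": "raw",
    ".raw": "raw",
}


def _sitk_to_volume(img: sitk.Image, modality: Modality) -> ImageVolume:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    sp = img.GetSpacing()  # (dx, dy, dz)
    org = img.GetOrigin()
    if len(sp) == 2:
        sp = (*sp, 1.0)
        org = (*org, 0.0)
    return ImageVolume(arr.astype(float), tuple(sp), tuple(org), modality)


def load_volume(
    path: str | os.PathLike,
    format_hint: Optional[str] = None,
    modality: Modality = Modality.OTHER,
) -> ImageVolume:
    """Load a volume from NIfTI / NRRD / Analyze / raw+sidecar, or a DICOM series directory.

    DICOM slices are ordered by spatial position (ImagePositionPatient), never
    by filename, and rescale slope/intercept are applied by the reader.  A
    directory with more than one SeriesInstanceUID raises
    :class:`MultiplicityError`.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if p.is_dir():
        return _load_dicom_series(p, modality)

    name = p.name.lower()
    fmt = format_hint
    if fmt is None:
        if name.endswith(".nii.gz"):
            fmt = "nifti"
        else:
            fmt = _EXT_FORMATS.get(p.suffix.lower())
    if fmt is None:
        raise FormatError(f"cannot infer format of {p}; pass format_hint")
    if fmt == "raw" and p.suffix.lower() == ".raw":
        return _load_raw(p, modality)
    try:
        img = sitk.ReadImage(str(p))
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise FormatError(f"could not read {p}: {exc}") from exc
    return _sitk_to_volume(img, modality)


def _load_dicom_series(directory: Path, modality: Modality) -> ImageVolume:
    reader = sitk.ImageSeriesReader()
    series_ids = reader.GetGDCMSeriesIDs(str(directory))
    if not series_ids:
        raise FormatError(f"no DICOM series found in {directory}")
    if len(series_ids) > 1:
        raise MultiplicityError(
            f"{directory} holds {len(series_ids)} DICOM series; one per folder is required"
        )
    files = reader.GetGDCMSeriesFileNames(str(directory), series_ids[0])
    reader.SetFileNames(files)
    img = reader.Execute()
    return _sitk_to_volume(img, modality)


def _load_raw(path: Path, modality: Modality) -> ImageVolume:
    """Raw voxel dump with a mandatory JSON sidecar (<name>.json) describing
    shape (nz, ny, nx), dtype, spacing and optionally origin."""
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"raw file {path} requires a sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    try:
        shape = tuple(int(n) for n in meta["shape"])
        dtype = np.dtype(meta["dtype"])
        spacing = tuple(float(s) for s in meta["spacing"])
    except KeyError as exc:
        raise FormatError(f"raw sidecar missing key {exc}") from exc
    arr = np.fromfile(path, dtype=dtype)
    if arr.size != int(np.prod(shape)):
        raise FormatError(
            f"raw file holds {arr.size} values, sidecar shape {shape} needs {int(np.prod(shape))}"
        )
    origin = tuple(float(o) for o in meta.get("origin", (0.0, 0.0, 0.0)))
    return ImageVolume(arr.reshape(shape).astype(float), spacing, origin, modality)


def save_volume(vol: ImageVolume | MaskVolume, path: str | os.PathLike) -> None:
    """Write to NIfTI/NRRD (by extension); lossless round-trip at stored precision."""
    arr = np.asarray(vol.values)
    img = sitk.GetImageFromArray(arr.astype(np.float64))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# VOI derivation


def derive_mask(raw_mask: ImageVolume, threshold_fraction: float = 0.5) -> MaskVolume:
    """Binarize a scalar mask: keep voxels >= threshold_fraction * max(raw_mask).

    A mask already in {0, c} yields the same voxel set for any fraction in (0, 1].
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    vals = np.asarray(raw_mask.values, dtype=float)
    vmax = vals.max()
    if vmax <= 0:
        raise EmptyVOIError("mask volume has no positive voxels")
    binary = (vals >= threshold_fraction * vmax).astype(np.uint8)
    if binary.sum() == 0:
        raise EmptyVOIError("thresholding removed every voxel")
    return MaskVolume(binary, raw_mask.spacing, raw_mask.origin)


# ---------------------------------------------------------------------------
# RT-struct rasterization


def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd ray-casting test, vectorized over query points."""
    inside = np.zeros(px.shape, dtype=bool)
    n = len(poly)
    for a in range(n):
        b = (a + 1) % n
        x1, y1 = poly[a]
        x2, y2 = poly[b]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < xint)
    return inside


def rasterize_rtstruct(
    contours: Sequence[np.ndarray], reference_grid: ImageVolume
) -> MaskVolume:
    """Rasterize closed planar polygons (Nx3 world-mm vertex arrays, constant z)
    onto the reference grid by the even-odd voxel-center rule; polygons sharing
    a slice are unioned.
    """
    nz, ny, nx = reference_grid.shape
    dx, dy, dz = reference_grid.spacing
    x0, y0, z0 = reference_grid.origin
    out = np.zeros((nz, ny, nx), dtype=np.uint8)
    gx = x0 + np.arange(nx) * dx
    gy = y0 + np.arange(ny) * dy
    px, py = np.meshgrid(gx, gy)  # (ny, nx)
    for cont in contours:
        cont = np.asarray(cont, dtype=float)
        if cont.ndim != 2 or cont.shape[1] != 3 or cont.shape[0] < 3:
            raise GeometryError("each contour must be an (N>=3, 3) vertex array")
        zs = cont[:, 2]
        if np.ptp(zs) > 1e-6:
            raise GeometryError("contour vertices must share one z-plane")
        z = float(zs[0])
        k = (z - z0) / dz
        kr = int(round(k))
        if not (0 <= kr < nz) or abs(k - kr) > 0.5 + 1e-9:
            raise PlacementError(f"contour z={z} mm matches no slice center within dz/2")
        out[kr] |= _points_in_polygon(px, py, cont[:, :2])
    if out.sum() == 0:
        raise EmptyVOIError("contours enclose no voxel centers")
    return MaskVolume(out, reference_grid.spacing, reference_grid.origin)


def load_rtstruct_contours(path: str | os.PathLike) -> list[np.ndarray]:
    """Extract contour vertex arrays from a DICOM RTSTRUCT file."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    contours: list[np.ndarray] = []
    for roi in getattr(ds, "ROIContourSequence", []):
        for c in getattr(roi, "ContourSequence", []):
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            contours.append(pts)
    if not contours:
        raise FormatError(f"{path} holds no contour data")
    return contours


# ---------------------------------------------------------------------------
# PET scaling


def _lean_body_mass_kg(weight_kg: float, height_cm: float, sex: str) -> float:
    """Janmahasatian sex-specific lean body mass (kg)."""
    bmi = weight_kg / (height_cm / 100.0) ** 2
    if sex.upper().startswith("M"):
        return 9270.0 * weight_kg / (6680.0 + 216.0 * bmi)
    return 9270.0 * weight_kg / (8780.0 + 244.0 * bmi)


def suv_convert(
    image: ImageVolume, patient: PatientInfo, mode: str = "SUV"
) -> ImageVolume:
    """Scale a PET activity-concentration image (Bq/ml) to SUV, SUL, or by an
    explicit factor.

    SUV = concentration * body_weight_g / decayed_activity_Bq, with the injected
    activity decayed from injection to scan start, A = A0 * 2^(-dt/half_life).
    SUL replaces body weight by Janmahasatian lean body mass.  SCALE multiplies
    every voxel by ``patient.scaling_override`` and ignores everything else.
    """
    mode = mode.upper()
    if image.modality != Modality.PET:
        raise ScalingError("SUV scaling applies to PET images only")
    if mode == "SCALE":
        if patient.scaling_override is None:
            raise ScalingError("SCALE mode requires scaling_override")
        factor = float(patient.scaling_override)
    elif mode in ("SUV", "SUL"):
        if patient.weight_kg is None or patient.weight_kg <= 0:
            raise ScalingError("positive patient weight is required")
        if patient.injected_activity_bq is None or patient.injected_activity_bq <= 0:
            raise ScalingError("positive injected activity is required")
        if patient.activity_pre_decayed:
            activity = patient.injected_activity_bq
        else:
            dt = patient.decay_interval_s()
            activity = patient.injected_activity_bq * math.pow(2.0, -dt / patient.half_life_s)
        if activity <= 0:
            raise ScalingError("decayed activity is nonpositive")
        if mode == "SUV":
            mass_g = patient.weight_kg * 1000.0
        else:
            if patient.height_cm is None or patient.sex is None:
                raise ScalingError("SUL requires height and sex")
            mass_g = _lean_body_mass_kg(patient.weight_kg, patient.height_cm, patient.sex) * 1000.0
        factor = mass_g / activity
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return replace(image, values=image.values * factor)
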