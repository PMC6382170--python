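"""INI configuration parsing: run configuration, feature selection, patient info.

Dialect: '#' and ';' comments, case-insensitive keys, section headers optional
(keys are globally unique).  Unknown keys are rejected by name, and every
resolved value keeps provenance ("file" vs "default") so the output metadata
can report exactly what drove a run.
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional

from .io_core import PatientInfo
from .preprocess import DiscretizationMethod, DiscretizationRule

__all__ = [
    "ConfigError",
    "RunConfig",
    "parse_config",
    "parse_feature_selection",
    "parse_patient_info",
    "CONFIG_KEYS",
]


class ConfigError(ValueError):
    """Malformed configuration value or unknown key."""


# Every accepted key, lower-case, with its documented default.
CONFIG_KEYS: dict[str, object] = {
    "useinterpolation": 0,
    "interpolationmethod": "trilinear",  # trilinear | cubic_spline | nearest
    "interpolation2d": 0,  # 1 = slice-by-slice in-plane resampling
    "targetspacing": "2",  # "2" (isotropic mm) or "dx,dy,dz"
    "resegmentimage": 0,
    "minintensity": None,
    "maxintensity": None,
    "excludeoutliers": 0,
    "outliersigma": 3.0,
    "discretizationmethod": "FBN",
    "nrbins": 64,
    "binwidth": None,
    "ivhdiscretize": 0,  # 1 = separate IVH discretization block active
    "ivhdiscretizationmethod": "FBN",
    "ivhnrbins": 1000,
    "ivhbinwidth": None,
    "thresholdforvoi": 0.5,
    "scalingmode": "",  # "" | SUV | SUL | SCALE (PET only)
    "activitypredecayed": 0,
    "masktruethreshold": 0.5,  # re-binarization level for interpolated masks
    "ngldmalpha": 0,
}

_CANONICAL = {
    "useinterpolation": "UseInterpolation",
    "interpolationmethod": "InterpolationMethod",
    "interpolation2d": "Interpolation2D",
    "targetspacing": "TargetSpacing",
    "resegmentimage": "ReSegmentImage",
    "minintensity": "MinIntensity",
    "maxintensity": "MaxIntensity",
    "excludeoutliers": "ExcludeOutliers",
    "outliersigma": "OutlierSigma",
    "discretizationmethod": "DiscretizationMethod",
    "nrbins": "NrBins",
    "binwidth": "BinWidth",
    "ivhdiscretize": "IVHDiscretize",
    "ivhdiscretizationmethod": "IVHDiscretizationMethod",
    "ivhnrbins": "IVHNrBins",
    "ivhbinwidth": "IVHBinWidth",
    "thresholdforvoi": "ThresholdForVOI",
    "scalingmode": "ScalingMode",
    "activitypredecayed": "ActivityPreDecayed",
    "masktruethreshold": "MaskTrueThreshold",
    "ngldmalpha": "NGLDMAlpha",
}

_METHOD_ALIASES = {
    "trilinear": "trilinear",
    "linear": "trilinear",
    "spline": "cubic_spline",
    "cubic_spline": "cubic_spline",
    "cubicspline": "cubic_spline",
    "nearest": "nearest",
    "nearestneighbor": "nearest",
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration with per-key provenance."""

    interpolation_enabled: bool = False
    interpolation_method: str = "trilinear"
    interpolation_2d: bool = False
    target_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    resegment_enabled: bool = False
    min_intensity: Optional[float] = None
    max_intensity: Optional[float] = None
    exclude_outliers: bool = False
    outlier_sigma: float = 3.0
    discretization: DiscretizationRule = DiscretizationRule(DiscretizationMethod.FBN, n_bins=64)
    ivh_discretization: Optional[DiscretizationRule] = None
    threshold_for_voi: float = 0.5
    scaling_mode: str = ""
    activity_pre_decayed: bool = False
    mask_true_threshold: float = 0.5
    ngldm_alpha: int = 0
    provenance: dict = field(default_factory=dict)
    source_text: str = ""


def _read_ini(path: str | Path) -> configparser.ConfigParser:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    text = p.read_text()
    stripped = text.lstrip()
    if not stripped.startswith("["):
        text = "[root]\n" + text
    cp = configparser.ConfigParser(
        comment_prefixes=("#", ";"), inline_comment_prefixes=("#", ";"), strict=False
    )
    cp.optionxform = str.lower  # case-insensitive keys
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise ConfigError(f"malformed INI file {p}: {exc}") from exc
    return cp


def _flatten(cp: configparser.ConfigParser) -> dict[str, str]:
    out: dict[str, str] = {}
    for section in cp.sections():
        for key, value in cp.items(section):
            out[key.lower()] = value
    return out


def _to_int(key: str, raw: str) -> int:
    try:
        return int(raw)
    except ValueError as exc:
        raise ConfigError(f"key {_CANONICAL.get(key, key)}: expected an integer, got {raw!r}") from exc


def _to_float(key: str, raw: str) -> float:
    try:
        return float(raw)
    except ValueError as exc:
        raise ConfigError(f"key {_CANONICAL.get(key, key)}: expected a number, got {raw!r}") from exc


def _parse_spacing(raw: str) -> tuple[float, float, float]:
    parts = [p for p in raw.replace(",", " ").split() if p]
    vals = [float(p) for p in parts]
    if len(vals) == 1:
        return (vals[0], vals[0], vals[0])
    if len(vals) == 3:
        return (vals[0], vals[1], vals[2])
    raise ConfigError(f"key TargetSpacing: expected 1 or 3 numbers, got {raw!r}")


def _build_rule(method: str, n_bins, bin_width, lower_bound) -> DiscretizationRule:
    m = method.strip().upper()
    if m not in ("FBN", "FBS"):
        raise ConfigError(f"unknown discretization method {method!r}")
    if m == "FBN":
        return DiscretizationRule(DiscretizationMethod.FBN, n_bins=n_bins)
    return DiscretizationRule(DiscretizationMethod.FBS, bin_width=bin_width, lower_bound=lower_bound)


def parse_config(path: str | Path) -> RunConfig:
    """Read an INI configuration into a fully resolved :class:`RunConfig`.

    Unknown keys raise :class:`ConfigError` naming the offending key; missing
    keys take their documented defaults.
    """
    cp = _read_ini(path)
    raw = _flatten(cp)
    unknown = set(raw) - set(CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    provenance = {
        _CANONICAL[k]: ("file" if k in raw else "default") for k in CONFIG_KEYS
    }

    def get(key: str) -> object:
        return raw.get(key, CONFIG_KEYS[key])

    method = _METHOD_ALIASES.get(str(get("interpolationmethod")).strip().lower().replace(" ", ""))
    if method is None:
        raise ConfigError(f"key InterpolationMethod: unknown method {get('interpolationmethod')!r}")

    reseg_on = bool(_to_int("resegmentimage", str(get("resegmentimage"))))
    min_i = None if get("minintensity") in (None, "") else _to_float("minintensity", str(get("minintensity")))
    max_i = None if get("maxintensity") in (None, "") else _to_float("maxintensity", str(get("maxintensity")))

    nrbins = _to_int("nrbins", str(get("nrbins")))
    binwidth = None if get("binwidth") in (None, "") else _to_float("binwidth", str(get("binwidth")))
    # FBS bins anchor at the re-segmentation lower bound when one exists,
    # keeping bins comparable across images.
    anchor = min_i if reseg_on else None
    rule = _build_rule(str(get("discretizationmethod")), nrbins, binwidth, anchor)

    ivh_rule = None
    if _to_int("ivhdiscretize", str(get("ivhdiscretize"))):
        ivh_bw = None if get("ivhbinwidth") in (None, "") else _to_float("ivhbinwidth", str(get("ivhbinwidth")))
        ivh_rule = _build_rule(
            str(get("ivhdiscretizationmethod")),
            _to_int("ivhnrbins", str(get("ivhnrbins"))),
            ivh_bw,
            anchor,
        )

    thr = _to_float("thresholdforvoi", str(get("thresholdforvoi")))
    if not 0 < thr <= 1:
        raise ConfigError("key ThresholdForVOI must lie in (0, 1]")

    return RunConfig(
        interpolation_enabled=bool(_to_int("useinterpolation", str(get("useinterpolation")))),
        interpolation_method=method,
        interpolation_2d=bool(_to_int("interpolation2d", str(get("interpolation2d")))),
        target_spacing=_parse_spacing(str(get("targetspacing"))),
        resegment_enabled=reseg_on,
        min_intensity=min_i if reseg_on else None,
        max_intensity=max_i if reseg_on else None,
        exclude_outliers=bool(_to_int("excludeoutliers", str(get("excludeoutliers")))),
        outlier_sigma=_to_float("outliersigma", str(get("outliersigma"))),
        discretization=rule,
        ivh_discretization=ivh_rule,
        threshold_for_voi=thr,
        scaling_mode=str(get("scalingmode")).strip().upper(),
        activity_pre_decayed=bool(_to_int("activitypredecayed", str(get("activitypredecayed")))),
        mask_true_threshold=_to_float("masktruethreshold", str(get("masktruethreshold"))),
        ngldm_alpha=_to_int("ngldmalpha", str(get("ngldmalpha"))),
        provenance=provenance,
        source_text=Path(path).read_text(),
    )


_GROUP_KEYS = {
    "morphology": "Morphology",
    "localintensity": "Local intensity",
    "statistics": "Statistics",
    "intensityvolume": "intensity volume",
    "ivh": "intensity volume",
    "intensityhistogram": "Intensity histogram",
    "ih": "Intensity histogram",
    "glcm": "GLCM",
    "glrlm": "GLRLM",
    "glszm": "GLSZM",
    "gldzm": "GLDZM",
    "ngtdm": "NGTDM",
    "ngldm": "NGLDM",
}


def parse_feature_selection(path: Optional[str | Path]) -> Optional[list[str]]:
    """Read a feature-output-definition file: one 0/1 flag per feature group.

    ``None`` (no file) selects all groups.
    """
    if path is None:
        return None
    cp = _read_ini(path)
    raw = _flatten(cp)
    unknown = set(raw) - set(_GROUP_KEYS)
    if unknown:
        raise ConfigError(f"unknown feature group key(s): {sorted(unknown)}")
    selected = []
    for key, group in _GROUP_KEYS.items():
        if key in raw and _to_int(key, raw[key]) == 0:
            continue
        if group not in selected:
            selected.append(group)
    return selected


def parse_patient_info(path: str | Path, activity_pre_decayed: bool = False) -> PatientInfo:
    """Read a patient-info INI (weight, height, sex, injected activity, times)."""
    cp = _read_ini(path)
    raw = _flatten(cp)
    known = {
        "weight", "height", "sex", "injectedactivity", "injectiontime",
        "scanstarttime", "halflife", "scalingfactor",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown patient-info key(s): {sorted(unknown)}")

    def _time(key: str) -> Optional[datetime]:
        if key not in raw:
            return None
        try:
            return datetime.fromisoformat(raw[key])
        except ValueError as exc:
            raise ConfigError(f"key {key}: expected ISO timestamp, got {raw[key]!r}") from exc

    return PatientInfo(
        weight_kg=_to_float("weight", raw["weight"]) if "weight" in raw else None,
        height_cm=_to_float("height", raw["height"]) if "height" in raw else None,
        sex=raw.get("sex"),
        injected_activity_bq=(
            _to_float("injectedactivity", raw["injectedactivity"])
            if "injectedactivity" in raw else None
        ),
        injection_time=_time("injectiontime"),
        scan_start_time=_time("scanstarttime"),
        half_life_s=_to_float("halflife", raw["halflife"]) if "halflife" in raw else 6586.2,
        scaling_override=(
            _to_float("scalingfactor", raw["scalingfactor"]) if "scalingfactor" in raw else None
        ),
        activity_pre_decayed=activity_pre_decayed,
    )
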