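"""Feature-table assembly: run every selected family on a preprocessed ROI.

The table is an ordered list of ``(group_label, feature_name, value)`` records.
Texture group labels join the family prefix with the aggregation-scheme suffix
(e.g. ``glcmFeatures2Davg``, ``GLRLMFeatures3Dmrg``); non-texture groups use
the family name directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import intensity as _intensity
from . import morphology as _morphology
from . import texture as _texture
from .preprocess import ROI, DiscretizedROI
from .texture import AggregationScheme, DIRECTIONAL_FAMILIES, TEXTURE_FAMILIES

__all__ = ["FeatureRecord", "FeatureTable", "compute_features", "FEATURE_GROUPS"]

FEATURE_GROUPS = (
    "Morphology",
    "Local intensity",
    "Statistics",
    "intensity volume",
    "Intensity histogram",
) + TEXTURE_FAMILIES

_TEXTURE_PREFIX = {
    "GLCM": "glcmFeatures",
    "GLRLM": "GLRLMFeatures",
    "GLSZM": "GLSZMFeatures",
    "GLDZM": "gldzmFeatures",
    "NGTDM": "ngtdmFeatures",
    "NGLDM": "ngldmFeatures",
}

_DIRECTIONAL_SCHEMES = (
    AggregationScheme.AVG_2D,
    AggregationScheme.SLICE_MERGED_2D,
    AggregationScheme.DIR_MERGED_2D,
    AggregationScheme.MERGED_2D,
    AggregationScheme.AVG_3D,
    AggregationScheme.MERGED_3D,
)
_UNDIRECTED_SCHEMES = (
    AggregationScheme.AVG_2D,
    AggregationScheme.MERGED_2D,
    AggregationScheme.MERGED_3D,
)

_SUFFIX = {
    AggregationScheme.AVG_2D: "2Davg",
    AggregationScheme.SLICE_MERGED_2D: "2Dmrg",
    AggregationScheme.DIR_MERGED_2D: "2DDmrg",
    AggregationScheme.MERGED_2D: "2Dvmrg",
    AggregationScheme.AVG_3D: "3Davg",
    AggregationScheme.MERGED_3D: "3Dmrg",
}
# Non-directional families keep one matrix per slice, so their merged-3D label
# drops the scheme qualifier and their merged-2D label is the plain 2D merge.
_UNDIRECTED_SUFFIX = {
    AggregationScheme.AVG_2D: "2Davg",
    AggregationScheme.MERGED_2D: "2Dmrg",
    AggregationScheme.MERGED_3D: "3D",
}


@dataclass(frozen=True)
class FeatureRecord:
    group: str
    feature: str
    value: float


@dataclass
class FeatureTable:
    records: list[FeatureRecord] = field(default_factory=list)

    def add(self, group: str, features: dict[str, float]) -> None:
        for name, value in features.items():
            self.records.append(FeatureRecord(group, name, float(value)))

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group, None)
        return list(seen)

    def get(self, group: str, feature: str) -> float:
        for r in self.records:
            if r.group == group and r.feature == feature:
                return r.value
        raise KeyError((group, feature))

    def to_rows(self) -> list[tuple[str, str, float]]:
        return [(r.group, r.feature, r.value) for r in self.records]


def compute_features(
    roi: ROI,
    droi: DiscretizedROI,
    droi_ivh: Optional[DiscretizedROI] = None,
    groups: Optional[Iterable[str]] = None,
    ngldm_alpha: int = 0,
) -> FeatureTable:
    """Compute every selected feature group.

    ``roi`` feeds morphology / local-intensity / first-order statistics (raw
    intensities); ``droi`` feeds histogram and texture families; ``droi_ivh``
    (defaulting to ``droi``) feeds the intensity-volume histogram.
    """
    selected = set(groups) if groups is not None else set(FEATURE_GROUPS)
    unknown = selected - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature groups: {sorted(unknown)}")
    table = FeatureTable()
    if "Morphology" in selected:
        table.add("Morphology", _morphology.morphology_features(roi))
    if "Local intensity" in selected:
        table.add("Local intensity", _morphology.local_intensity_features(roi))
    if "Statistics" in selected:
        table.add("Statistics", _intensity.first_order(roi))
    if "intensity volume" in selected:
        table.add("intensity volume", _intensity.ivh_features(droi_ivh or droi))
    if "Intensity histogram" in selected:
        table.add("Intensity histogram", _intensity.ih_features(droi))
    for family in TEXTURE_FAMILIES:
        if family not in selected:
            continue
        directional = family in DIRECTIONAL_FAMILIES
        schemes = _DIRECTIONAL_SCHEMES if directional else _UNDIRECTED_SCHEMES
        suffixes = _SUFFIX if directional else _UNDIRECTED_SUFFIX
        kw = {"alpha": ngldm_alpha} if family == "NGLDM" else {}
        for scheme in schemes:
            label = _TEXTURE_PREFIX[family] + suffixes[scheme]
            table.add(label, _texture.aggregate(family, droi, scheme, **kw))
    return table
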