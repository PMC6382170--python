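"""CSV and provenance output.

A run writes three files with aligned names: ``<out>.csv`` (the feature
values), ``<out>_config.ini`` (a verbatim copy of the configuration) and
``<out>_info.txt`` (input paths, calculated groups, warnings).  Existing files
are never overwritten: on collision the new files get an ISO-8601 basic
timestamp suffix (YYYYMMDDTHHMMSS).

Floats are serialized with ``repr`` (shortest round-trip decimal), so repeated
runs on identical inputs produce byte-identical CSV.
"""

from __future__ import annotations

import csv
from datetime import datetime
from pathlib import Path
from typing import Optional

import numpy as np

from .features import FeatureTable

__all__ = ["write_outputs", "format_value"]


def format_value(value: float) -> str:
    if isinstance(value, float) and np.isnan(value):
        return "nan"
    return repr(float(value))


def _resolve_collision(base: Path) -> str:
    """Suffix appended to all output names when <out>.csv already exists."""
    if not base.with_suffix(".csv").exists():
        return ""
    return "_" + datetime.now().strftime("%Y%m%dT%H%M%S")


def write_outputs(
    table: FeatureTable,
    out_path: str | Path,
    config_text: str = "",
    run_metadata: Optional[dict[str, str]] = None,
) -> dict[str, Path]:
    """Write the feature CSV plus configuration copy and metadata file.

    ``out_path`` is the stem; '.csv' is appended automatically.  Returns the
    paths written, keyed 'csv' / 'config' / 'metadata'.
    """
    base = Path(out_path)
    if base.suffix == ".csv":
        base = base.with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)
    suffix = _resolve_collision(base)
    stem = base.with_name(base.name + suffix)
    csv_path = stem.with_suffix(".csv")
    config_path = stem.with_name(stem.name + "_config.ini")
    meta_path = stem.with_name(stem.name + "_info.txt")

    nan_warnings = [
        f"feature '{r.group}/{r.feature}' is undefined (nan)"
        for r in table.records
        if isinstance(r.value, float) and np.isnan(r.value)
    ]
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "feature", "value"])
        for group, feature, value in table.to_rows():
            writer.writerow([group, feature, format_value(value)])
    config_path.write_text(config_text)
    lines = []
    for key, value in (run_metadata or {}).items():
        lines.append(f"{key}: {value}")
    lines.append("calculated groups: " + ", ".join(table.groups()))
    for w in nan_warnings:
        lines.append("warning: " + w)
    meta_path.write_text("\n".join(lines) + "\n")
    return {"csv": csv_path, "config": config_path, "metadata": meta_path}
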