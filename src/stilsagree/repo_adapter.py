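"""Adapter for externally deposited annotation exports.

Public multi-reader annotation deposits ship one row per reader x ROI but
with platform-specific column names and label spellings.  This adapter maps
such an export onto the normalized annotation schema via a configurable
column map, so downstream code never sees platform-native layouts.

The default column map covers the common variants (``ReaderID`` /
``reader``, ``RoiID`` / ``roi``, ``stils_density`` / ``density`` /
``score``, ...); pass an explicit ``column_map`` for anything else.  Density
cells may be blank or carry sentinel text (``NA``, ``n/a``, ``NE``, ``not
evaluable``) for non-evaluable ROIs — both become absent densities.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .annotations import AnnotationRecord, frame_to_records, normalize_label

__all__ = ["read_repository_export", "DEFAULT_COLUMN_MAP"]

#: schema column -> candidate export column names (first match wins;
#: matching is case-insensitive with '_', '-' and ' ' treated alike).
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "reader_id": ("reader_id", "readerid", "reader", "pathologist_id", "annotator"),
    "platform": ("platform", "modality", "viewer"),
    "case_id": ("case_id", "caseid", "case", "slide_id", "slide"),
    "roi_id": ("roi_id", "roiid", "roi", "region_id"),
    "batch_id": ("batch_id", "batchid", "batch"),
    "roi_label": ("roi_label", "label", "roi_type", "classification"),
    "density": ("density", "stils_density", "stils", "score", "density_estimate"),
    "percent_stroma": ("percent_stroma", "pct_stroma", "stroma", "percent_tumor_stroma"),
    "duration_s": ("duration_s", "duration", "time_s", "annotation_time", "elapsed_s"),
    "timestamp": ("timestamp", "time", "datetime", "created_at"),
}

_MISSING_DENSITY_SENTINELS = {"", "na", "n/a", "ne", "not evaluable", "none", "nan"}


def _canon(name: str) -> str:
    return name.strip().casefold().replace("-", "_").replace(" ", "_")


def read_repository_export(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    platform: str | None = None,
    delimiter: str = ",",
) -> list[AnnotationRecord]:
    """Read a platform-native delimited export into annotation records.

    ``column_map`` maps schema columns to export column names explicitly;
    without it, :data:`DEFAULT_COLUMN_MAP` candidates are tried.  ``platform``
    fills the platform field when the export lacks such a column.  Missing
    batch/case columns are tolerated (empty strings) since many exports key
    rows by ROI only; a missing reader, ROI or label column raises
    ``KeyError``.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    by_canon = {_canon(c): c for c in raw.columns}

    def find(schema_col: str) -> str | None:
        if column_map is not None and schema_col in column_map:
            return column_map[schema_col]
        for cand in DEFAULT_COLUMN_MAP[schema_col]:
            if cand in by_canon:
                return by_canon[cand]
        return None

    out = pd.DataFrame(index=raw.index)
    for schema_col in DEFAULT_COLUMN_MAP:
        src = find(schema_col)
        if src is not None:
            out[schema_col] = raw[src].astype(str).str.strip()
        elif schema_col in ("reader_id", "roi_id", "roi_label"):
            raise KeyError(
                f"export {path} has no column for {schema_col!r}; "
                "pass an explicit column_map"
            )
        else:
            out[schema_col] = ""
    if platform is not None:
        out["platform"] = platform

    def parse_density(cell: str) -> float | None:
        if cell.casefold() in _MISSING_DENSITY_SENTINELS:
            return None
        return float(cell.rstrip("%"))

    out["roi_label"] = out["roi_label"].map(normalize_label)
    out["density"] = out["density"].map(parse_density)
    out["percent_stroma"] = out["percent_stroma"].map(parse_density)
    out["duration_s"] = out["duration_s"].map(lambda c: float(c) if c else 0.0)
    out["timestamp"] = out["timestamp"].map(lambda c: c or None)
    return frame_to_records(out)
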