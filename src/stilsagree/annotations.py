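"""Data model for multi-reader ROI annotation studies of sTILs density.

The unit of data is one pathologist's annotation of one region of interest
(ROI): a categorical ROI label drawn from a four-term vocabulary and, when the
label marks the ROI as evaluable (i.e. it contains tumor-associated stroma), a
stromal tumor-infiltrating lymphocyte (sTILs) density estimate on the 0-100%
scale.  sTILs density is defined as the percent of the tumor-associated
stromal area occupied by lymphocytes; no area measurements appear in the data,
so the definition is carried here only as the [0, 100] range invariant.

Density estimates are grouped into three clinically motivated bins:

* ``low``       0% to 10%
* ``moderate``  11% to 40%
* ``high``      41% to 100%

Raw estimates are integers, but means of estimates are not, so bins are
realised as the real intervals [0, 10], (10, 40] and (40, 100]: the mean of a
9% and an 11% estimate is 10% and falls in the low bin.

This module owns the record types, delimited-text I/O, label vocabulary and
normalisation, evaluability semantics, bin assignment, and study validation.
Everything downstream (agreement statistics, workload summaries, the
simulator) builds on these types.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ANNOTATION_COLUMNS",
    "CATALOG_COLUMNS",
    "EVALUABLE_LABELS",
    "NON_EVALUABLE_LABELS",
    "LABEL_VOCABULARY",
    "DENSITY_BINS",
    "DENSITY_BIN_NAMES",
    "AnnotationRecord",
    "ROICatalogEntry",
    "DensityBin",
    "Violation",
    "SchemaError",
    "RowParseError",
    "UnknownLabelError",
    "DensityRangeError",
    "normalize_label",
    "is_evaluable",
    "assign_bin",
    "read_annotations",
    "write_annotations",
    "read_catalog",
    "write_catalog",
    "records_to_frame",
    "frame_to_records",
    "validate_study",
    "write_violations",
]


# --------------------------------------------------------------------------
# Vocabulary and bins
# --------------------------------------------------------------------------

#: The two ROI labels that mark an ROI as evaluable for sTILs density
#: (the ROI contains tumor-associated stroma).
EVALUABLE_LABELS = ("intratumoral stroma", "invasive margin")

#: The two ROI labels that mark an ROI as not evaluable.
NON_EVALUABLE_LABELS = ("tumor with no intervening stroma", "other region")

LABEL_VOCABULARY = EVALUABLE_LABELS + NON_EVALUABLE_LABELS

#: Extra spellings accepted on input (keys are normalised: casefolded,
#: whitespace collapsed).  Three annotation platforms produced data with
#: unspecified casing/punctuation, so matching is deliberately forgiving.
_LABEL_ALIASES = {
    "intra-tumoral stroma": "intratumoral stroma",
    "intra tumoral stroma": "intratumoral stroma",
    "tumor with no intervening stroma": "tumor with no intervening stroma",
    "tumour with no intervening stroma": "tumor with no intervening stroma",
    "other": "other region",
}


class UnknownLabelError(ValueError):
    """An ROI label string is not in the four-term vocabulary."""


class DensityRangeError(ValueError):
    """A density value lies outside the 0-100 percentage scale."""


class SchemaError(ValueError):
    """A delimited file is missing a mandatory column."""


class RowParseError(ValueError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _normalize_key(text: str) -> str:
    return " ".join(text.split()).casefold()


def normalize_label(label: str) -> str:
    """Map a raw label string onto the canonical four-term vocabulary.

    Matching is case- and whitespace-insensitive, with a small alias table
    for common variant spellings.  Raises :class:`UnknownLabelError` for
    anything else.
    """
    key = _normalize_key(label)
    for canonical in LABEL_VOCABULARY:
        if key == canonical:
            return canonical
    if key in _LABEL_ALIASES:
        return _LABEL_ALIASES[key]
    raise UnknownLabelError(
        f"unknown ROI label {label!r}; expected one of {list(LABEL_VOCABULARY)}"
    )


def is_evaluable(roi_label: str) -> bool:
    """True iff the label marks the ROI as evaluable for sTILs density.

    "intratumoral stroma" and "invasive margin" are evaluable; "tumor with
    no intervening stroma" and "other region" are not.  Unknown labels raise
    :class:`UnknownLabelError`.
    """
    return normalize_label(roi_label) in EVALUABLE_LABELS


@dataclass(frozen=True)
class DensityBin:
    """One clinical density bin: a half-open/closed interval on [0, 100]."""

    name: str
    lower: float  # exclusive, except the low bin which includes 0
    upper: float  # inclusive

    def __contains__(self, density: float) -> bool:
        if self.name == "low":
            return self.lower <= density <= self.upper
        return self.lower < density <= self.upper


#: The three density bins.  Together they partition [0, 100].
DENSITY_BINS = (
    DensityBin("low", 0.0, 10.0),
    DensityBin("moderate", 10.0, 40.0),
    DensityBin("high", 40.0, 100.0),
)

DENSITY_BIN_NAMES = tuple(b.name for b in DENSITY_BINS)


def assign_bin(density: float) -> str:
    """Assign a density (0-100, fractional allowed) to its clinical bin.

    low = [0, 10], moderate = (10, 40], high = (40, 100].  Means of integer
    estimates flow through here, hence the real-interval edges: mean(9, 11)
    = 10 is low.  Out-of-range or non-finite values raise
    :class:`DensityRangeError`.
    """
    if not math.isfinite(density) or not 0.0 <= density <= 100.0:
        raise DensityRangeError(f"density {density!r} outside [0, 100]")
    for b in DENSITY_BINS:
        if density in b:
            return b.name
    raise AssertionError("unreachable: bins partition [0, 100]")


# --------------------------------------------------------------------------
# Record types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationRecord:
    """One reader's annotation of one ROI.

    ``density`` and ``percent_stroma`` are ``None`` when absent;
    a density is expected exactly when ``roi_label`` is evaluable.
    ``(reader_id, platform, roi_id, timestamp)`` identifies a record.
    """

    reader_id: str
    platform: str
    case_id: str
    roi_id: str
    batch_id: str
    roi_label: str
    density: float | None = None
    percent_stroma: float | None = None
    duration_s: float = 0.0
    timestamp: str | None = None

    @property
    def evaluable(self) -> bool:
        return is_evaluable(self.roi_label)

    @property
    def density_bin(self) -> str | None:
        """Clinical bin of the density estimate, or None when absent."""
        return None if self.density is None else assign_bin(self.density)


@dataclass(frozen=True)
class ROICatalogEntry:
    """Study-design identity of an ROI: its case, batch and within-case slot."""

    roi_id: str
    case_id: str
    batch_id: str
    ordinal_in_case: int


ANNOTATION_COLUMNS = (
    "reader_id",
    "platform",
    "case_id",
    "roi_id",
    "batch_id",
    "roi_label",
    "density",
    "percent_stroma",
    "duration_s",
    "timestamp",
)

#: Columns that must be present in an annotation file; the optional value
#: columns may be absent entirely (treated as all-empty).
_MANDATORY_ANNOTATION_COLUMNS = (
    "reader_id",
    "platform",
    "case_id",
    "roi_id",
    "batch_id",
    "roi_label",
)

CATALOG_COLUMNS = ("roi_id", "case_id", "batch_id", "ordinal_in_case")


# --------------------------------------------------------------------------
# Delimited-text I/O
# --------------------------------------------------------------------------


def _parse_float(cell: str, line: int, column: str) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise RowParseError(line, f"unparseable {column} value {cell!r}") from None


def read_annotations(
    path: str | Path, delimiter: str = ","
) -> list[AnnotationRecord]:
    """Read an annotation table from delimited text (default comma, UTF-8).

    The header row names the schema columns in any order.  Labels are
    normalised to the canonical vocabulary; empty density / percent_stroma /
    duration / timestamp cells become absent values.  A missing mandatory
    column raises :class:`SchemaError` naming the column; a bad cell raises
    :class:`RowParseError` with the 1-based line number.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in _MANDATORY_ANNOTATION_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing mandatory column {col!r} in {path}")
        for row in reader:
            line = reader.line_num
            try:
                label = normalize_label(row["roi_label"])
            except UnknownLabelError as exc:
                raise RowParseError(line, str(exc)) from None
            duration = _parse_float(row.get("duration_s") or "", line, "duration_s")
            if duration is not None and duration < 0:
                raise RowParseError(line, f"negative duration_s {duration}")
            ts = (row.get("timestamp") or "").strip() or None
            records.append(
                AnnotationRecord(
                    reader_id=row["reader_id"].strip(),
                    platform=row["platform"].strip(),
                    case_id=row["case_id"].strip(),
                    roi_id=row["roi_id"].strip(),
                    batch_id=row["batch_id"].strip(),
                    roi_label=label,
                    density=_parse_float(row.get("density") or "", line, "density"),
                    percent_stroma=_parse_float(
                        row.get("percent_stroma") or "", line, "percent_stroma"
                    ),
                    duration_s=0.0 if duration is None else duration,
                    timestamp=ts,
                )
            )
    return records


def _format_optional(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def write_annotations(
    records: Iterable[AnnotationRecord], path: str | Path, delimiter: str = ","
) -> None:
    """Write records as delimited text; round-trips exactly through
    :func:`read_annotations` (floats serialised with shortest repr)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(ANNOTATION_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.reader_id,
                    r.platform,
                    r.case_id,
                    r.roi_id,
                    r.batch_id,
                    r.roi_label,
                    _format_optional(r.density),
                    _format_optional(r.percent_stroma),
                    repr(float(r.duration_s)),
                    r.timestamp or "",
                ]
            )


def read_catalog(path: str | Path, delimiter: str = ",") -> list[ROICatalogEntry]:
    """Read an ROI catalog (roi_id, case_id, batch_id, ordinal_in_case)."""
    path = Path(path)
    entries: list[ROICatalogEntry] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in CATALOG_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing mandatory column {col!r} in {path}")
        for row in reader:
            line = reader.line_num
            try:
                ordinal = int(row["ordinal_in_case"])
            except ValueError:
                raise RowParseError(
                    line, f"unparseable ordinal_in_case {row['ordinal_in_case']!r}"
                ) from None
            entries.append(
                ROICatalogEntry(
                    roi_id=row["roi_id"].strip(),
                    case_id=row["case_id"].strip(),
                    batch_id=row["batch_id"].strip(),
                    ordinal_in_case=ordinal,
                )
            )
    return entries


def write_catalog(
    entries: Iterable[ROICatalogEntry], path: str | Path, delimiter: str = ","
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(CATALOG_COLUMNS)
        for e in entries:
            writer.writerow([e.roi_id, e.case_id, e.batch_id, e.ordinal_in_case])


def records_to_frame(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Annotation records as a DataFrame with the standard schema columns."""
    return pd.DataFrame(
        [[getattr(r, c) for c in ANNOTATION_COLUMNS] for r in records],
        columns=list(ANNOTATION_COLUMNS),
    )


def frame_to_records(frame: pd.DataFrame) -> list[AnnotationRecord]:
    """Build records from a DataFrame carrying the standard schema columns.

    NaN in density / percent_stroma / timestamp means absent; labels are
    normalised.
    """
    records = []
    for row in frame.itertuples(index=False):
        density = getattr(row, "density", None)
        stroma = getattr(row, "percent_stroma", None)
        duration = getattr(row, "duration_s", 0.0)
        ts = getattr(row, "timestamp", None)
        records.append(
            AnnotationRecord(
                reader_id=str(row.reader_id),
                platform=str(row.platform),
                case_id=str(row.case_id),
                roi_id=str(row.roi_id),
                batch_id=str(row.batch_id),
                roi_label=normalize_label(str(row.roi_label)),
                density=None if density is None or pd.isna(density) else float(density),
                percent_stroma=None if stroma is None or pd.isna(stroma) else float(stroma),
                duration_s=0.0 if duration is None or pd.isna(duration) else float(duration),
                timestamp=None if ts is None or pd.isna(ts) else str(ts),
            )
        )
    return records


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One validation finding: never raised, always reported."""

    rule: str
    severity: str  # "error" | "warning"
    record: str  # identity of the offending record(s)
    message: str


def _record_identity(r: AnnotationRecord) -> str:
    return f"reader={r.reader_id} platform={r.platform} roi={r.roi_id} ts={r.timestamp}"


def validate_study(
    records: Sequence[AnnotationRecord],
    catalog: Sequence[ROICatalogEntry] | None = None,
) -> list[Violation]:
    """Check a record collection against the study rules; report, never raise.

    Rules checked per record:

    * ``density-range``     density outside [0, 100]
    * ``stroma-range``      percent_stroma outside [0, 100]
    * ``negative-duration`` duration_s < 0
    * ``missing-density``   evaluable label but no density (the task requires
      a density estimate whenever the ROI is evaluable)
    * ``unexpected-density`` non-evaluable label with a density present (the
      density is reported and ignored downstream)
    * ``unknown-roi``       roi_id not in the catalog (when a catalog is given)
    * ``catalog-mismatch``  case/batch disagree with the catalog entry
    * ``duplicate-record``  two records share (reader, platform, roi, timestamp)
    """
    violations: list[Violation] = []
    catalog_by_id = {e.roi_id: e for e in catalog} if catalog is not None else None
    seen: dict[tuple, int] = {}

    for r in records:
        ident = _record_identity(r)
        if r.density is not None and not 0.0 <= r.density <= 100.0:
            violations.append(
                Violation("density-range", "error", ident,
                          f"density {r.density} outside [0, 100]")
            )
        if r.percent_stroma is not None and not 0.0 <= r.percent_stroma <= 100.0:
            violations.append(
                Violation("stroma-range", "error", ident,
                          f"percent_stroma {r.percent_stroma} outside [0, 100]")
            )
        if r.duration_s < 0:
            violations.append(
                Violation("negative-duration", "error", ident,
                          f"duration_s {r.duration_s} < 0")
            )
        try:
            evaluable = r.evaluable
        except UnknownLabelError as exc:
            violations.append(Violation("unknown-label", "error", ident, str(exc)))
            evaluable = None
        if evaluable is True and r.density is None:
            violations.append(
                Violation("missing-density", "error", ident,
                          "evaluable ROI label without a density estimate")
            )
        if evaluable is False and r.density is not None:
            violations.append(
                Violation("unexpected-density", "warning", ident,
                          "density present on a non-evaluable label; ignored downstream")
            )
        if catalog_by_id is not None:
            entry = catalog_by_id.get(r.roi_id)
            if entry is None:
                violations.append(
                    Violation("unknown-roi", "error", ident,
                              f"roi_id {r.roi_id!r} not in catalog")
                )
            elif entry.case_id != r.case_id or entry.batch_id != r.batch_id:
                violations.append(
                    Violation(
                        "catalog-mismatch", "error", ident,
                        f"case/batch ({r.case_id}, {r.batch_id}) != catalog "
                        f"({entry.case_id}, {entry.batch_id})",
                    )
                )
        key = (r.reader_id, r.platform, r.roi_id, r.timestamp)
        if key in seen:
            violations.append(
                Violation("duplicate-record", "error", ident,
                          "duplicate (reader_id, platform, roi_id, timestamp)")
            )
        else:
            seen[key] = 1
    return violations


def write_violations(
    violations: Sequence[Violation], path: str | Path, delimiter: str = ","
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["rule", "severity", "record", "message"])
        for v in violations:
            writer.writerow([v.rule, v.severity, v.record, v.message])
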