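"""Time-burden and coverage summaries for multi-reader annotation studies.

Annotation software records how long each ROI annotation took (time on the
input screen only, so interruptions inflate individual durations — long
durations are flagged, never trimmed).  Microscope-based collection adds a
fixed per-ROI hardware overhead (stage movement and slide-image registration)
that the software does not record; it enters as a supplied constant per
platform, not something estimated from the data.

Study-time projection is a simple linear rule:

    hours = (mean_annotation_s + hardware_overhead_s) * n_rois / 3600

e.g. 29.98 s/ROI with no overhead projects a 640-ROI study at 5.33 h, while
27.41 s/ROI plus a 46.34 s/ROI microscope overhead projects 13.11 h.

Coverage tabulations count annotations per ROI, complete "passes" over each
batch (one reader covering a configurable fraction of a batch's ROIs on one
platform), and the distribution of ROI labels and density bins per platform.

Reader-count convention: a reader who used two platforms is counted once per
platform, and the pooled row sums the per-platform counts — so the pooled
reader count can exceed the number of distinct people.  This mirrors how
multi-platform studies tabulate platform-local reader pools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    DENSITY_BIN_NAMES,
    EVALUABLE_LABELS,
    LABEL_VOCABULARY,
    AnnotationRecord,
    ROICatalogEntry,
    assign_bin,
    is_evaluable,
)

__all__ = [
    "TimingSummary",
    "CoverageTable",
    "timing_summary",
    "project_time",
    "timing_table",
    "coverage_counts",
    "long_duration_records",
]

#: Durations above this many seconds are flagged as probable interruptions
#: in reports (10 minutes); they are never removed from the averages.
LONG_DURATION_S = 600.0

POOLED = "All"


@dataclass(frozen=True)
class TimingSummary:
    """Per-platform (or pooled) annotation-time summary."""

    platform: str
    n_readers: int
    n_observations: int
    mean_annotation_s: float
    sd_annotation_s: float
    hardware_overhead_s: float  # 0 for digital platforms


def timing_summary(
    records: Iterable[AnnotationRecord],
    hardware_overhead: Mapping[str, float] | None = None,
) -> list[TimingSummary]:
    """Mean and sample SD of annotation durations per platform plus pooled.

    The pooled row is labelled ``"All"``: its observation count and moments
    pool every record, and its reader count is the *sum* of per-platform
    reader counts (platform-local convention; see module docstring).  Its
    hardware overhead is reported as 0.  Platforms with no records are
    omitted; empty input yields an empty list.
    """
    hardware_overhead = dict(hardware_overhead or {})
    by_platform: dict[str, list[AnnotationRecord]] = {}
    for r in records:
        by_platform.setdefault(r.platform, []).append(r)
    if not by_platform:
        return []
    out = []
    for platform in sorted(by_platform):
        recs = by_platform[platform]
        d = np.array([r.duration_s for r in recs], dtype=float)
        out.append(
            TimingSummary(
                platform=platform,
                n_readers=len({r.reader_id for r in recs}),
                n_observations=len(recs),
                mean_annotation_s=float(d.mean()),
                sd_annotation_s=float(d.std(ddof=1)) if d.size > 1 else 0.0,
                hardware_overhead_s=float(hardware_overhead.get(platform, 0.0)),
            )
        )
    all_d = np.array(
        [r.duration_s for recs in by_platform.values() for r in recs], dtype=float
    )
    out.append(
        TimingSummary(
            platform=POOLED,
            n_readers=sum(s.n_readers for s in out),
            n_observations=int(all_d.size),
            mean_annotation_s=float(all_d.mean()),
            sd_annotation_s=float(all_d.std(ddof=1)) if all_d.size > 1 else 0.0,
            hardware_overhead_s=0.0,
        )
    )
    return out


def project_time(
    mean_annotation_s: float, hardware_overhead_s: float, n_rois: int
) -> float:
    """Projected reader hours to annotate ``n_rois`` ROIs.

    ``(mean_annotation_s + hardware_overhead_s) * n_rois / 3600``; linear in
    the ROI count and monotone in both time arguments.  Tables round to two
    decimals; the return value is unrounded.
    """
    if mean_annotation_s < 0 or hardware_overhead_s < 0 or n_rois < 0:
        raise ValueError("times and ROI counts must be nonnegative")
    return (mean_annotation_s + hardware_overhead_s) * n_rois / 3600.0


def timing_table(
    summaries: Sequence[TimingSummary],
    n_rois_batch: int = 80,
    n_rois_study: int = 640,
) -> pd.DataFrame:
    """Timing report with batch- and study-time projections, 2-dp rounding.

    Projections are left blank (NaN) for the pooled row, which mixes
    platforms with different overheads.
    """
    rows = []
    for s in summaries:
        pooled = s.platform == POOLED
        rows.append(
            {
                "platform": s.platform,
                "readers": s.n_readers,
                "observations": s.n_observations,
                "mean_annotation_s": round(s.mean_annotation_s, 2),
                "sd_annotation_s": round(s.sd_annotation_s, 2),
                "hardware_overhead_s": None if pooled else round(s.hardware_overhead_s, 2),
                "batch_time_h": None if pooled else round(
                    project_time(s.mean_annotation_s, s.hardware_overhead_s, n_rois_batch), 2
                ),
                "study_time_h": None if pooled else round(
                    project_time(s.mean_annotation_s, s.hardware_overhead_s, n_rois_study), 2
                ),
            }
        )
    return pd.DataFrame(rows)


def long_duration_records(
    records: Iterable[AnnotationRecord], threshold_s: float = LONG_DURATION_S
) -> list[AnnotationRecord]:
    """Records whose duration exceeds the interruption-flag threshold."""
    return [r for r in records if r.duration_s > threshold_s]


@dataclass(frozen=True)
class CoverageTable:
    """Coverage and distribution tabulations for one study.

    ``label_counts``: platforms x 4 ROI labels (+ pooled "All" row);
    ``bin_counts``: platforms x 3 density bins, counting usable density
    estimates; ``per_roi_counts``: annotations per ROI over all platforms;
    ``batch_passes``: complete annotation passes per batch, where a pass is
    one (reader, platform) covering at least ``pass_threshold`` of the
    batch's ROIs.
    """

    label_counts: pd.DataFrame
    bin_counts: pd.DataFrame
    per_roi_counts: pd.Series
    batch_passes: pd.Series
    pass_threshold: float

    @property
    def n_observations(self) -> int:
        return int(self.label_counts.loc[POOLED].sum())

    @property
    def n_evaluable(self) -> int:
        return int(self.label_counts.loc[POOLED, list(EVALUABLE_LABELS)].sum())

    def distribution_table(self) -> pd.DataFrame:
        """Label and density-bin counts side by side, one row per platform."""
        return pd.concat([self.label_counts, self.bin_counts], axis=1)


def coverage_counts(
    records: Sequence[AnnotationRecord],
    catalog: Sequence[ROICatalogEntry],
    pass_threshold: float = 1.0,
) -> CoverageTable:
    """Tabulate annotation coverage against the study catalog.

    Conservation properties: per platform, the four label counts sum to the
    platform's observation count, and the three bin counts sum to its count
    of usable density estimates.
    """
    if not 0.0 < pass_threshold <= 1.0:
        raise ValueError("pass_threshold must be in (0, 1]")
    platforms = sorted({r.platform for r in records})
    labels = list(LABEL_VOCABULARY)
    label_counts = pd.DataFrame(0, index=platforms + [POOLED], columns=labels)
    bin_counts = pd.DataFrame(0, index=platforms + [POOLED], columns=list(DENSITY_BIN_NAMES))
    roi_counts: dict[str, int] = {e.roi_id: 0 for e in catalog}
    for r in records:
        label_counts.loc[r.platform, r.roi_label] += 1
        if r.density is not None and is_evaluable(r.roi_label):
            bin_counts.loc[r.platform, assign_bin(r.density)] += 1
        if r.roi_id in roi_counts:
            roi_counts[r.roi_id] += 1
    label_counts.loc[POOLED] = label_counts.loc[platforms].sum()
    bin_counts.loc[POOLED] = bin_counts.loc[platforms].sum()

    batch_rois: dict[str, set[str]] = {}
    for e in catalog:
        batch_rois.setdefault(e.batch_id, set()).add(e.roi_id)
    covered: dict[tuple[str, str, str], set[str]] = {}
    roi_batch = {e.roi_id: e.batch_id for e in catalog}
    for r in records:
        batch = roi_batch.get(r.roi_id)
        if batch is not None:
            covered.setdefault((r.reader_id, r.platform, batch), set()).add(r.roi_id)
    passes = dict.fromkeys(sorted(batch_rois), 0)
    for (_, _, batch), rois in covered.items():
        need = math.ceil(pass_threshold * len(batch_rois[batch]))
        if len(rois) >= need:
            passes[batch] += 1
    return CoverageTable(
        label_counts=label_counts,
        bin_counts=bin_counts,
        per_roi_counts=pd.Series(roi_counts, name="n_annotations").sort_index(),
        batch_passes=pd.Series(passes, name="n_passes"),
        pass_threshold=pass_threshold,
    )
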