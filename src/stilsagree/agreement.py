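"""Inter-pathologist agreement statistics for sTILs-density annotations.

Two strands of analysis live here.

**Per-ROI variability.**  For every ROI with at least ``min_readers`` density
estimates, the sample mean, sample variance (n-1 denominator) and coefficient
of variation (CV = sd / mean) over readers are computed, and the resulting
summaries can be partitioned into equal-count bins ordered by mean to expose
how variance and CV move with the mean density (variance increases with the
mean; CV decreases).

**Two-reader agreement.**  The mean squared difference between two readers'
estimates of the same ROI,

    MSD = E[(X_j'kl - X_jkl)^2],

needs no reference standard; RMSD = sqrt(MSD).  Per ROI the mean of squared
differences over all unordered reader pairs equals exactly twice the sample
variance of that ROI's estimates — the identity used by :func:`pairwise_msd`.
For a chosen pair of readers the analysis counts *paired observations* (ROIs
where both readers agree on evaluability, or per bin, on the bin) and
*averaged observations* (co-evaluable ROIs assigned to the bin of the mean of
the two estimates), computes RMSD overall and within each averaged bin, and
builds Bland-Altman panels per bin: differences against means, the bias line
m̄, and limits of agreement m̄ ± 2·sqrt(RMSD² − m̄²) — twice the standard
deviation of the differences, since RMSD² = m̄² + sd².

The model object :class:`TwoReaderAgreement` wraps the two-reader strand:
construct it from two readers' records (or a full study table plus reader
IDs), call :meth:`~TwoReaderAgreement.fit`, and read the
:class:`TwoReaderAgreementResults`, whose ``summary()`` prints the
individual / paired / averaged / RMSD table.

ROIs are treated as independent; correlation of ROIs within a case is
deliberately ignored (a full multi-reader multi-case variance decomposition
is out of scope), and no confidence intervals are attached to the limits —
with sparse moderate/high bins they would be uninterpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    DENSITY_BIN_NAMES,
    AnnotationRecord,
    ROICatalogEntry,
    assign_bin,
    is_evaluable,
    records_to_frame,
    frame_to_records,
)

__all__ = [
    "ROISummary",
    "BinnedCurve",
    "MSDResult",
    "CrossCounts",
    "BlandAltmanBin",
    "NoPairedDataError",
    "DuplicateAnnotationError",
    "roi_summaries",
    "binned_curve",
    "pairwise_msd",
    "evaluability_cross_counts",
    "averaged_bin_counts",
    "bin_rmsd",
    "bland_altman",
    "complete_readers",
    "TwoReaderAgreement",
    "TwoReaderAgreementResults",
]


class NoPairedDataError(ValueError):
    """No ROI carries enough estimates for the requested statistic."""


class DuplicateAnnotationError(ValueError):
    """A reader annotated the same ROI more than once and no dedup policy applies."""


# --------------------------------------------------------------------------
# Per-ROI summaries and the variance / CV curves
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ROISummary:
    """Reader statistics for one ROI: n, mean, sample variance, CV.

    ``cv`` is ``None`` when the mean is zero (CV undefined); such ROIs are
    skipped by the CV curve.
    """

    roi_id: str
    n_readers: int
    mean: float
    sample_variance: float
    cv: float | None


def _usable_density(r: AnnotationRecord) -> bool:
    # A density counts only when the reader's own label was evaluable;
    # densities attached to non-evaluable labels are validation findings
    # and are ignored here.
    return r.density is not None and is_evaluable(r.roi_label)


def roi_summaries(
    records: Iterable[AnnotationRecord], min_readers: int = 2
) -> list[ROISummary]:
    """Per-ROI mean / variance / CV over readers' density estimates.

    Only ROIs with at least ``min_readers`` usable density estimates are
    summarised.  Sample variance uses the n-1 denominator, so single-estimate
    ROIs never qualify when ``min_readers >= 2``.  Output is sorted by
    ``roi_id``.
    """
    if min_readers < 1:
        raise ValueError("min_readers must be >= 1")
    by_roi: dict[str, list[float]] = {}
    for r in records:
        if _usable_density(r):
            by_roi.setdefault(r.roi_id, []).append(float(r.density))
    out = []
    for roi_id in sorted(by_roi):
        xs = np.asarray(by_roi[roi_id], dtype=float)
        if xs.size < min_readers:
            continue
        mean = float(xs.mean())
        var = float(xs.var(ddof=1)) if xs.size > 1 else 0.0
        cv = None if mean == 0.0 else math.sqrt(var) / mean
        out.append(ROISummary(roi_id, int(xs.size), mean, var, cv))
    return out


@dataclass(frozen=True)
class BinnedCurve:
    """Equal-count binning of ROI summaries ordered by mean density.

    Each row of :attr:`table` describes one bin: member ROI count, mean of
    the per-ROI means, mean per-ROI sample variance, and mean CV over the
    member ROIs with a defined CV.
    """

    table: pd.DataFrame  # columns: n_rois, mean_density, mean_variance, mean_cv

    @property
    def n_bins(self) -> int:
        return len(self.table)


def binned_curve(summaries: Sequence[ROISummary], n_bins: int = 10) -> BinnedCurve:
    """Partition summaries into ``n_bins`` consecutive equal-count groups.

    Summaries are sorted by mean (ties broken by roi_id); with N summaries
    the first bins hold floor(N / n_bins) ROIs and the N mod n_bins leftover
    ROIs are assigned one each to the last bins, so for N = 495 and ten bins
    the sizes are 49 x 5 then 50 x 5.
    """
    n = len(summaries)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n == 0:
        raise ValueError("no summaries to bin")
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds number of summaries ({n})")
    ordered = sorted(summaries, key=lambda s: (s.mean, s.roi_id))
    base, extra = divmod(n, n_bins)
    sizes = [base] * (n_bins - extra) + [base + 1] * extra
    rows = []
    start = 0
    for size in sizes:
        members = ordered[start : start + size]
        start += size
        cvs = [s.cv for s in members if s.cv is not None]
        rows.append(
            {
                "n_rois": size,
                "mean_density": float(np.mean([s.mean for s in members])),
                "mean_variance": float(np.mean([s.sample_variance for s in members])),
                "mean_cv": float(np.mean(cvs)) if cvs else np.nan,
            }
        )
    return BinnedCurve(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# Pairwise MSD / RMSD over all readers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MSDResult:
    """Pairwise mean-squared-difference summary over qualifying ROIs."""

    msd: float
    rmsd: float
    per_roi: dict[str, float]
    n_rois: int


def pairwise_msd(records: Iterable[AnnotationRecord]) -> MSDResult:
    """Reader-to-reader MSD and RMSD, averaged over ROIs.

    Per ROI, MSD is the mean of (x_i - x_j)^2 over all unordered reader
    pairs, which equals 2 x the sample variance of the ROI's estimates.
    The overall MSD is the unweighted mean of per-ROI MSDs over ROIs with
    at least two estimates; RMSD = sqrt(MSD).  Raises
    :class:`NoPairedDataError` when no ROI has two estimates.
    """
    summaries = roi_summaries(records, min_readers=2)
    if not summaries:
        raise NoPairedDataError("no ROI carries at least two density estimates")
    per_roi = {s.roi_id: 2.0 * s.sample_variance for s in summaries}
    msd = float(np.mean(list(per_roi.values())))
    return MSDResult(msd=msd, rmsd=math.sqrt(msd), per_roi=per_roi, n_rois=len(per_roi))


# --------------------------------------------------------------------------
# Two-reader pairing
# --------------------------------------------------------------------------


def _dedup_reader_records(
    records: Iterable[AnnotationRecord], policy: str
) -> dict[str, AnnotationRecord]:
    """One record per ROI for a single reader.

    ``policy='error'`` raises on repeats; ``policy='latest'`` keeps the
    record with the greatest timestamp (ISO-8601 strings order correctly;
    absent timestamps sort first).
    """
    by_roi: dict[str, AnnotationRecord] = {}
    for r in records:
        if r.roi_id not in by_roi:
            by_roi[r.roi_id] = r
            continue
        if policy == "error":
            raise DuplicateAnnotationError(
                f"reader {r.reader_id!r} annotated roi {r.roi_id!r} more than once "
                "(pass dedup='latest' to keep the latest timestamp)"
            )
        if policy == "latest":
            if (r.timestamp or "") >= (by_roi[r.roi_id].timestamp or ""):
                by_roi[r.roi_id] = r
        else:
            raise ValueError(f"unknown dedup policy {policy!r}")
    return by_roi


def _paired(
    records_a: Iterable[AnnotationRecord],
    records_b: Iterable[AnnotationRecord],
    dedup: str = "error",
) -> list[tuple[AnnotationRecord, AnnotationRecord]]:
    a = _dedup_reader_records(records_a, dedup)
    b = _dedup_reader_records(records_b, dedup)
    return [(a[roi], b[roi]) for roi in sorted(a.keys() & b.keys())]


def _co_evaluable(
    pairs: Sequence[tuple[AnnotationRecord, AnnotationRecord]]
) -> list[tuple[str, float, float]]:
    """(roi_id, x_a, x_b) for ROIs where both readers gave usable densities."""
    return [
        (ra.roi_id, float(ra.density), float(rb.density))
        for ra, rb in pairs
        if _usable_density(ra) and _usable_density(rb)
    ]


@dataclass(frozen=True)
class CrossCounts:
    """Two-reader evaluability cross-counts and per-bin paired counts.

    ROIs where the readers disagree on evaluability contribute to no count;
    ``paired_bin_counts[b]`` counts ROIs where *both* readers' own estimates
    fall in bin ``b`` (observations are lost when estimates cross bins).
    """

    n_both_not_evaluable: int
    n_both_evaluable: int
    paired_bin_counts: dict[str, int]


def evaluability_cross_counts(
    records_a: Iterable[AnnotationRecord],
    records_b: Iterable[AnnotationRecord],
    dedup: str = "error",
) -> CrossCounts:
    """Count paired observations for two readers over their shared ROIs."""
    pairs = _paired(records_a, records_b, dedup)
    n_nn = sum(
        1 for ra, rb in pairs if not is_evaluable(ra.roi_label) and not is_evaluable(rb.roi_label)
    )
    co = _co_evaluable(pairs)
    bins = dict.fromkeys(DENSITY_BIN_NAMES, 0)
    for _, xa, xb in co:
        ba, bb = assign_bin(xa), assign_bin(xb)
        if ba == bb:
            bins[ba] += 1
    return CrossCounts(n_nn, len(co), bins)


def averaged_bin_counts(
    records_a: Iterable[AnnotationRecord],
    records_b: Iterable[AnnotationRecord],
    dedup: str = "error",
) -> dict[str, int]:
    """Count co-evaluable ROIs by the bin of the mean of the two estimates.

    An ROI scored 9% and 11% averages to 10% and lands in the low bin.  The
    counts sum to the number of co-evaluable ROIs.
    """
    pairs = _paired(records_a, records_b, dedup)
    counts = dict.fromkeys(DENSITY_BIN_NAMES, 0)
    for _, xa, xb in _co_evaluable(pairs):
        counts[assign_bin((xa + xb) / 2.0)] += 1
    return counts


def bin_rmsd(
    records_a: Iterable[AnnotationRecord],
    records_b: Iterable[AnnotationRecord],
    dedup: str = "error",
) -> tuple[float, dict[str, float | None]]:
    """RMSD over all co-evaluable ROIs and within each averaged bin.

    ``rmsd_all = sqrt(mean (x_a - x_b)^2)``; per-bin RMSD restricts the mean
    to ROIs whose averaged estimate falls in that bin (``None`` for empty
    bins).  Raises :class:`NoPairedDataError` with no co-evaluable ROI.
    """
    pairs = _paired(records_a, records_b, dedup)
    co = _co_evaluable(pairs)
    if not co:
        raise NoPairedDataError("no co-evaluable ROI for this reader pair")
    sq = np.array([(xa - xb) ** 2 for _, xa, xb in co])
    by_bin: dict[str, list[float]] = {b: [] for b in DENSITY_BIN_NAMES}
    for (_, xa, xb), s in zip(co, sq):
        by_bin[assign_bin((xa + xb) / 2.0)].append(s)
    rmsd_bins = {
        b: (math.sqrt(float(np.mean(v))) if v else None) for b, v in by_bin.items()
    }
    return math.sqrt(float(sq.mean())), rmsd_bins


@dataclass(frozen=True)
class BlandAltmanBin:
    """Bland-Altman panel for one averaged-density bin.

    ``points`` holds one row per co-evaluable ROI in the bin with columns
    roi_id, mean, diff.  ``mean_diff`` is the bias line m̄; the limits are
    m̄ ± 2·sqrt(RMSD² − m̄²) (RMSD² − m̄² is the variance of the differences
    about m̄ with the n denominator, clamped at 0 against roundoff).
    """

    name: str
    points: pd.DataFrame
    mean_diff: float | None
    rmsd: float | None
    lower_limit: float | None
    upper_limit: float | None


def bland_altman(
    records_a: Iterable[AnnotationRecord],
    records_b: Iterable[AnnotationRecord],
    dedup: str = "error",
    direction: tuple[str, str] | None = None,
) -> dict[str, BlandAltmanBin]:
    """Per-bin Bland-Altman points, bias and limits of agreement.

    Differences are taken as (reader with the lexicographically smaller ID)
    minus (the other); pass ``direction=(first_id, second_id)`` to override.
    Panels are keyed by averaged-bin name; an empty bin yields a panel with
    no points and ``None`` statistics.
    """
    a_list, b_list = list(records_a), list(records_b)
    ids = {r.reader_id for r in a_list} | {r.reader_id for r in b_list}
    if direction is not None:
        first, second = direction
    else:
        first, second = sorted(ids) if len(ids) == 2 else (None, None)
    pairs = _paired(a_list, b_list, dedup)
    co = _co_evaluable(pairs)
    # orient each pair so the difference is first-reader minus second-reader
    a_ids = {r.reader_id for r in a_list}
    flip = first is not None and first not in a_ids
    rows: dict[str, list[tuple[str, float, float]]] = {b: [] for b in DENSITY_BIN_NAMES}
    for roi, xa, xb in co:
        diff = (xb - xa) if flip else (xa - xb)
        mean = (xa + xb) / 2.0
        rows[assign_bin(mean)].append((roi, mean, diff))
    panels = {}
    for name, pts in rows.items():
        frame = pd.DataFrame(pts, columns=["roi_id", "mean", "diff"])
        if len(frame):
            diffs = frame["diff"].to_numpy()
            mbar = float(diffs.mean())
            rmsd = math.sqrt(float((diffs**2).mean()))
            half = 2.0 * math.sqrt(max(rmsd**2 - mbar**2, 0.0))
            panels[name] = BlandAltmanBin(name, frame, mbar, rmsd, mbar - half, mbar + half)
        else:
            panels[name] = BlandAltmanBin(name, frame, None, None, None, None)
    return panels


def complete_readers(
    records: Iterable[AnnotationRecord],
    catalog: Sequence[ROICatalogEntry],
    platform: str | None = None,
) -> list[str]:
    """Readers whose annotations cover every catalog ROI on one platform.

    An annotation of any kind (evaluable or not) counts as coverage.  When
    ``platform`` is given only that platform's records are considered;
    otherwise a reader qualifies if any single platform's records cover the
    catalog.  Returns sorted reader IDs.
    """
    all_rois = {e.roi_id for e in catalog}
    cover: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if platform is not None and r.platform != platform:
            continue
        cover.setdefault((r.reader_id, r.platform), set()).add(r.roi_id)
    return sorted(
        {rid for (rid, _), rois in cover.items() if all_rois <= rois}
    )


# --------------------------------------------------------------------------
# Model / Results objects
# --------------------------------------------------------------------------


class TwoReaderAgreement:
    """Agreement model for two readers' annotations of a shared ROI set.

    Parameters
    ----------
    records_a, records_b
        Each reader's full-study annotation records (one usable record per
        ROI; repeats raise unless ``dedup='latest'``).
    dedup
        ``'error'`` (default) or ``'latest'`` — policy for repeated
        annotations of one ROI by one reader.
    direction
        Optional ``(first_id, second_id)`` fixing the sign of differences;
        by default the lexicographically smaller reader ID comes first.

    Examples
    --------
    >>> model = TwoReaderAgreement.from_records(records, readers=("4776", "0455"))
    >>> res = model.fit()
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(
        self,
        records_a: Sequence[AnnotationRecord],
        records_b: Sequence[AnnotationRecord],
        dedup: str = "error",
        direction: tuple[str, str] | None = None,
    ):
        self.records_a = list(records_a)
        self.records_b = list(records_b)
        if not self.records_a or not self.records_b:
            raise ValueError("both readers need at least one record")
        ids_a = {r.reader_id for r in self.records_a}
        ids_b = {r.reader_id for r in self.records_b}
        if len(ids_a) != 1 or len(ids_b) != 1:
            raise ValueError("each record collection must belong to a single reader")
        self.reader_a = next(iter(ids_a))
        self.reader_b = next(iter(ids_b))
        if self.reader_a == self.reader_b:
            raise ValueError("the two collections belong to the same reader")
        self.dedup = dedup
        self.direction = direction or tuple(sorted((self.reader_a, self.reader_b)))

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[AnnotationRecord],
        readers: tuple[str, str] | None = None,
        platform: str | None = None,
        catalog: Sequence[ROICatalogEntry] | None = None,
        dedup: str = "error",
    ) -> "TwoReaderAgreement":
        """Build the model from a full study table.

        With ``readers=None`` the pair is auto-selected as the readers who
        annotated every catalog ROI on the given platform ("complete
        readers"); exactly two must qualify, otherwise a ``ValueError``
        lists the candidates.
        """
        records = [
            r for r in records if platform is None or r.platform == platform
        ]
        if readers is None:
            if catalog is None:
                raise ValueError("auto-selection of complete readers requires a catalog")
            found = complete_readers(records, catalog, platform)
            if len(found) != 2:
                raise ValueError(
                    f"complete-reader auto-selection found {len(found)} candidate(s) "
                    f"{found}; expected exactly 2 — pass readers=(id, id)"
                )
            readers = (found[0], found[1])
        ra = [r for r in records if r.reader_id == readers[0]]
        rb = [r for r in records if r.reader_id == readers[1]]
        for rid, rr in zip(readers, (ra, rb)):
            if not rr:
                raise ValueError(f"no records for reader {rid!r}")
        return cls(ra, rb, dedup=dedup)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        readers: tuple[str, str] | None = None,
        platform: str | None = None,
        catalog: Sequence[ROICatalogEntry] | None = None,
        dedup: str = "error",
    ) -> "TwoReaderAgreement":
        """Build the model from a DataFrame with the standard schema columns."""
        return cls.from_records(
            frame_to_records(frame), readers=readers, platform=platform,
            catalog=catalog, dedup=dedup,
        )

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "TwoReaderAgreementResults":
        """Compute all paired agreement statistics."""
        a, b = self.records_a, self.records_b
        first, second = self.direction
        if first == self.reader_b:
            a, b = b, a

        def individual(recs: Sequence[AnnotationRecord]) -> dict[str, int]:
            dd = _dedup_reader_records(recs, self.dedup)
            out = {"not_evaluable": 0, "evaluable": 0}
            out.update(dict.fromkeys(DENSITY_BIN_NAMES, 0))
            for r in dd.values():
                if _usable_density(r):
                    out["evaluable"] += 1
                    out[assign_bin(r.density)] += 1
                elif not is_evaluable(r.roi_label):
                    out["not_evaluable"] += 1
            return out

        # after the swap above, collection a belongs to `first`, b to `second`
        cross = evaluability_cross_counts(a, b, self.dedup)
        averaged = averaged_bin_counts(a, b, self.dedup)
        rmsd_all, rmsd_bins = bin_rmsd(a, b, self.dedup)
        panels = bland_altman(a, b, self.dedup, direction=(first, second))
        co = _co_evaluable(_paired(a, b, self.dedup))
        diffs = np.array([xa - xb for _, xa, xb in co])
        return TwoReaderAgreementResults(
            reader_a=first,
            reader_b=second,
            individual_a=individual(a),
            individual_b=individual(b),
            cross_counts=cross,
            averaged_counts=averaged,
            rmsd_all=rmsd_all,
            rmsd_by_bin=rmsd_bins,
            mean_diff_all=float(diffs.mean()),
            panels=panels,
        )


@dataclass(frozen=True)
class TwoReaderAgreementResults:
    """Fitted two-reader agreement statistics.

    Differences are ``reader_a - reader_b`` (reader_a is the first element
    of the model's ``direction``).
    """

    reader_a: str
    reader_b: str
    individual_a: Mapping[str, int]
    individual_b: Mapping[str, int]
    cross_counts: CrossCounts
    averaged_counts: Mapping[str, int]
    rmsd_all: float
    rmsd_by_bin: Mapping[str, float | None]
    mean_diff_all: float
    panels: Mapping[str, BlandAltmanBin]

    # -- derived views -----------------------------------------------------

    @property
    def n_both_evaluable(self) -> int:
        return self.cross_counts.n_both_evaluable

    @property
    def n_both_not_evaluable(self) -> int:
        return self.cross_counts.n_both_not_evaluable

    @property
    def mean_diff_by_bin(self) -> dict[str, float | None]:
        return {b: p.mean_diff for b, p in self.panels.items()}

    @property
    def limits_by_bin(self) -> dict[str, tuple[float, float] | None]:
        return {
            b: (None if p.lower_limit is None else (p.lower_limit, p.upper_limit))
            for b, p in self.panels.items()
        }

    def table(self) -> pd.DataFrame:
        """The agreement table: individual, paired, averaged and RMSD rows
        across the not-evaluable / all / low / moderate / high columns."""
        cols = ["not_evaluable", "all_densities", *DENSITY_BIN_NAMES]

        def indiv_row(d: Mapping[str, int]) -> list:
            return [d["not_evaluable"], d["evaluable"], *(d[b] for b in DENSITY_BIN_NAMES)]

        cc = self.cross_counts
        rows = {
            f"reader {self.reader_a}": indiv_row(self.individual_a),
            f"reader {self.reader_b}": indiv_row(self.individual_b),
            "paired observations": [
                cc.n_both_not_evaluable,
                cc.n_both_evaluable,
                *(cc.paired_bin_counts[b] for b in DENSITY_BIN_NAMES),
            ],
            "averaged observations": [
                np.nan,
                cc.n_both_evaluable,
                *(self.averaged_counts[b] for b in DENSITY_BIN_NAMES),
            ],
            "RMSD": [
                np.nan,
                self.rmsd_all,
                *(
                    np.nan if self.rmsd_by_bin[b] is None else self.rmsd_by_bin[b]
                    for b in DENSITY_BIN_NAMES
                ),
            ],
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    def bland_altman_frame(self) -> pd.DataFrame:
        """All Bland-Altman points with their averaged-bin membership."""
        frames = []
        for name, p in self.panels.items():
            if len(p.points):
                f = p.points.copy()
                f.insert(0, "bin", name)
                frames.append(f)
        if not frames:
            return pd.DataFrame(columns=["bin", "roi_id", "mean", "diff"])
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Plain-text agreement report in the standard table layout."""
        lines = [
            f"Two-reader agreement: {self.reader_a} vs {self.reader_b}",
            f"(differences are {self.reader_a} - {self.reader_b})",
            "",
        ]
        tab = self.table()
        lines.append(tab.to_string(float_format=lambda v: f"{v:.2f}", na_rep="N/A"))
        lines.append("")
        lines.append("Bland-Altman (per averaged bin):")
        for name in DENSITY_BIN_NAMES:
            p = self.panels[name]
            if p.mean_diff is None:
                lines.append(f"  {name:>8}: no paired points")
            else:
                lines.append(
                    f"  {name:>8}: n={len(p.points):4d}  mbar={p.mean_diff:7.2f}  "
                    f"RMSD={p.rmsd:6.2f}  limits=[{p.lower_limit:.2f}, {p.upper_limit:.2f}]"
                )
        return "\n".join(lines)

    def plot(self, **kwargs):
        """Bland-Altman panel figure; see :func:`stilsagree.plots.plot_bland_altman`."""
        from .plots import plot_bland_altman

        return plot_bland_altman(self, **kwargs)
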