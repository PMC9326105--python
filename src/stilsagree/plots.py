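"""Figures for reader-variability and agreement reports.

Two figure families: variance / CV against mean density (scatter of per-ROI
summaries with equal-count binned averages overlaid, vertical lines at the
clinical bin edges) and per-bin Bland-Altman panels (differences against
means, bias line, limits of agreement).  All functions return the Figure so
callers can save or embed it; the CLI writes SVGs.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless report generation
import matplotlib.pyplot as plt
import numpy as np

from .agreement import (
    BinnedCurve,
    ROISummary,
    TwoReaderAgreementResults,
    binned_curve,
)
from .annotations import DENSITY_BINS, DENSITY_BIN_NAMES

__all__ = ["plot_variance_curves", "plot_bland_altman"]

_BIN_EDGES = [10.0, 40.0]


def _bin_guides(ax):
    for edge in _BIN_EDGES:
        ax.axvline(edge, color="0.6", linestyle="--", linewidth=0.8)


def plot_variance_curves(
    summaries: Sequence[ROISummary],
    curve: BinnedCurve | None = None,
    n_bins: int = 10,
):
    """Variance and CV of per-ROI estimates as functions of the mean.

    Left panel: per-ROI sample variance against mean with the equal-count
    binned mean-variance steps; right panel: the same for CV (zero-mean ROIs
    have no CV and are omitted).  Dashed vertical lines mark the low /
    moderate / high bin edges.
    """
    if curve is None:
        curve = binned_curve(summaries, n_bins=n_bins)
    fig, (ax_var, ax_cv) = plt.subplots(1, 2, figsize=(10, 4))
    means = np.array([s.mean for s in summaries])
    variances = np.array([s.sample_variance for s in summaries])
    ax_var.plot(means, variances, "o", ms=3, alpha=0.4, color="tab:blue")
    ax_var.plot(
        curve.table["mean_density"], curve.table["mean_variance"],
        drawstyle="steps-mid", color="black", lw=1.5, label="binned mean variance",
    )
    _bin_guides(ax_var)
    ax_var.set_xlabel("mean sTILs density (%)")
    ax_var.set_ylabel("sample variance")
    ax_var.legend(frameon=False, fontsize=8)

    with_cv = [(s.mean, s.cv) for s in summaries if s.cv is not None]
    if with_cv:
        m, c = zip(*with_cv)
        ax_cv.plot(m, c, "o", ms=3, alpha=0.4, color="tab:blue")
    ax_cv.plot(
        curve.table["mean_density"], curve.table["mean_cv"],
        drawstyle="steps-mid", color="black", lw=1.5, label="binned mean CV",
    )
    _bin_guides(ax_cv)
    ax_cv.set_xlabel("mean sTILs density (%)")
    ax_cv.set_ylabel("coefficient of variation")
    ax_cv.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_bland_altman(results: TwoReaderAgreementResults, max_marker: float = 200.0):
    """2x2 Bland-Altman panels: all densities plus one panel per bin.

    Marker area scales with the number of ROIs sharing a (mean, diff) point;
    the solid line is the bin bias m̄ and the dashed lines the limits of
    agreement m̄ ± 2·sqrt(RMSD² − m̄²).
    """
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey=True)
    panels = [("all densities", None)] + [(b, b) for b in DENSITY_BIN_NAMES]
    all_points = results.bland_altman_frame()
    for ax, (title, bin_name) in zip(axes.ravel(), panels):
        pts = all_points if bin_name is None else all_points[all_points["bin"] == bin_name]
        if len(pts):
            grouped = pts.groupby(["mean", "diff"]).size().reset_index(name="n")
            sizes = max_marker * grouped["n"] / grouped["n"].max()
            ax.scatter(grouped["mean"], grouped["diff"], s=sizes,
                       alpha=0.5, color="tab:blue", edgecolor="none")
        if bin_name is None:
            mbar = results.mean_diff_all
            rmsd = results.rmsd_all
            half = 2.0 * float(np.sqrt(max(rmsd**2 - mbar**2, 0.0)))
            lo, hi = mbar - half, mbar + half
        else:
            p = results.panels[bin_name]
            mbar, lo, hi = p.mean_diff, p.lower_limit, p.upper_limit
        if mbar is not None:
            ax.axhline(mbar, color="black", lw=1.2)
            ax.axhline(lo, color="tab:red", lw=1.0, linestyle="--")
            ax.axhline(hi, color="tab:red", lw=1.0, linestyle="--")
        ax.set_title(title, fontsize=10)
        ax.set_xlabel("mean of estimates (%)")
        ax.set_ylabel(f"difference ({results.reader_a} - {results.reader_b})")
    fig.tight_layout()
    return fig
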