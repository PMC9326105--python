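"""Seeded simulator of multi-reader sTILs annotation studies.

The generator reproduces the statistical structure observed in multi-reader
pilot data, so every pipeline stage can be exercised on data with known
truth:

* a study catalog of 64 cases x 10 ROIs grouped into 8 batches of 8 cases
  (640 ROIs), all configurable;
* a four-label ROI process in which ~73% of ROIs are truly evaluable and
  readers reproduce the catalog label with probability ``p_label_concord``;
* latent densities skewed low (defaults: 71% low / 21% moderate / 8% high,
  uniform within the bin);
* reader noise whose SD grows with the latent bin (defaults 3.27 / 10.08 /
  18.56, i.e. the per-bin two-reader RMSDs 4.62 / 14.25 / 26.25 divided by
  sqrt(2)), so per-ROI variance increases with the mean while the CV
  decreases; reported densities are clamped to [0, 100] and rounded to
  integers, as readers report whole percentages;
* lognormal annotation durations averaging ~30 s.

This is a calibrated stand-in for reader behaviour, not a cognitive model:
it has no training effects, no platform differences in noise, and no
within-case ROI correlation.  Identical configs (including seed) give
byte-identical output; the generator is NumPy's PCG64 via
``numpy.random.default_rng``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .annotations import (
    DENSITY_BINS,
    DENSITY_BIN_NAMES,
    EVALUABLE_LABELS,
    LABEL_VOCABULARY,
    NON_EVALUABLE_LABELS,
    AnnotationRecord,
    ROICatalogEntry,
    assign_bin,
    is_evaluable,
)

__all__ = [
    "SyntheticConfig",
    "LatentROI",
    "SimulatedStudy",
    "build_catalog",
    "sample_latents",
    "simulate_study",
]

_BIN_INTERVALS = {b.name: (b.lower, b.upper) for b in DENSITY_BINS}

#: Start of the simulated collection period for generated timestamps.
_EPOCH = datetime(2020, 2, 1, 9, 0, 0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study.

    Structural defaults follow the 640-ROI split-plot-style design (8 batches
    x 8 cases x 10 ROIs); distributional defaults are calibrated to observed
    multi-reader annotation data: bin weights from the averaged-observation
    distribution, per-bin noise SDs from the per-bin RMSD / sqrt(2), an
    evaluable-ROI fraction of 0.73, and lognormal durations with mean 30 s
    (log-SD 0.9 gives SD ~33.5 s).  All of it is configuration, not constants.

    ``sigma_linear`` switches the noise SD to a + b*mu (a smooth alternative
    to the piecewise-constant per-bin SDs).  ``reader_bias`` adds a fixed
    per-reader offset (one value per reader) before clamping, enabling
    nonzero Bland-Altman bias.  ``latent_ranges`` restricts the uniform
    latent draw within each bin, e.g. to interior sub-ranges away from the
    0/100 clamp boundaries.
    """

    n_cases: int = 64
    rois_per_case: int = 10
    n_batches: int = 8
    n_readers: int = 10
    bin_weights: tuple[float, float, float] = (0.71, 0.21, 0.08)
    sigma_by_bin: tuple[float, float, float] = (3.27, 10.08, 18.56)
    p_label_concord: float = 0.9
    p_roi_evaluable: float = 0.73
    duration_log_mean: float = math.log(30.0) - 0.9**2 / 2  # lognormal mean 30 s
    duration_log_sd: float = 0.9
    seed: int = 0
    platform: str = "PathPresenter"
    # evaluable-label and non-evaluable-label splits (observed label ratios)
    evaluable_label_weights: tuple[float, float] = (0.94, 0.06)
    non_evaluable_label_weights: tuple[float, float] = (0.36, 0.64)
    sigma_linear: tuple[float, float] | None = None
    reader_bias: tuple[float, ...] | None = None
    latent_ranges: Mapping[str, tuple[float, float]] | None = None

    def validate(self) -> None:
        if self.n_cases < 1 or self.rois_per_case < 1 or self.n_batches < 1:
            raise ValueError("study dimensions must be positive")
        if self.n_cases % self.n_batches != 0:
            raise ValueError(
                f"n_batches={self.n_batches} must divide n_cases={self.n_cases}"
            )
        if self.n_readers < 1:
            raise ValueError("n_readers must be >= 1")
        for p in (self.p_label_concord, self.p_roi_evaluable):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for w in (
            self.bin_weights,
            self.evaluable_label_weights,
            self.non_evaluable_label_weights,
        ):
            if any(x < 0 for x in w) or not math.isclose(sum(w), 1.0, abs_tol=1e-9):
                raise ValueError(f"weights {w} must be nonnegative and sum to 1")
        if any(s < 0 for s in self.sigma_by_bin):
            raise ValueError("noise SDs must be nonnegative")
        if self.reader_bias is not None and len(self.reader_bias) != self.n_readers:
            raise ValueError("reader_bias must supply one value per reader")
        if self.latent_ranges is not None:
            for name, (lo, hi) in self.latent_ranges.items():
                blo, bhi = _BIN_INTERVALS[name]
                if not (blo <= lo < hi <= bhi):
                    raise ValueError(
                        f"latent range {name}=({lo}, {hi}) outside bin ({blo}, {bhi}]"
                    )

    # -- config file round trip -------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        if data["latent_ranges"] is not None:
            data["latent_ranges"] = {k: list(v) for k, v in data["latent_ranges"].items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for key in ("bin_weights", "sigma_by_bin", "evaluable_label_weights",
                    "non_evaluable_label_weights", "sigma_linear", "reader_bias"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        if data.get("latent_ranges") is not None:
            data["latent_ranges"] = {
                k: tuple(v) for k, v in data["latent_ranges"].items()
            }
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class LatentROI:
    """The generative truth for one ROI: its catalog label and, when the ROI
    is truly evaluable, the latent density mu every reader estimates."""

    roi_id: str
    catalog_label: str
    true_density: float | None

    @property
    def evaluable(self) -> bool:
        return is_evaluable(self.catalog_label)

    @property
    def true_bin(self) -> str | None:
        return None if self.true_density is None else assign_bin(self.true_density)


@dataclass(frozen=True)
class SimulatedStudy:
    """One simulated study: records plus the latent truth and catalog."""

    config: SyntheticConfig
    catalog: list[ROICatalogEntry]
    latents: list[LatentROI]
    records: list[AnnotationRecord]

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(l.roi_id, l.catalog_label, l.true_density) for l in self.latents],
            columns=["roi_id", "catalog_label", "true_density"],
        )


def build_catalog(config: SyntheticConfig) -> list[ROICatalogEntry]:
    """The study design: cases assigned to batches in equal contiguous
    blocks, a fixed number of ROIs per case."""
    config.validate()
    cases_per_batch = config.n_cases // config.n_batches
    entries = []
    cw = len(str(config.n_cases))
    for c in range(config.n_cases):
        case_id = f"C{c + 1:0{cw}d}"
        batch_id = f"B{c // cases_per_batch + 1}"
        for r in range(config.rois_per_case):
            entries.append(
                ROICatalogEntry(
                    roi_id=f"{case_id}-ROI{r + 1:02d}",
                    case_id=case_id,
                    batch_id=batch_id,
                    ordinal_in_case=r + 1,
                )
            )
    return entries


def _latent_interval(config: SyntheticConfig, bin_name: str) -> tuple[float, float]:
    if config.latent_ranges is not None and bin_name in config.latent_ranges:
        return config.latent_ranges[bin_name]
    return _BIN_INTERVALS[bin_name]


def sample_latents(
    catalog: Sequence[ROICatalogEntry],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> list[LatentROI]:
    """Draw each ROI's true label and (for evaluable ROIs) latent density.

    An ROI is evaluable with probability ``p_roi_evaluable``; its label is
    then drawn within the evaluable (or non-evaluable) pair by the configured
    weights.  Evaluable ROIs draw a bin from ``bin_weights`` and mu uniform
    within that bin's (possibly restricted) interval.
    """
    latents = []
    for entry in catalog:
        if rng.random() < config.p_roi_evaluable:
            label = EVALUABLE_LABELS[
                int(rng.choice(2, p=config.evaluable_label_weights))
            ]
            bin_name = DENSITY_BIN_NAMES[int(rng.choice(3, p=config.bin_weights))]
            lo, hi = _latent_interval(config, bin_name)
            mu = float(rng.uniform(lo, hi))
        else:
            label = NON_EVALUABLE_LABELS[
                int(rng.choice(2, p=config.non_evaluable_label_weights))
            ]
            mu = None
        latents.append(LatentROI(entry.roi_id, label, mu))
    return latents


def _noise_sd(config: SyntheticConfig, mu: float) -> float:
    if config.sigma_linear is not None:
        a, b = config.sigma_linear
        return max(a + b * mu, 0.0)
    return config.sigma_by_bin[DENSITY_BIN_NAMES.index(assign_bin(mu))]


def simulate_study(config: SyntheticConfig) -> SimulatedStudy:
    """Generate a complete study: every reader annotates every ROI.

    Per reader x ROI: the reader reproduces the catalog label with
    probability ``p_label_concord`` and otherwise picks uniformly among the
    three other labels.  When the reader's label is evaluable and the ROI
    has a latent density, the reported density is
    ``round(clip(mu + bias_j + eps, 0, 100))`` with
    ``eps ~ Normal(0, sigma(mu))``; when the reader's label is evaluable but
    the ROI is truly non-evaluable (a label confusion), the density is drawn
    uniformly from the low bin.  Durations are lognormal; timestamps accrue
    per reader from a fixed epoch.  Identical configs (seed included) yield
    identical studies.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    catalog = build_catalog(config)
    latents = sample_latents(catalog, config, rng)
    latent_by_roi = {l.roi_id: l for l in latents}
    entry_by_roi = {e.roi_id: e for e in catalog}
    biases = config.reader_bias or (0.0,) * config.n_readers
    rw = len(str(config.n_readers))
    records = []
    for j in range(config.n_readers):
        reader_id = f"R{j + 1:0{rw}d}"
        clock = _EPOCH + timedelta(days=j)  # one reader-session per day
        for entry in catalog:
            latent = latent_by_roi[entry.roi_id]
            if rng.random() < config.p_label_concord:
                label = latent.catalog_label
            else:
                others = [l for l in LABEL_VOCABULARY if l != latent.catalog_label]
                label = others[int(rng.integers(len(others)))]
            density: float | None = None
            if is_evaluable(label):
                if latent.true_density is not None:
                    eps = rng.normal(0.0, _noise_sd(config, latent.true_density))
                    raw = latent.true_density + biases[j] + eps
                else:
                    # confusion case: reader sees stroma where the truth has
                    # none and reports a low-bin density
                    raw = rng.uniform(0.0, 10.0)
                density = float(round(min(max(raw, 0.0), 100.0)))
            duration = float(
                rng.lognormal(config.duration_log_mean, config.duration_log_sd)
            )
            clock += timedelta(seconds=duration)
            records.append(
                AnnotationRecord(
                    reader_id=reader_id,
                    platform=config.platform,
                    case_id=entry.case_id,
                    roi_id=entry.roi_id,
                    batch_id=entry.batch_id,
                    roi_label=label,
                    density=density,
                    percent_stroma=None,
                    duration_s=round(duration, 2),
                    timestamp=clock.isoformat(timespec="seconds"),
                )
            )
    return SimulatedStudy(config=config, catalog=catalog, latents=latents, records=records)
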