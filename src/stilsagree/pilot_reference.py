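"""Published tabulations of the public multi-reader sTILs pilot study.

The pilot study (raw annotations deposited at https://github.com/DIDSR/HTT)
collected 7373 sTILs density annotations of 640 breast-biopsy ROIs from 29
pathologists on three platforms: an optical microscope (eeDAP) and two
digital slide viewers (PathPresenter, caMicroscope).  These constants are
its published summary tables, carried here so that reports, consistency
checks and simulator calibration can reference them without re-deriving the
raw data.

Reader counts are platform-local (a pathologist using two platforms counts
once per platform), so the pooled reader count (37) exceeds the number of
distinct pathologists (29).
"""

from __future__ import annotations

__all__ = [
    "STUDY_N_ROIS",
    "BATCH_N_ROIS",
    "PILOT_TIMING",
    "PILOT_DISTRIBUTION",
    "PILOT_TWO_READER",
]

STUDY_N_ROIS = 640
BATCH_N_ROIS = 80

#: Per-platform annotation timing: reader count, observation count, mean and
#: sample SD of per-ROI annotation seconds, and the per-ROI hardware overhead
#: (microscope stage movement + slide registration; absent for digital
#: viewers).  The published projections follow from
#: (mean + overhead) * n_rois / 3600.
PILOT_TIMING: dict[str, dict] = {
    "eeDAP": {
        "readers": 7, "observations": 440,
        "mean_annotation_s": 27.41, "sd_annotation_s": 24.94,
        "hardware_overhead_s": 46.34,
        "batch_time_h": 1.64, "study_time_h": 13.11,
    },
    "PathPresenter": {
        "readers": 10, "observations": 1833,
        "mean_annotation_s": 29.98, "sd_annotation_s": 29.37,
        "hardware_overhead_s": 0.0,
        "batch_time_h": 0.67, "study_time_h": 5.33,
    },
    "caMicroscope": {
        "readers": 20, "observations": 5100,
        "mean_annotation_s": 39.06, "sd_annotation_s": 34.73,
        "hardware_overhead_s": 0.0,
        "batch_time_h": 0.87, "study_time_h": 6.94,
    },
    "All": {
        "readers": 37, "observations": 7373,
        "mean_annotation_s": 32.15, "sd_annotation_s": 35.52,
    },
}

#: Distribution of the 7373 annotations over the four ROI labels and, for
#: evaluable labels, over the three density bins.  Per platform the label
#: counts sum to the observation count and the bin counts to the evaluable
#: count.
PILOT_DISTRIBUTION: dict[str, dict[str, int]] = {
    "eeDAP": {
        "intratumoral stroma": 349, "invasive margin": 5,
        "tumor with no intervening stroma": 9, "other region": 77,
        "low": 323, "moderate": 21, "high": 10,
    },
    "PathPresenter": {
        "intratumoral stroma": 1326, "invasive margin": 91,
        "tumor with no intervening stroma": 288, "other region": 128,
        "low": 1127, "moderate": 211, "high": 79,
    },
    "caMicroscope": {
        "intratumoral stroma": 3917, "invasive margin": 270,
        "tumor with no intervening stroma": 210, "other region": 703,
        "low": 3042, "moderate": 912, "high": 233,
    },
    "All": {
        "intratumoral stroma": 5592, "invasive margin": 366,
        "tumor with no intervening stroma": 507, "other region": 908,
        "low": 4492, "moderate": 1144, "high": 322,
    },
}

#: Agreement analysis of the two pathologists (anonymized IDs 4776 and 0455)
#: who annotated all 640 ROIs on the PathPresenter platform: individual
#: not-evaluable / per-bin counts, paired observations (both readers agree on
#: evaluability or on the bin), averaged observations (binned by the mean of
#: the two estimates), and the RMSD overall and within each averaged bin.
PILOT_TWO_READER: dict[str, dict] = {
    "reader_4776": {"not_evaluable": 92, "all": 548, "low": 426, "moderate": 94, "high": 28},
    "reader_0455": {"not_evaluable": 189, "all": 451, "low": 344, "moderate": 68, "high": 39},
    "paired": {"not_evaluable": 89, "all": 448, "low": 313, "moderate": 44, "high": 24},
    "averaged": {"all": 448, "low": 319, "moderate": 93, "high": 36},
    "rmsd": {"all": 10.62, "low": 4.62, "moderate": 14.25, "high": 26.25},
}
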