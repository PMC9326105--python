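"""Agreement statistics: ROI summaries, curves, MSD/RMSD, pairing, Bland-Altman.

Expected values are either hand-computed or checked against independent
brute-force oracles (explicit pair enumeration for the MSD identity).
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stilsagree import (
    TwoReaderAgreement,
    averaged_bin_counts,
    bin_rmsd,
    binned_curve,
    bland_altman,
    complete_readers,
    evaluability_cross_counts,
    pairwise_msd,
    roi_summaries,
)
from stilsagree.agreement import DuplicateAnnotationError, NoPairedDataError
from conftest import make_record, two_reader_records


def records_for(estimates_by_roi):
    """One evaluable record per (roi, reader) from {roi: [estimates]}."""
    return [
        make_record(reader_id=f"R{j}", roi_id=roi, density=float(x))
        for roi, xs in estimates_by_roi.items()
        for j, x in enumerate(xs)
    ]


# -- per-ROI summaries -----------------------------------------------------


def test_summary_of_identical_estimates_has_zero_variance_and_cv():
    (s,) = roi_summaries(records_for({"A": [10, 10, 10]}))
    assert (s.n_readers, s.mean, s.sample_variance, s.cv) == (3, 10.0, 0.0, 0.0)


def test_summary_hand_computed_variance_and_cv():
    """Estimates {0, 10}: mean 5, sample variance (n-1 denominator) 50,
    CV = sqrt(50)/5 ~ 1.4142."""
    (s,) = roi_summaries(records_for({"A": [0, 10]}))
    assert s.mean == 5.0
    assert s.sample_variance == 50.0
    assert s.cv == pytest.approx(math.sqrt(2), abs=1e-9)


def test_single_estimate_rois_are_excluded_at_min_readers_two():
    summaries = roi_summaries(records_for({"A": [5], "B": [5, 7]}), min_readers=2)
    assert [s.roi_id for s in summaries] == ["B"]


def test_cv_is_absent_exactly_when_mean_is_zero():
    (s,) = roi_summaries(records_for({"A": [0, 0]}))
    assert s.mean == 0.0 and s.cv is None


# -- equal-count binning ---------------------------------------------------


def test_decile_partition_sizes_for_495_rois():
    """495 ROIs in 10 equal-count bins: five bins of 49 then five of 50."""
    summaries = roi_summaries(
        records_for({f"ROI{i:03d}": [i % 100, (i + 1) % 100] for i in range(495)})
    )
    curve = binned_curve(summaries, n_bins=10)
    assert curve.table["n_rois"].tolist() == [49] * 5 + [50] * 5
    assert curve.table["n_rois"].sum() == 495  # conservation


def test_one_roi_per_bin_reproduces_each_variance():
    summaries = roi_summaries(
        records_for({f"R{i}": [9.0 * i, 9.0 * i + i] for i in range(1, 11)})
    )
    curve = binned_curve(summaries, n_bins=10)
    expected = [s.sample_variance for s in sorted(summaries, key=lambda s: s.mean)]
    assert curve.table["mean_variance"].tolist() == pytest.approx(expected)
    assert curve.table["mean_density"].is_monotonic_increasing


def test_more_bins_than_summaries_is_an_error():
    summaries = roi_summaries(records_for({"A": [1, 2]}))
    with pytest.raises(ValueError):
        binned_curve(summaries, n_bins=2)


# -- pairwise MSD / RMSD ---------------------------------------------------


def brute_force_roi_msd(estimates):
    """Independent oracle: mean squared difference over explicit unordered
    reader pairs."""
    pairs = list(itertools.combinations(estimates, 2))
    return sum((a - b) ** 2 for a, b in pairs) / len(pairs)


def test_identical_readers_give_zero_msd():
    records = records_for({"A": [10, 10], "B": [55, 55, 55]})
    result = pairwise_msd(records)
    assert result.msd == 0.0 and result.rmsd == 0.0


def test_per_roi_msd_equals_brute_force_pair_enumeration():
    """MSD per ROI = 2 x sample variance; checked on 1,000 random small
    instances against the pair-enumeration oracle."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        n = int(rng.integers(2, 7))
        xs = rng.integers(0, 101, n).astype(float).tolist()
        result = pairwise_msd(records_for({"A": xs}))
        assert result.per_roi["A"] == pytest.approx(brute_force_roi_msd(xs), abs=1e-9)


def test_overall_msd_is_unweighted_mean_over_rois():
    by_roi = {"A": [0.0, 10.0], "B": [20.0, 26.0, 20.0]}
    result = pairwise_msd(records_for(by_roi))
    expected = np.mean([brute_force_roi_msd(v) for v in by_roi.values()])
    assert result.msd == pytest.approx(expected)
    assert result.rmsd == pytest.approx(math.sqrt(expected))
    assert result.n_rois == 2


def test_no_roi_with_two_estimates_signals_empty_result():
    with pytest.raises(NoPairedDataError):
        pairwise_msd(records_for({"A": [5]}))


# -- two-reader pairing ----------------------------------------------------


def test_all_not_evaluable_pairs_count_only_in_both_not_evaluable():
    a, b = two_reader_records([None] * 4, [None] * 4)
    cc = evaluability_cross_counts(a, b)
    assert cc.n_both_not_evaluable == 4
    assert cc.n_both_evaluable == 0
    assert all(v == 0 for v in cc.paired_bin_counts.values())


def test_discordant_evaluability_contributes_to_no_count():
    a, b = two_reader_records([5.0, None], [None, 7.0])
    cc = evaluability_cross_counts(a, b)
    assert cc.n_both_not_evaluable == 0 and cc.n_both_evaluable == 0


def test_paired_bins_lose_cross_bin_observations():
    # (9, 11) crosses low/moderate: co-evaluable but paired in no bin
    a, b = two_reader_records([9.0, 20.0], [11.0, 30.0])
    cc = evaluability_cross_counts(a, b)
    assert cc.n_both_evaluable == 2
    assert cc.paired_bin_counts == {"low": 0, "moderate": 1, "high": 0}


def test_averaged_bin_uses_mean_of_the_two_estimates():
    """Estimates 9% and 11% average to 10% and count in the low bin."""
    a, b = two_reader_records([9.0], [11.0])
    assert averaged_bin_counts(a, b) == {"low": 1, "moderate": 0, "high": 0}


def test_averaged_counts_sum_to_co_evaluable_count(two_reader_study):
    records = two_reader_study.records
    a = [r for r in records if r.reader_id == "R1"]
    b = [r for r in records if r.reader_id == "R2"]
    cc = evaluability_cross_counts(a, b)
    averaged = averaged_bin_counts(a, b)
    assert sum(averaged.values()) == cc.n_both_evaluable
    assert sum(cc.paired_bin_counts.values()) <= cc.n_both_evaluable


def test_duplicate_annotations_error_unless_latest_policy():
    a = [make_record("RA", timestamp="2020-01-01T00:00:00", density=5.0),
         make_record("RA", timestamp="2020-01-02T00:00:00", density=9.0)]
    b = [make_record("RB", density=5.0)]
    with pytest.raises(DuplicateAnnotationError):
        evaluability_cross_counts(a, b)
    counts = averaged_bin_counts(a, b, dedup="latest")  # keeps the 9.0 record
    assert counts["low"] == 1
    _, rmsd_bins = bin_rmsd(a, b, dedup="latest")
    assert rmsd_bins["low"] == pytest.approx(4.0)  # |9 - 5|


# -- per-bin RMSD ----------------------------------------------------------


def test_zero_differences_give_zero_rmsd_everywhere():
    a, b = two_reader_records([5.0, 20.0, 60.0], [5.0, 20.0, 60.0])
    rmsd_all, by_bin = bin_rmsd(a, b)
    assert rmsd_all == 0.0
    assert by_bin == {"low": 0.0, "moderate": 0.0, "high": 0.0}


def test_single_pair_rmsd_in_its_averaged_bin():
    """Estimates (0, 10) average to 5 (low); low RMSD = |0 - 10| = 10."""
    a, b = two_reader_records([0.0], [10.0])
    rmsd_all, by_bin = bin_rmsd(a, b)
    assert rmsd_all == pytest.approx(10.0)
    assert by_bin["low"] == pytest.approx(10.0)
    assert by_bin["moderate"] is None and by_bin["high"] is None


# -- Bland-Altman ----------------------------------------------------------


def test_constant_difference_collapses_the_limits():
    """All differences equal d: m-bar = d, RMSD = |d|, limits both = d."""
    a, b = two_reader_records([8.0, 6.0, 9.0], [5.0, 3.0, 6.0])
    panel = bland_altman(a, b)["low"]
    assert panel.mean_diff == pytest.approx(3.0)
    assert panel.rmsd == pytest.approx(3.0)
    assert panel.lower_limit == pytest.approx(3.0)
    assert panel.upper_limit == pytest.approx(3.0)


def test_symmetric_differences_hand_computed_limits():
    """Differences {-10, +10}: m-bar 0, RMSD 10, limits +-20."""
    a, b = two_reader_records([0.0, 10.0], [10.0, 0.0])
    panel = bland_altman(a, b)["low"]
    assert panel.mean_diff == pytest.approx(0.0)
    assert panel.rmsd == pytest.approx(10.0)
    assert (panel.lower_limit, panel.upper_limit) == pytest.approx((-20.0, 20.0))


def test_mixed_differences_hand_computed_limits():
    """Differences {0, 0, 6, -6}: m-bar 0, RMSD sqrt(18), limits +-2*sqrt(18)."""
    a, b = two_reader_records([5.0, 5.0, 9.0, 0.0], [5.0, 5.0, 3.0, 6.0])
    panel = bland_altman(a, b)["low"]
    assert panel.mean_diff == pytest.approx(0.0)
    assert panel.rmsd == pytest.approx(math.sqrt(18.0))
    assert panel.upper_limit == pytest.approx(2 * math.sqrt(18.0))
    assert panel.lower_limit == pytest.approx(-2 * math.sqrt(18.0))


def test_difference_direction_defaults_to_lexicographic_and_is_overridable():
    a, b = two_reader_records([9.0], [5.0])
    assert bland_altman(a, b)["low"].mean_diff == pytest.approx(4.0)  # RA - RB
    flipped = bland_altman(a, b, direction=("RB", "RA"))["low"]
    assert flipped.mean_diff == pytest.approx(-4.0)


@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=100),
            st.integers(min_value=0, max_value=100),
        ),
        min_size=1,
        max_size=30,
    )
)
def test_rmsd_dominates_absolute_mean_difference(pairs):
    """RMSD >= |m-bar| on any two-reader dataset (Jensen), per bin and overall."""
    a, b = two_reader_records([float(x) for x, _ in pairs], [float(y) for _, y in pairs])
    rmsd_all, _ = bin_rmsd(a, b)
    diffs = [float(x - y) for x, y in pairs]
    assert rmsd_all >= abs(sum(diffs) / len(diffs)) - 1e-9
    for panel in bland_altman(a, b).values():
        if panel.mean_diff is not None:
            assert panel.rmsd >= abs(panel.mean_diff) - 1e-9
            assert panel.lower_limit <= panel.mean_diff <= panel.upper_limit


@given(
    st.lists(
        st.tuples(
            st.one_of(st.none(), st.integers(min_value=0, max_value=100)),
            st.one_of(st.none(), st.integers(min_value=0, max_value=100)),
        ),
        min_size=1,
        max_size=25,
    )
)
def test_swapping_readers_negates_differences_and_preserves_counts(pairs):
    """Reader swap: every m-bar flips sign; RMSD and all counts unchanged."""
    va = [None if x is None else float(x) for x, _ in pairs]
    vb = [None if y is None else float(y) for _, y in pairs]
    a, b = two_reader_records(va, vb)
    cc_ab, cc_ba = evaluability_cross_counts(a, b), evaluability_cross_counts(b, a)
    assert cc_ab == cc_ba
    assert averaged_bin_counts(a, b) == averaged_bin_counts(b, a)
    if cc_ab.n_both_evaluable:
        rmsd_ab, bins_ab = bin_rmsd(a, b)
        rmsd_ba, bins_ba = bin_rmsd(b, a)
        assert rmsd_ab == pytest.approx(rmsd_ba)
        for name in bins_ab:
            if bins_ab[name] is not None:
                assert bins_ab[name] == pytest.approx(bins_ba[name])
        # fixing direction to (RB, RA) negates every difference vs (RA, RB)
        pa = bland_altman(a, b, direction=("RA", "RB"))
        pb = bland_altman(a, b, direction=("RB", "RA"))
        for name in pa:
            if pa[name].mean_diff is not None:
                assert pb[name].mean_diff == pytest.approx(-pa[name].mean_diff)


# -- model / results objects -----------------------------------------------


def test_complete_reader_auto_selection(two_reader_study):
    readers = complete_readers(two_reader_study.records, two_reader_study.catalog)
    assert readers == ["R1", "R2"]


def test_auto_selection_rejects_incomplete_readers(two_reader_study):
    records = [r for r in two_reader_study.records
               if not (r.reader_id == "R2" and r.roi_id.startswith("C01-"))]
    with pytest.raises(ValueError, match="1 candidate"):
        TwoReaderAgreement.from_records(records, catalog=two_reader_study.catalog)


def test_results_table_is_internally_consistent(two_reader_study):
    res = TwoReaderAgreement.from_records(
        two_reader_study.records, catalog=two_reader_study.catalog
    ).fit()
    tab = res.table()
    assert tab.loc["averaged observations", "all_densities"] == res.n_both_evaluable
    assert (
        tab.loc["averaged observations", ["low", "moderate", "high"]].sum()
        == res.n_both_evaluable
    )
    assert (
        tab.loc["paired observations", ["low", "moderate", "high"]].sum()
        <= res.n_both_evaluable
    )
    # the summary renders without error and names both readers
    text = res.summary()
    assert "R1" in text and "R2" in text
    assert len(res.bland_altman_frame()) == res.n_both_evaluable


def test_model_from_dataframe_matches_from_records(two_reader_study):
    from stilsagree import records_to_frame

    frame = records_to_frame(two_reader_study.records)
    res_df = TwoReaderAgreement.from_dataframe(frame, readers=("R1", "R2")).fit()
    res_rec = TwoReaderAgreement.from_records(
        two_reader_study.records, readers=("R1", "R2")
    ).fit()
    assert res_df.rmsd_all == pytest.approx(res_rec.rmsd_all)
    assert res_df.averaged_counts == res_rec.averaged_counts
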