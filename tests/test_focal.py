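"""Focal aberrations: extraction, germline filters, HFRs, and the filter ledger."""

import numpy as np
import pandas as pd
import pytest

from focalcna import focal

from conftest import make_calls


# ---------------------------------------------------------------------------
# extraction and the focal size rule
# ---------------------------------------------------------------------------

def test_adjacent_same_state_segments_merge_into_one_focal_aberration():
    calls = make_calls([
        ("s1", "chr1", 0, 1_000_000, "gain"),
        ("s1", "chr1", 1_000_000, 2_500_000, "gain"),
        ("s1", "chr1", 2_500_000, 9_000_000, "neutral"),
    ])
    abs_ = focal.extract_aberrations(calls)
    assert len(abs_) == 1
    a = abs_[0]
    assert (a.start_bp, a.end_bp, a.direction, a.focal) == \
        (0, 2_500_000, "gain", True)


def test_direction_change_starts_a_new_aberration():
    calls = make_calls([
        ("s1", "chr1", 0, 1_000_000, "gain"),
        ("s1", "chr1", 1_000_000, 2_000_000, "loss"),
    ])
    abs_ = focal.extract_aberrations(calls)
    assert [(a.direction, a.start_bp) for a in abs_] == \
        [("gain", 0), ("loss", 1_000_000)]


def test_focal_size_limit_is_inclusive_at_three_megabases():
    calls = make_calls([
        ("s1", "chr1", 0, 3_000_000, "loss"),
        ("s2", "chr1", 0, 3_000_001, "loss"),
    ])
    by_sample = {a.sample_id: a for a in focal.extract_aberrations(calls)}
    assert by_sample["s1"].focal is True
    assert by_sample["s2"].focal is False


def test_extraction_is_invariant_to_segment_row_order():
    rows = [
        ("s1", "chr1", 2_000_000, 3_000_000, "gain"),
        ("s1", "chr1", 0, 1_000_000, "gain"),
        ("s1", "chr1", 1_000_000, 2_000_000, "gain"),
    ]
    a1 = focal.extract_aberrations(make_calls(rows))
    a2 = focal.extract_aberrations(make_calls(rows[::-1]))
    assert a1 == a2
    assert a1[0].size_bp == 3_000_000


# ---------------------------------------------------------------------------
# germline filter 1: catalog coverage
# ---------------------------------------------------------------------------

def make_ab(sample, start, end, direction="loss", chrom="chr1"):
    return focal.Aberration(
        sample, chrom, start, end, direction, (end - start) <= 3_000_000
    )


def catalog(*ivals, chrom="chr1"):
    return pd.DataFrame(
        [(chrom, s, e) for s, e in ivals], columns=["chrom", "start", "end"]
    )


def test_low_catalog_coverage_keeps_the_aberration():
    a = make_ab("s1", 0, 1_000_000)
    kept, removed = focal.filter_catalog_overlap([a], catalog((0, 100_000)))
    assert kept == [a] and removed == []


def test_majority_catalog_coverage_removes_the_aberration():
    a = make_ab("s1", 0, 1_000_000)
    kept, removed = focal.filter_catalog_overlap([a], catalog((0, 600_000)))
    assert kept == [] and removed == [a]


def test_catalog_coverage_threshold_is_inclusive_at_half():
    a = make_ab("s1", 0, 1_000_000)
    kept, removed = focal.filter_catalog_overlap([a], catalog((0, 500_000)))
    assert removed == [a]


def test_overlapping_catalog_entries_are_counted_once():
    # two catalog intervals overlap; union covers 0.4 < 0.5 -> keep
    a = make_ab("s1", 0, 1_000_000)
    kept, removed = focal.filter_catalog_overlap(
        [a], catalog((0, 300_000), (200_000, 400_000))
    )
    assert kept == [a]


def test_broad_aberrations_bypass_the_catalog_filter():
    a = make_ab("s1", 0, 10_000_000)  # non-focal
    kept, removed = focal.filter_catalog_overlap(
        [a], catalog((0, 10_000_000))
    )
    assert kept == [a] and removed == []


# ---------------------------------------------------------------------------
# germline filter 2: bidirectional loci
# ---------------------------------------------------------------------------

def test_locus_with_recurrent_gains_and_losses_is_removed():
    cluster = [
        make_ab("s1", 0, 500_000, "gain"),
        make_ab("s2", 100_000, 600_000, "gain"),
        make_ab("s3", 0, 400_000, "loss"),
        make_ab("s4", 200_000, 500_000, "loss"),
    ]
    kept, removed = focal.filter_bidirectional(cluster)
    assert kept == [] and len(removed) == 4


def test_single_discordant_sample_does_not_trigger_removal():
    cluster = [
        make_ab("s1", 0, 500_000, "gain"),
        make_ab("s2", 100_000, 600_000, "gain"),
        make_ab("s3", 0, 400_000, "loss"),
    ]
    kept, removed = focal.filter_bidirectional(cluster)
    assert len(kept) == 3 and removed == []


def test_unidirectional_recurrence_is_preserved():
    cluster = [make_ab(f"s{i}", 0, 500_000, "loss") for i in range(3)]
    kept, removed = focal.filter_bidirectional(cluster)
    assert len(kept) == 3 and removed == []


def test_same_sample_gain_and_loss_count_once_per_direction():
    # both directions recurrent requires >= 2 distinct samples per direction
    cluster = [
        make_ab("s1", 0, 500_000, "gain"),
        make_ab("s1", 0, 500_000, "loss"),
        make_ab("s2", 0, 500_000, "gain"),
        make_ab("s2", 0, 500_000, "loss"),
    ]
    kept, removed = focal.filter_bidirectional(cluster)
    assert len(removed) == 4


# ---------------------------------------------------------------------------
# high-frequency regions
# ---------------------------------------------------------------------------

def test_nested_aberrations_yield_the_inner_interval():
    abs_ = [make_ab("s1", 100, 400), make_ab("s2", 200, 300)]
    (h,) = focal.compute_hfrs(abs_)
    assert (h.start_bp, h.end_bp, h.focal_count) == (200, 300, 2)


def test_chained_overlaps_take_leftmost_maximal_depth_run():
    abs_ = [make_ab("s1", 0, 10), make_ab("s2", 5, 15), make_ab("s3", 10, 20)]
    (h,) = focal.compute_hfrs(abs_)
    # depth 2 on [5,10) (s1,s2) and on [10,15) (s2,s3): one contiguous run
    assert (h.start_bp, h.end_bp, h.focal_count) == (5, 15, 2)


def test_single_sample_cluster_yields_no_hfr():
    assert focal.compute_hfrs([make_ab("s1", 0, 100)]) == []


def test_duplicate_intervals_from_one_sample_count_once():
    abs_ = [make_ab("s1", 0, 100), make_ab("s1", 0, 100), make_ab("s2", 0, 100)]
    (h,) = focal.compute_hfrs(abs_)
    assert h.focal_count == 2


def test_directions_form_separate_hfrs():
    abs_ = [
        make_ab("s1", 0, 100, "gain"), make_ab("s2", 0, 100, "gain"),
        make_ab("s3", 50, 150, "loss"), make_ab("s4", 50, 150, "loss"),
    ]
    hfrs = focal.compute_hfrs(abs_)
    assert sorted(h.direction for h in hfrs) == ["gain", "loss"]


def test_hfr_computation_is_invariant_to_input_order():
    abs_ = [make_ab(f"s{i}", 100 * i, 100 * i + 350) for i in range(5)]
    h1 = focal.compute_hfrs(abs_)
    h2 = focal.compute_hfrs(abs_[::-1])
    assert [(h.start_bp, h.end_bp, h.focal_count) for h in h1] == \
        [(h.start_bp, h.end_bp, h.focal_count) for h in h2]


def brute_force_depth_run(members):
    """Per-base oracle for the leftmost maximal run at maximum sample depth."""
    lo = min(a.start_bp for a in members)
    hi = max(a.end_bp for a in members)
    depth = np.zeros(hi - lo, dtype=int)
    for sample in {a.sample_id for a in members}:
        cov = np.zeros(hi - lo, dtype=bool)
        for a in members:
            if a.sample_id == sample:
                cov[a.start_bp - lo:a.end_bp - lo] = True
        depth += cov
    dmax = depth.max()
    at_max = np.flatnonzero(depth == dmax)
    start = at_max[0]
    end = start
    while end < depth.size and depth[end] == dmax:
        end += 1
    return lo + int(start), lo + int(end), int(dmax)


@pytest.mark.parametrize("seed", range(8))
def test_hfr_interval_matches_per_base_depth_oracle(seed):
    rng = np.random.default_rng(400 + seed)
    members = []
    for i in range(int(rng.integers(3, 21))):
        s = int(rng.integers(0, 900))
        e = s + int(rng.integers(1, 100))
        members.append(make_ab(f"s{rng.integers(0, 8)}", s, e))
    hfrs = focal.compute_hfrs(members, recurrence_min=1)
    # clusters partition members; check each HFR against the oracle run
    for h in hfrs:
        got = (h.start_bp, h.end_bp, h.focal_count)
        assert got == brute_force_depth_run(h.member_aberrations)


def test_total_count_requires_full_same_direction_containment():
    h = focal.HFR("chr1", 100, 200, "loss", focal_count=2)
    all_abs = [
        make_ab("s1", 100, 200),            # exact: counts
        make_ab("s2", 0, 3_500_000),        # broad container: counts
        make_ab("s3", 150, 400),            # partial overlap: no
        make_ab("s4", 100, 200, "gain"),    # wrong direction: no
        make_ab("s2", 50, 250),             # s2 again: still one sample
    ]
    focal.count_total(h, all_abs)
    assert h.total_count == 2


# ---------------------------------------------------------------------------
# filter ledger
# ---------------------------------------------------------------------------

def test_ledger_identity_observed_minus_removals_equals_retained():
    led = focal.make_ledger((550, 266, 145))
    assert led.n_retained == 139


def test_inconsistent_ledger_counts_are_rejected():
    with pytest.raises(ValueError):
        focal.FilterLedger(5, 3, 3, -1)
    with pytest.raises(ValueError):
        focal.FilterLedger(10, 2, 3, 4)  # 10 - 2 - 3 != 4


def test_run_focal_stage_ledger_is_internally_consistent():
    calls = make_calls([
        # recurrent loss locus (kept)
        ("s1", "chr1", 0, 1_000_000, "loss"),
        ("s2", "chr1", 0, 1_000_000, "loss"),
        ("s1", "chr1", 1_000_000, 9_000_000, "neutral"),
        ("s2", "chr1", 1_000_000, 9_000_000, "neutral"),
        # recurrent locus fully inside the catalog (removed by filter 1)
        ("s1", "chr2", 0, 500_000, "gain"),
        ("s2", "chr2", 0, 500_000, "gain"),
        ("s1", "chr2", 500_000, 9_000_000, "neutral"),
        ("s2", "chr2", 500_000, 9_000_000, "neutral"),
    ])
    cat = catalog((0, 500_000), chrom="chr2")
    out = focal.run_focal_stage(calls, cat)
    led = out["ledger"]
    assert (led.n_recurrent_observed, led.n_removed_catalog,
            led.n_removed_bidirectional, led.n_retained) == (4, 2, 0, 2)
    assert len(out["hfrs"]) == 1
    assert out["hfrs"][0].direction == "loss"


def test_hfr_table_one_based_display_coordinates():
    h = focal.HFR("chr5", 99, 200, "gain", focal_count=3, total_count=5,
                  genes=["ABC1"])
    frame0 = focal.hfrs_to_frame([h])
    frame1 = focal.hfrs_to_frame([h], one_based=True)
    assert (frame0.loc[0, "Start"], frame0.loc[0, "End"]) == (99, 200)
    assert (frame1.loc[0, "Start"], frame1.loc[0, "End"]) == (100, 200)
    assert frame0.loc[0, "Focal_gain"] == 3
    assert frame0.loc[0, "Total_gain"] == 5
    assert frame0.loc[0, "Genes"] == "ABC1"
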