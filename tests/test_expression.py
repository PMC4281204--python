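"""Expression normalization, fold changes, flags, candidates, validation."""

import numpy as np
import pandas as pd
import pytest

from focalcna import expression as xp


def fc_table(data, columns=None):
    df = pd.DataFrame(data) if columns is None else pd.DataFrame(data, columns=columns)
    return xp.FoldChangeTable(values=df)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def test_quantile_normalization_equalizes_sorted_columns():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.normal(size=(200, 5)))
    out = xp.quantile_normalize(df)
    sorted_cols = np.sort(out.to_numpy(), axis=0)
    for j in range(1, 5):
        assert np.allclose(sorted_cols[:, j], sorted_cols[:, 0])


def test_quantile_normalization_preserves_within_sample_ranks():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.normal(size=(50, 3)))
    out = xp.quantile_normalize(df)
    for col in df:
        assert (df[col].rank() == out[col].rank()).all()


def test_quantile_normalization_is_idempotent():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(rng.normal(size=(80, 4)))
    once = xp.quantile_normalize(df)
    assert np.allclose(xp.quantile_normalize(once), once)


# ---------------------------------------------------------------------------
# LOESS detrending
# ---------------------------------------------------------------------------

def test_trend_free_data_stays_near_zero_log2ratio():
    rng = np.random.default_rng(6)
    mu = rng.normal(8, 1.5, 300)
    tum = pd.DataFrame(
        2.0 ** (mu[:, None] + rng.normal(0, 0.05, (300, 4))),
        index=[f"g{i}" for i in range(300)], columns=list("ABCD"),
    )
    ref = pd.DataFrame(
        2.0 ** (mu[:, None] + rng.normal(0, 0.05, (300, 3))),
        index=tum.index, columns=["R1", "R2", "R3"],
    )
    norm = xp.normalize_expression(tum, ref)
    assert abs(norm.to_numpy().mean()) < 0.02


def test_intensity_dependent_trend_is_removed():
    rng = np.random.default_rng(7)
    mu = rng.uniform(4, 12, 400)
    trend = 0.1 * (mu - 8.0)  # log2ratio rises with intensity
    tum = pd.DataFrame(
        2.0 ** (mu[:, None] + trend[:, None] + rng.normal(0, 0.05, (400, 3))),
        index=[f"g{i}" for i in range(400)], columns=list("ABC"),
    )
    ref = pd.DataFrame(
        2.0 ** (mu[:, None] + rng.normal(0, 0.05, (400, 2))),
        index=tum.index, columns=["R1", "R2"],
    )
    norm = xp.normalize_expression(tum, ref)
    a = mu  # average intensity proxy
    m = norm.mean(axis=1).to_numpy()
    slope = np.polyfit(a, m, 1)[0]
    assert abs(slope) < 0.01


def test_normalization_rejects_non_positive_intensities():
    tum = pd.DataFrame(np.ones((20, 2)), index=[f"g{i}" for i in range(20)])
    tum.iloc[3, 0] = -1.0
    ref = pd.DataFrame(np.ones((20, 1)), index=tum.index)
    with pytest.raises(ValueError, match="non-positive"):
        xp.normalize_expression(tum, ref)


def test_normalization_requires_shared_genes():
    tum = pd.DataFrame(np.ones((20, 2)), index=[f"g{i}" for i in range(20)])
    ref = pd.DataFrame(np.ones((20, 1)), index=[f"h{i}" for i in range(20)])
    with pytest.raises(ValueError, match="shared"):
        xp.normalize_expression(tum, ref)


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

def test_fold_change_is_tumor_over_mean_reference():
    tum = pd.DataFrame({"T1": [4.0], "T2": [1.0]}, index=["g1"])
    ref = pd.DataFrame({"R1": [1.0], "R2": [3.0]}, index=["g1"])  # mean 2.0
    fc = xp.compute_fold_changes(tum, ref)
    assert fc.values.loc["g1", "T1"] == pytest.approx(2.0)
    assert fc.values.loc["g1", "T2"] == pytest.approx(0.5)


def test_fold_change_from_log2_is_two_to_the_m():
    norm = pd.DataFrame({"T1": [1.0, -1.0]}, index=["g1", "g2"])
    fc = xp.fold_changes_from_log2(norm)
    assert list(fc.values["T1"]) == pytest.approx([2.0, 0.5])


def test_multi_probe_genes_collapse_to_highest_mean_intensity_probe():
    tum = pd.DataFrame({"T1": [10.0, 100.0], "T2": [10.0, 100.0]},
                       index=["probeA", "probeB"])
    ref = pd.DataFrame({"R1": [5.0, 25.0]}, index=["probeA", "probeB"])
    pm = pd.DataFrame({"probe": ["probeA", "probeB"], "gene": ["G", "G"]})
    fc = xp.compute_fold_changes(tum, ref, probe_map=pm)
    # probeB is brighter, so G's fold change comes from probeB: 100/25
    assert fc.values.loc["G", "T1"] == pytest.approx(4.0)


def test_requested_genes_without_probe_are_reported_not_dropped():
    tum = pd.DataFrame({"T1": [4.0]}, index=["g1"])
    ref = pd.DataFrame({"R1": [2.0]}, index=["g1"])
    fc = xp.compute_fold_changes(tum, ref, genes=["g1", "g2", "g3"])
    assert fc.no_information == ["g2", "g3"]
    assert list(fc.values.index) == ["g1"]


# ---------------------------------------------------------------------------
# flagging thresholds
# ---------------------------------------------------------------------------

def test_loss_flag_boundary_is_inclusive_at_three_quarters():
    fc = fc_table({"T1": [0.75], "T2": [0.76], "T3": [0.74]}, )
    fc.values.index = ["g"]
    flags = xp.flag_aberrant_expression(fc, {"g": "loss"})
    assert list(flags.loc["g"]) == [True, False, True]


def test_gain_flag_boundary_is_inclusive_at_three_halves():
    fc = fc_table({"T1": [1.5], "T2": [1.49], "T3": [1.51]})
    fc.values.index = ["g"]
    flags = xp.flag_aberrant_expression(fc, {"g": "gain"})
    assert list(flags.loc["g"]) == [True, False, True]


def test_strict_mode_excludes_the_boundary():
    fc = fc_table({"T1": [0.75], "T2": [1.5]})
    fc.values.index = ["g"]
    strict = xp.Thresholds(strict_fc=True)
    loss = xp.flag_aberrant_expression(fc, {"g": "loss"}, strict)
    gain = xp.flag_aberrant_expression(fc, {"g": "gain"}, strict)
    assert not loss.loc["g", "T1"] and not gain.loc["g", "T2"]


def test_flags_are_direction_specific():
    fc = fc_table({"T1": [0.5, 0.5], "T2": [2.0, 2.0]})
    fc.values.index = ["lossy", "gainy"]
    flags = xp.flag_aberrant_expression(fc, {"lossy": "loss", "gainy": "gain"})
    assert list(flags.loc["lossy"]) == [True, False]
    assert list(flags.loc["gainy"]) == [False, True]


def test_gene_without_direction_raises():
    fc = fc_table({"T1": [0.5]})
    fc.values.index = ["g"]
    with pytest.raises(ValueError):
        xp.flag_aberrant_expression(fc, {})


# ---------------------------------------------------------------------------
# candidate selection and validation
# ---------------------------------------------------------------------------

def flags_with_counts(counts, n_samples):
    """One gene per entry; gene g_i flagged in counts[i] of n_samples tumors."""
    data = {
        f"T{j}": [j < c for c in counts] for j in range(n_samples)
    }
    df = pd.DataFrame(data, index=[f"g{i}" for i in range(len(counts))])
    return df


def test_candidate_frequency_boundary_seven_of_twenty_is_35_percent():
    flags = flags_with_counts([7, 6], 20)
    directions = {"g0": "loss", "g1": "loss"}
    cands = xp.select_candidates(flags, xp.Thresholds(), 20, directions)
    assert [c.gene for c in cands] == ["g0"]
    assert cands[0].freq_discovery == pytest.approx(0.35)


def test_eleven_of_thirtyone_selected_ten_not():
    flags = flags_with_counts([11, 10], 31)
    directions = {"g0": "gain", "g1": "gain"}
    cands = xp.select_candidates(flags, xp.Thresholds(), 31, directions)
    # 11/31 = 35.5% >= 35%; 10/31 = 32.3% < 35%
    assert [c.gene for c in cands] == ["g0"]


def test_selection_is_monotone_in_flag_counts():
    thresholds = xp.Thresholds()
    directions = {f"g{i}": "loss" for i in range(21)}
    flags = flags_with_counts(list(range(21)), 20)
    selected = {c.gene for c in
                xp.select_candidates(flags, thresholds, 20, directions)}
    cut = min(int(g[1:]) for g in selected)
    assert selected == {f"g{i}" for i in range(cut, 21)}


def test_validation_assigns_all_three_statuses():
    cands = [
        xp.CandidateDriver("confirmed_gene", "loss", 0.5),
        xp.CandidateDriver("weak_gene", "loss", 0.5),
        xp.CandidateDriver("absent_gene", "loss", 0.5),
    ]
    vals = pd.DataFrame(
        {f"T{j}": [0.5 if j < 5 else 1.0, 0.5 if j < 2 else 1.0]
         for j in range(10)},
        index=["confirmed_gene", "weak_gene"],
    )
    vfc = xp.FoldChangeTable(values=vals, no_information=["absent_gene"])
    out = xp.validate_candidates(cands, vfc)
    statuses = {c.gene: c.status for c in out}
    assert statuses == {
        "confirmed_gene": "confirmed",       # 5/10 = 50% >= 35%
        "weak_gene": "not_confirmed",        # 2/10 = 20%
        "absent_gene": "no_information",
    }
    freqs = {c.gene: c.freq_validation for c in out}
    assert freqs["confirmed_gene"] == pytest.approx(0.5)
    assert freqs["absent_gene"] is None


def test_validation_does_not_mutate_input_candidates():
    cand = xp.CandidateDriver("g", "loss", 0.4)
    vfc = xp.FoldChangeTable(values=pd.DataFrame(index=["x"]),
                             no_information=["g"])
    xp.validate_candidates([cand], vfc)
    assert cand.status == "candidate"


def test_thresholds_reject_nonsense_values():
    with pytest.raises(ValueError):
        xp.Thresholds(fc_under=1.2)
    with pytest.raises(ValueError):
        xp.Thresholds(freq_min=0.0)
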