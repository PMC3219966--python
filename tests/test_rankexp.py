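"""Rank-expectation statistic, voting, DDE merging and classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromdyn import Genome
from chromdyn.density import DensityTrack, STAGES
from chromdyn.rankexp import (
    ORDERED_PAIRS,
    bh_significant,
    classify_temporal,
    cluster_profiles,
    consistent_enrichment,
    merge_dde_bins,
    rank_expectation,
    tabulate_classes,
)


def brute_rank_expectation(a, b, window):
    """Independent re-implementation: explicit per-position median/MAD."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    mask = ~((a == 0) & (b == 0))
    ai, bi = a[mask], b[mask]
    order = np.argsort(bi, kind="stable")
    ap = ai[order]
    n = len(ap)
    h = window // 2
    p = np.empty(n)
    for i in range(n):
        w = ap[max(0, i - h): i + h + 1]
        m = np.median(w)
        s = 1.4826 * np.median(np.abs(w - m))
        z = (ap[i] - m) / s if s > 0 else 0.0
        p[i] = stats.norm.sf(z)
    tmp = np.empty(n)
    tmp[order] = p
    out = np.full(len(a), np.nan)
    out[mask] = tmp
    return out


def test_matches_brute_force_on_poisson_data():
    rng = np.random.default_rng(0)
    b = rng.poisson(7.0, size=600).astype(float)
    a = b + rng.poisson(2.0, size=600)
    a[300] = b[300] * 10 + 50  # one strongly enriched bin
    got = rank_expectation(a, b, local_window=101)
    want = brute_rank_expectation(a, b, 101)
    assert np.allclose(got, want, atol=1e-9, equal_nan=True)
    assert np.nanargmin(got) == 300


def test_null_self_comparison_flags_little():
    rng = np.random.default_rng(1)
    x = rng.poisson(7.0, size=5000).astype(float)
    y = rng.poisson(7.0, size=5000).astype(float)
    p = rank_expectation(x, y, local_window=501)
    sig = bh_significant(p, 0.05)
    assert sig.mean() <= 0.05


def test_constant_signals_give_half_p_values():
    a = np.full(300, 4.0)
    p = rank_expectation(a, a, local_window=101)
    assert np.allclose(p, 0.5)


def test_input_validation():
    with pytest.raises(ValueError):
        rank_expectation(np.ones(10), np.ones(11), local_window=101)
    with pytest.raises(ValueError):
        rank_expectation(np.ones(300), np.ones(300), local_window=100)
    with pytest.raises(ValueError):
        rank_expectation(np.ones(300), np.ones(300), local_window=51)


def test_enrichment_never_flagged_in_both_polarities():
    rng = np.random.default_rng(2)
    b = rng.poisson(6.0, size=4000).astype(float)
    a = rng.poisson(6.0, size=4000).astype(float)
    a[1000:1010] += 40
    b[3000:3010] += 40
    p_ab = rank_expectation(a, b, local_window=501)
    p_ba = rank_expectation(b, a, local_window=501)
    both = bh_significant(p_ab, 0.05) & bh_significant(p_ba, 0.05)
    assert not both.any()


def test_consistent_enrichment_votes():
    n = 10
    lo = np.full(n, 1e-12)
    hi = np.full(n, 0.9)
    def sets(k):
        return [lo if i < k else hi for i in range(4)]
    assert consistent_enrichment(sets(3), 0.05).all()
    assert consistent_enrichment(sets(4), 0.05).all()
    assert not consistent_enrichment(sets(2), 0.05).any()
    with pytest.raises(ValueError):
        consistent_enrichment(sets(3)[:3], 0.05)


# ---------------------------------------------------------------------------
# DDE merging and classification
# ---------------------------------------------------------------------------

def _tracks_with_flags(n_bins, flag_spec):
    """Build minimal replicate tracks plus a full flags dict.

    ``flag_spec`` maps ordered stage pair -> list of flagged bin indices.
    """
    genome = Genome({"chr": n_bins * 20})
    values = np.ones(n_bins)
    tracks = {
        s: [DensityTrack(genome=genome, bin_size=20, window=150,
                         values={"chr": values * (1 + i)}) for i in range(2)]
        for s in STAGES
    }
    flags = {}
    for pair in ORDERED_PAIRS:
        arr = np.zeros(n_bins, dtype=bool)
        for idx in flag_spec.get(pair, []):
            arr[idx] = True
        flags[pair] = arr
    return tracks, flags


def test_merge_single_isolated_bin():
    tracks, flags = _tracks_with_flags(50, {(5, 14): [10]})
    ddes = merge_dde_bins(flags, tracks)
    assert len(ddes) == 1
    assert (ddes.iloc[0]["start"], ddes.iloc[0]["end"]) == (200, 220)


def test_merge_adjacent_bins_same_signature():
    tracks, flags = _tracks_with_flags(50, {(5, 14): [10, 11, 12, 13, 14]})
    ddes = merge_dde_bins(flags, tracks)
    assert len(ddes) == 1
    assert ddes.iloc[0]["end"] - ddes.iloc[0]["start"] == 100


def test_adjacent_bins_with_different_signatures_split():
    tracks, flags = _tracks_with_flags(
        50, {(5, 14): [10, 11], (14, 5): [12, 13]}
    )
    ddes = merge_dde_bins(flags, tracks)
    assert len(ddes) == 2


def test_classify_stage_specific():
    enrich = {(5, t): True for t in STAGES if t != 5}
    dens = {5: 10.0, 9: 2.0, 10: 2.0, 11: 2.0, 14: 2.0}
    assert classify_temporal(enrich, dens) == "stage5"


def test_classify_early_pattern():
    # enriched 5>14 and 9>14 only, peak at stage 5
    enrich = {(5, 14): True, (9, 14): True}
    dens = {5: 10.0, 9: 8.0, 10: 5.0, 11: 3.0, 14: 1.0}
    assert classify_temporal(enrich, dens) == "early"


def test_classify_trough_as_mixed():
    # 5>10 and 14>10: undulating accessibility
    enrich = {(5, 10): True, (14, 10): True}
    dens = {5: 10.0, 9: 5.0, 10: 1.0, 11: 5.0, 14: 9.0}
    assert classify_temporal(enrich, dens) == "mixed"


def test_classify_requires_enrichment_matrix():
    with pytest.raises(ValueError):
        classify_temporal({}, {5: 1.0, 9: 1.0, 10: 1.0, 11: 1.0, 14: 1.0})


def test_tabulation_reproduces_reference_percentages():
    counts = {"stage5": 193, "stage9": 50, "stage10": 21, "stage11": 423,
              "stage14": 1446, "early": 4431, "late": 4166, "mixed": 283}
    # the reference class counts sum to 11,013 while the reference element
    # total is 11,014; the reference percentages use the latter denominator
    table = tabulate_classes(counts, total=11_014).set_index("temporal_class")
    assert table.loc["stage14", "percentage"] == 13.13
    assert table.loc["early", "percentage"] == 40.23
    assert table.loc["late", "percentage"] == 37.82
    assert table.loc["stage5", "percentage"] == 1.75
    assert table["count"].sum() == 11_013  # listed classes; one element unlisted
    assert table["percentage"].sum() <= 100.0


def test_tabulation_single_element_and_empty():
    single = pd.DataFrame({"temporal_class": ["late"]})
    table = tabulate_classes(single)
    assert table.iloc[0]["percentage"] == 100.0
    with pytest.raises(ValueError):
        tabulate_classes({})


# ---------------------------------------------------------------------------
# profile clustering
# ---------------------------------------------------------------------------

def _dde_frame(profiles):
    df = pd.DataFrame(profiles, columns=[f"d{s}" for s in STAGES])
    df.insert(0, "chrom", "chr")
    df.insert(1, "start", np.arange(len(df)) * 1000)
    df.insert(2, "end", np.arange(len(df)) * 1000 + 150)
    return df


def test_cluster_single_group():
    ddes = _dde_frame([[1, 1, 1, 1, 1]] * 5)
    out = cluster_profiles(ddes, k=1, seed=0)
    assert set(out["labels"]) == {0}


def test_cluster_recovers_planted_families():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(0)
    early = [[1, 0.8, 0.5, 0.2, 0.05] + rng.normal(0, 0.02, 5) for _ in range(30)]
    late = [[0.05, 0.2, 0.5, 0.8, 1.0] + rng.normal(0, 0.02, 5) for _ in range(30)]
    ddes = _dde_frame([np.abs(p) for p in early + late])
    out = cluster_profiles(ddes, k=2, seed=0)
    truth = [0] * 30 + [1] * 30
    assert adjusted_rand_score(truth, out["labels"]) == 1.0
    # clusters ordered by stage of peak mean accessibility
    assert out["mean_profiles"].iloc[0].idxmax() == "d5"


def test_cluster_degenerate_identical_profiles():
    import warnings

    ddes = _dde_frame([[1, 1, 1, 1, 1]] * 6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = cluster_profiles(ddes, k=2, seed=0)
    assert len(set(out["labels"])) == 1  # one non-empty cluster


def test_cluster_k_exceeding_elements_rejected():
    with pytest.raises(ValueError):
        cluster_profiles(_dde_frame([[1, 0, 0, 0, 0]]), k=2, seed=0)
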