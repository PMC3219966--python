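"""Density binning and scan-statistic hotspot calling against brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromdyn import (
    EmptyBackground,
    Genome,
    HotspotParams,
    SimulationConfig,
    TagSet,
    bin_density,
    call_accessible_regions,
    call_hotspots,
    fdr_threshold,
    scan_z,
    simulate_tags,
)
from chromdyn.hotspots import tag_zscores, uniform_random_tags


def tagset(positions, chrom="chr", stage=5, rep=0):
    return TagSet(stage=stage, replicate=rep, positions={chrom: np.asarray(positions)})


# ---------------------------------------------------------------------------
# bin_density
# ---------------------------------------------------------------------------

def test_empty_tagset_gives_zero_track():
    genome = Genome({"chr": 1000})
    track = bin_density(tagset([]), genome)
    assert track.values["chr"].sum() == 0
    assert len(track.values["chr"]) == 50


def test_density_counts_match_direct_containment():
    genome = Genome({"chr": 1000})
    track = bin_density(tagset([100, 110, 500]), genome, bin_size=20, window=150)
    # bin with midpoint 110 (index 5) counts tags in [35, 185)
    assert track.values["chr"][5] == 2
    # bin with midpoint 510 (index 25) counts tags in [435, 585)
    assert track.values["chr"][25] == 1


def test_density_oracle_brute_force():
    genome = Genome({"chr": 2000})
    rng = np.random.default_rng(3)
    pos = np.sort(rng.integers(0, 2000, 300))
    track = bin_density(tagset(pos), genome, bin_size=20, window=150)
    for i in range(100):
        mid = i * 20 + 10
        expected = int(((pos >= mid - 75) & (pos < mid + 75)).sum())
        assert track.values["chr"][i] == expected


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=100, max_value=9_800))
def test_single_tag_touches_seven_or_eight_bins(position):
    # interior tags only: truncation at chromosome ends removes covering bins
    genome = Genome({"chr": 10_000})
    track = bin_density(tagset([position]), genome)
    assert track.values["chr"].sum() in (7, 8)


def test_window_smaller_than_bin_rejected():
    genome = Genome({"chr": 1000})
    with pytest.raises(ValueError):
        bin_density(tagset([10]), genome, bin_size=20, window=10)


# ---------------------------------------------------------------------------
# scan_z
# ---------------------------------------------------------------------------

def test_scan_z_matches_closed_form():
    # n_L = 1000 background tags, n_w = 30 in the scan window, p = 0.005
    genome = Genome({"chr": 100_000})
    rng = np.random.default_rng(0)
    params = HotspotParams(scan_window=250, background_span=50_000)
    at = 50_000
    inner = np.linspace(at - 124, at + 124, 30).astype(int)
    outer = rng.integers(at - 25_000, at + 25_000, 970)
    outer = outer[(np.abs(outer - at) > 130)][:970]
    pos = np.sort(np.concatenate([inner, outer]))
    n_l = len(pos)
    z = scan_z(tagset(pos), genome, params, "chr", at)
    p = 250 / 50_000
    expected = (30 - n_l * p) / np.sqrt(n_l * p * (1 - p))
    assert z == pytest.approx(expected, abs=1e-12)
    # worked numbers: n_L=1000, n_w=30 -> z ~ 11.21
    assert (30 - 1000 * 0.005) / np.sqrt(1000 * 0.005 * 0.995) == pytest.approx(11.21, abs=0.01)


def test_scan_z_zero_when_observation_equals_expectation():
    n_l, n_w, p = 1000, 5, 0.005
    assert (n_w - n_l * p) == 0


def test_scan_z_empty_background_raises_skip_signal():
    genome = Genome({"chr": 200_000})
    params = HotspotParams()
    with pytest.raises(EmptyBackground):
        scan_z(tagset([150_000]), genome, params, "chr", 10_000)


def test_scan_z_brute_force_oracle_small_instance():
    genome = Genome({"chr": 10_000})
    rng = np.random.default_rng(5)
    pos = np.sort(rng.integers(0, 10_000, 400))
    params = HotspotParams(scan_window=250, background_span=5_000)
    z = tag_zscores(tagset(pos), genome, params)["chr"]
    for i in range(0, 400, 7):
        at = pos[i]
        lo, hi = max(0, at - 2500), min(10_000, at + 2500)
        n_l = int(((pos >= np.ceil(lo)) & (pos < hi)).sum())
        n_w = int(((pos >= at - 125) & (pos < at + 125)).sum())
        p = 250 / (hi - lo)
        expected = (n_w - n_l * p) / np.sqrt(n_l * p * (1 - p))
        assert z[i] == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# fdr_threshold
# ---------------------------------------------------------------------------

def test_fdr_threshold_examples():
    assert fdr_threshold([1.0, 2.0, 3.0], [0.5, 0.4], 0.01) == 1.0
    observed = [10.0] * 99 + [50.0]
    random = [10.0] * 100
    assert fdr_threshold(observed, random, 0.01) == 50.0
    same = list(np.arange(100.0))
    assert fdr_threshold(same, same, 0.01) == np.inf
    with pytest.raises(ValueError):
        fdr_threshold([], [1.0], 0.01)


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def test_region_merge_arithmetic():
    genome = Genome({"chr": 100_000})
    params = HotspotParams(merge_gap=250, scan_window=250)
    tags = tagset([1000, 1100, 1200])
    z = {"chr": np.array([10.0, 10.0, 10.0])}
    regions = call_accessible_regions(tags, genome, params, 5.0, zscores=z)
    assert len(regions) == 1
    assert (regions.iloc[0]["start"], regions.iloc[0]["end"]) == (875, 1325)
    # tags 10 kb apart stay separate
    tags2 = tagset([1000, 11_000])
    z2 = {"chr": np.array([10.0, 10.0])}
    assert len(call_accessible_regions(tags2, genome, params, 5.0, zscores=z2)) == 2
    # nothing above threshold -> empty
    assert len(call_accessible_regions(tags, genome, params, 99.0, zscores=z)) == 0


def test_raising_threshold_never_adds_regions_or_coverage():
    genome = Genome({"chr": 100_000})
    config = SimulationConfig(genome=genome, background_rate=0.05, seed=11)
    tags = simulate_tags(config, 5, 0)
    params = HotspotParams()
    z = tag_zscores(tags, genome, params)
    prev_n, prev_bp = np.inf, np.inf
    for t in (1.0, 2.0, 3.0, 4.0):
        regions = call_accessible_regions(tags, genome, params, t, zscores=z)
        bp = (regions["end"] - regions["start"]).sum() if len(regions) else 0
        assert len(regions) <= prev_n and bp <= prev_bp
        prev_n, prev_bp = len(regions), bp


def test_region_calls_match_brute_force_on_small_instance():
    genome = Genome({"chr": 10_000})
    rng = np.random.default_rng(9)
    pos = np.sort(rng.integers(0, 10_000, 500))
    params = HotspotParams(scan_window=250, background_span=5_000, merge_gap=250)
    tags = tagset(pos)
    z = tag_zscores(tags, genome, params)["chr"]
    threshold = 1.5
    regions = call_accessible_regions(tags, genome, params, threshold)
    # brute force: qualifying tags, scan gaps, expand by W/2
    keep = pos[~np.isnan(z) & (z >= threshold)]
    expected = []
    if len(keep):
        start = prev = keep[0]
        for p in keep[1:]:
            if p - prev > 250:
                expected.append((max(0, start - 125), min(10_000, prev + 125)))
                start = p
            prev = p
        expected.append((max(0, start - 125), min(10_000, prev + 125)))
    assert [(r["start"], r["end"]) for _, r in regions.iterrows()] == expected


def test_null_calibration_with_fresh_random_sets(genome_1mb):
    # planted simulation scored against random sets not used for thresholding
    from chromdyn.experiments import _spread_sites
    from chromdyn.hotspots import call_hotspots, tag_zscores, uniform_random_tags

    sites = _spread_sites(genome_1mb, 50, "constitutive")
    params = HotspotParams()
    fdrs = []
    for seed in range(1, 8):
        config = SimulationConfig(
            genome=genome_1mb, background_rate=0.05, planted_sites=tuple(sites),
            site_enrichment=5.0, seed=seed,
        )
        tags = simulate_tags(config, 5, 0)
        regions, threshold, _ = call_hotspots(tags, genome_1mb, params, seed=seed)
        rng = np.random.default_rng(seed + 999)
        fresh = uniform_random_tags(tags, genome_1mb, rng)
        fresh_regions = call_accessible_regions(fresh, genome_1mb, params, threshold)
        fdrs.append(len(fresh_regions) / max(len(regions), 1))
    assert np.median(fdrs) <= 2 * params.fdr
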