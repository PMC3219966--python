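"""Genomic categories, overlap/enrichment statistics, promoter and exon
clustering, and the IUPAC matcher."""

import math

import numpy as np
import pandas as pd
import pytest

from chromdyn import Genome, SimulationConfig, make_annotation
from chromdyn.annotate import (
    GenomeAnnotation,
    assign_category,
    cluster_promoters,
    conservation_compare,
    eligible_exons,
    hypergeom_enrichment,
    motif_match,
    overlap_binomial,
    periexonic_analysis,
    promoter_profiles,
    promoter_window,
)
from chromdyn.density import DensityTrack, STAGES


def toy_annotation():
    """One plus-strand gene with the full feature layout."""
    genome = Genome({"chr": 50_000})
    genes = pd.DataFrame(
        [("g1", "chr", "+", 10_000, 14_000, 10_000, True)],
        columns=["gene_id", "chrom", "strand", "start", "end", "tss", "regulator"],
    )
    features = pd.DataFrame(
        [
            ("g1", "chr", "+", "five_utr", 10_000, 10_200),
            ("g1", "chr", "+", "cds", 10_200, 10_600),
            ("g1", "chr", "+", "intron", 10_600, 11_200),
            ("g1", "chr", "+", "cds", 11_200, 11_600),
            ("g1", "chr", "+", "three_utr", 11_600, 12_000),
        ],
        columns=["gene_id", "chrom", "strand", "feature", "start", "end"],
    )
    return GenomeAnnotation(genome=genome, genes=genes, features=features)


def dhs_at(*centers):
    return pd.DataFrame(
        [("chr", c - 75, c + 75) for c in centers], columns=["chrom", "start", "end"]
    )


def test_category_precedence_and_totality():
    annot = toy_annotation()
    cats = assign_category(dhs_at(9_950, 10_400, 10_900, 11_400, 11_800, 30_000), annot)
    assert list(cats) == ["TSS", "CDS", "intron", "CDS", "3'UTR", "intergenic"]
    # 5'UTR centre within 100 bp of the TSS is claimed by the TSS category
    assert list(assign_category(dhs_at(10_090), annot)) == ["TSS"]
    assert list(assign_category(dhs_at(10_150), annot)) == ["5'UTR"]
    many = dhs_at(*np.linspace(500, 49_000, 40).astype(int))
    cats = assign_category(many, annot)
    assert len(cats) == len(many)  # total function


def test_overlap_binomial_worked_examples():
    genome = Genome({"chr": 100_000})
    subjects = pd.DataFrame([("chr", 0, 10_000)], columns=["chrom", "start", "end"])
    queries = pd.DataFrame(
        [("chr", i * 500, i * 500 + 100) for i in range(20)],
        columns=["chrom", "start", "end"],
    )
    frac, p = overlap_binomial(queries.iloc[:10], subjects, genome)
    assert frac == 1.0
    assert p == pytest.approx(0.1**10, rel=1e-9)
    # zero overlaps -> p = 1
    far = pd.DataFrame([("chr", 90_000, 90_100)], columns=["chrom", "start", "end"])
    frac0, p0 = overlap_binomial(far, subjects, genome)
    assert (frac0, p0) == (0.0, 1.0)


def test_overlap_binomial_tail_enumeration():
    # 5 of 10 successes at q = 0.5 -> P(X >= 5) = 638/1024
    genome = Genome({"chr": 100_000})
    subjects = pd.DataFrame([("chr", 0, 50_000)], columns=["chrom", "start", "end"])
    inside = [("chr", 1000 * i, 1000 * i + 10) for i in range(5)]
    outside = [("chr", 60_000 + 1000 * i, 60_000 + 1000 * i + 10) for i in range(5)]
    queries = pd.DataFrame(inside + outside, columns=["chrom", "start", "end"])
    frac, p = overlap_binomial(queries, subjects, genome)
    assert frac == 0.5
    assert p == pytest.approx(638 / 1024, rel=1e-12)


def test_overlap_binomial_agrees_with_monte_carlo():
    genome = Genome({"chr": 100_000})
    rng = np.random.default_rng(0)
    subjects = pd.DataFrame(
        [("chr", s, s + 2000) for s in range(0, 100_000, 10_000)][:3],
        columns=["chrom", "start", "end"],
    )  # covers 6%
    n, b = 20, 4
    queries = pd.DataFrame(
        [("chr", 500 + i, 501 + i) for i in range(b)]
        + [("chr", 50_000 + 100 * i, 50_001 + 100 * i) for i in range(n - b)],
        columns=["chrom", "start", "end"],
    )
    # place the first b inside subjects
    queries.loc[:b - 1, "start"] = [100, 300, 10_100, 20_100]
    queries.loc[:b - 1, "end"] = queries.loc[:b - 1, "start"] + 1
    frac, p = overlap_binomial(queries, subjects, genome)
    assert frac == b / n
    q = 0.06
    mc = 0
    n_mc = 10_000
    for _ in range(n_mc):
        pos = rng.integers(0, 100_000, n)
        hits = ((pos % 10_000) < 2000) & (pos < 30_000)
        mc += int(hits.sum() >= b)
    p_mc = mc / n_mc
    se = math.sqrt(max(p_mc * (1 - p_mc), 1e-9) / n_mc)
    assert abs(p - p_mc) < 3 * se + 0.01


def brute_hypergeom_tail(b, B, n, N):
    total = math.comb(N, n)
    return sum(math.comb(B, k) * math.comb(N - B, n - k) for k in range(b, min(B, n) + 1)) / total


def test_hypergeometric_examples_and_enumeration():
    assert hypergeom_enrichment(0, 5, 4, 10) == 1.0
    assert hypergeom_enrichment(4, 5, 4, 10) == pytest.approx(5 / 210, abs=1e-12)
    assert hypergeom_enrichment(3, 3, 3, 6) == pytest.approx(1 / 20, abs=1e-12)
    rng = np.random.default_rng(1)
    for _ in range(25):
        N = int(rng.integers(5, 50))
        B = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        b = int(rng.integers(0, min(B, n) + 1))
        assert hypergeom_enrichment(b, B, n, N) == pytest.approx(
            brute_hypergeom_tail(b, B, n, N), abs=1e-12
        )
    with pytest.raises(ValueError):
        hypergeom_enrichment(5, 3, 4, 10)


def test_conservation_compare_separates_planted_signal():
    genome = Genome({"chr": 100_000})
    ddes = pd.DataFrame(
        [("chr", 1000 * i, 1000 * i + 200) for i in range(5, 25)],
        columns=["chrom", "start", "end"],
    )
    track = {"chr": np.full(100_000, 0.2, dtype=np.float32)}
    for _, r in ddes.iterrows():
        track["chr"][r["start"]:r["end"]] = 0.8
    res = conservation_compare(ddes, track, genome, seed=3)
    assert res["elements"]["ci_low"] > res["random"]["ci_high"]
    # constant track: identical medians
    flat = {"chr": np.full(100_000, 0.3, dtype=np.float32)}
    res2 = conservation_compare(ddes, flat, genome, seed=3)
    assert res2["elements"]["median"] == pytest.approx(res2["random"]["median"])
    a = conservation_compare(ddes, track, genome, seed=3)
    assert a == res  # seeded reproducibility


# ---------------------------------------------------------------------------
# promoter profiles and clustering
# ---------------------------------------------------------------------------

def _track(genome, values):
    return DensityTrack(genome=genome, bin_size=20, window=150, values={"chr": values})


def test_promoter_profiles_oriented_windows():
    genome = Genome({"chr": 10_000})
    genes = pd.DataFrame(
        [
            ("plus", "chr", "+", 2_000, 3_000, 2_000, False),
            ("minus", "chr", "-", 6_000, 7_000, 6_999, False),
        ],
        columns=["gene_id", "chrom", "strand", "start", "end", "tss", "regulator"],
    )
    annot = GenomeAnnotation(genome=genome, genes=genes, features=genes.iloc[:0].assign(feature=None))
    vals = np.zeros(500)
    vals[(2_000 - 30) // 20] = 7.0        # inside plus promoter [-60, +40)
    vals[(6_999 + 50) // 20] = 9.0        # genomic-downstream of minus TSS = oriented upstream
    tracks = {s: _track(genome, vals * (1 if s == 5 else 0)) for s in STAGES}
    prof = promoter_profiles(tracks, annot)
    assert prof.loc["plus", 5] == 7.0
    assert prof.loc["minus", 5] == 9.0
    assert (prof[9] == 0).all()
    # oriented window arithmetic
    assert promoter_window(1000, "+") == (940, 1040)
    assert promoter_window(1000, "-") == (960, 1060)


def test_promoter_metacluster_recovery_and_motif_fractions():
    rng = np.random.default_rng(0)
    rows, names = [], []
    for i in range(60):
        rows.append(np.array([1.0, 0.9, 0.7, 0.5, 0.3]) + rng.normal(0, 0.03, 5))
        names.append(f"down{i}")
    for i in range(60):
        rows.append(np.array([0.2, 0.4, 0.6, 0.8, 1.0]) + rng.normal(0, 0.03, 5))
        names.append(f"up{i}")
    for i in range(60):
        rows.append(np.array([1.0, 1.0, 1.0, 1.0, 1.0]) + rng.normal(0, 0.03, 5))
        names.append(f"flat{i}")
    profiles = pd.DataFrame(np.abs(rows), index=names, columns=list(STAGES))
    motifs = pd.DataFrame({"DRE": [n.startswith("down") for n in names]}, index=names)
    out = cluster_promoters(profiles, k=6, seed=0, motif_matrix=motifs)
    assign = out["assignments"].set_index("gene_id")
    correct = 0
    for n in names:
        want = "down" if n.startswith("down") else "up" if n.startswith("up") else "constitutive"
        correct += assign.loc[n, "metacluster"] == want
    assert correct / len(names) >= 0.95
    # motif fraction arithmetic: a pure 'down' cluster is DRE-enriched 3x
    stats = out["motif_stats"]
    down_clusters = out["cluster_means"][out["cluster_means"]["metacluster"] == "down"].index
    sub = stats[(stats["cluster"].isin(down_clusters)) & (stats["motif"] == "DRE")]
    assert (sub["fraction"] > 0.9).all()
    assert (sub["enrichment"] > 2.5).all()


def test_cluster_promoters_k_exceeding_profiles_rejected():
    profiles = pd.DataFrame(np.ones((3, 5)), columns=list(STAGES))
    with pytest.raises(ValueError):
        cluster_promoters(profiles, k=5, seed=0)


# ---------------------------------------------------------------------------
# peri-exonic analysis
# ---------------------------------------------------------------------------

def _exon_annotation():
    """Three exons; only the middle one passes both length and flank filters."""
    genome = Genome({"chr": 20_000})
    rows = [
        ("g1", "chr", "+", "five_utr", 1_000, 1_100),
        ("g1", "chr", "+", "cds", 1_100, 1_300),          # too short (200)
        ("g1", "chr", "+", "intron", 1_300, 1_900),
        ("g1", "chr", "+", "cds", 1_900, 2_300),          # 400 bp, flanks 600/500
        ("g1", "chr", "+", "intron", 2_300, 2_800),
        ("g1", "chr", "+", "cds", 2_800, 3_200),          # long enough, no right intron
        ("g1", "chr", "+", "three_utr", 3_200, 3_400),
    ]
    features = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "feature", "start", "end"]
    )
    genes = pd.DataFrame(
        [("g1", "chr", "+", 1_000, 3_400, 1_000, False)],
        columns=["gene_id", "chrom", "strand", "start", "end", "tss", "regulator"],
    )
    return GenomeAnnotation(genome=genome, genes=genes, features=features)


def test_exon_filters_trace():
    annot = _exon_annotation()
    ok = eligible_exons(annot, min_exon_len=320, min_flank=300)
    assert len(ok) == 1
    assert (ok.iloc[0]["start"], ok.iloc[0]["end"]) == (1_900, 2_300)


def test_periexonic_elevated_expression_fraction():
    annot = _exon_annotation()
    annot.exon_expression = pd.DataFrame(
        [("g1", "chr", 1_900, 2_300, 30.0)],
        columns=["gene_id", "chrom", "start", "end", "expression"],
    )
    tracks = {
        s: DensityTrack(genome=annot.genome, bin_size=20, window=150,
                        values={"chr": np.ones(1000)})
        for s in STAGES
    }
    res = periexonic_analysis(tracks, annot, k=4, expr_threshold=25.0)
    assert len(res["exons"]) == 1
    assert res["elevated_fraction"].iloc[0] == 1.0
    res_hi = periexonic_analysis(tracks, annot, k=4, expr_threshold=50.0)
    assert res_hi["elevated_fraction"].iloc[0] == 0.0


def test_periexonic_no_passing_exons_is_empty_not_error():
    annot = _exon_annotation()
    tracks = {
        s: DensityTrack(genome=annot.genome, bin_size=20, window=150,
                        values={"chr": np.ones(1000)})
        for s in STAGES
    }
    res = periexonic_analysis(tracks, annot, min_exon_len=5_000)
    assert len(res["exons"]) == 0
    assert res["clusters"] is None


def test_elevated_expression_fraction_arithmetic():
    # cluster of 4 exons with expressions (30, 10, 40, 5), threshold 25 -> 0.5
    vals = np.array([30.0, 10.0, 40.0, 5.0])
    assert (vals > 25).mean() == 0.5


# ---------------------------------------------------------------------------
# IUPAC matcher
# ---------------------------------------------------------------------------

def test_motif_match_examples():
    assert motif_match("GGTATAAAGG", "TATAAA")
    assert not motif_match("GGGGGG", "TATAAA")
    assert motif_match("AATCAGTTAA", "TCAKTY")  # K={G,T}, Y={C,T}
    assert not motif_match("AATCACTTAA", "TCAKTY")
    with pytest.raises(ValueError):
        motif_match("ACGX", "TATA")
    with pytest.raises(ValueError):
        motif_match("ACGT", "")


def test_generated_annotation_supports_periexonic_pipeline():
    genome = Genome({"chrA": 500_000, "chrB": 500_000})
    config = SimulationConfig(genome=genome, seed=9, n_genes=30)
    annot, _ = make_annotation(config)
    ok = eligible_exons(annot)
    assert len(ok) >= 10  # middle exons are built to pass the filters
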