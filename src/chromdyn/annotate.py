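"""Gene annotation container and downstream annotation statistics.

Covers genomic-category assignment of DHSs, interval-overlap significance
under a binomial placement null, conservation comparison against matched
random sites, hypergeometric expression-term enrichment, core-promoter
accessibility clustering with motif enrichment, peri-exonic accessibility
clustering, and a minimal IUPAC consensus matcher.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .density import STAGES, DensityTrack
from .genome import Genome
from .intervals import (
    coverage_fraction,
    merge_intervals,
    overlaps_any,
    sort_intervals,
)

#: The ten core-promoter motifs tracked in the promoter analysis: the four
#: classical elements (TATA, INR, DPE, DRE) plus MTE and five further
#: conserved core-promoter motifs.
CORE_PROMOTER_MOTIFS = (
    "TATA", "INR", "DPE", "DRE", "MTE", "Ohler1", "Ohler5", "Ohler6", "Ohler7", "Ohler8",
)

GENE_FEATURES = ("five_utr", "cds", "intron", "three_utr")

#: Genomic category precedence for DHS assignment (TSS proximity first).
CATEGORY_ORDER = ("TSS", "5'UTR", "CDS", "intron", "3'UTR", "intergenic")

_FEATURE_TO_CATEGORY = {
    "five_utr": "5'UTR",
    "cds": "CDS",
    "intron": "intron",
    "three_utr": "3'UTR",
}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass
class GenomeAnnotation:
    """Toy gene annotation: gene models, promoter motifs, exon expression.

    ``genes`` has one row per gene: ``gene_id, chrom, strand, start, end,
    tss, regulator`` (bool: encodes a transcription factor / regulator).
    ``features`` has one row per gene part: ``gene_id, chrom, strand,
    feature, start, end`` with feature in ``five_utr/cds/intron/three_utr``.
    ``promoter_motifs`` is a boolean gene x motif matrix; ``exon_expression``
    carries per-CDS-exon early (pre-zygotic) expression values; ``gene_terms``
    maps genes to expression-pattern annotation terms.
    """

    genome: Genome
    genes: pd.DataFrame
    features: pd.DataFrame
    promoter_motifs: pd.DataFrame | None = None
    exon_expression: pd.DataFrame | None = None
    gene_terms: pd.DataFrame | None = None

    def feature_intervals(self, feature: str) -> pd.DataFrame:
        sub = self.features[self.features["feature"] == feature]
        return sub[["chrom", "start", "end"]].reset_index(drop=True)

    def tss_table(self) -> pd.DataFrame:
        return self.genes[["gene_id", "chrom", "strand", "tss"]].reset_index(drop=True)

    def cds_intervals(self) -> pd.DataFrame:
        return self.feature_intervals("cds")

    def noncoding_intervals(self) -> pd.DataFrame:
        """Complement of the merged CDS set, per chromosome."""
        cds = merge_intervals(self.cds_intervals())
        rows = []
        for chrom in self.genome:
            clen = self.genome.length(chrom)
            prev = 0
            sub = cds[cds["chrom"] == chrom]
            for s, e in zip(sub["start"], sub["end"]):
                if s > prev:
                    rows.append((chrom, prev, int(s)))
                prev = max(prev, int(e))
            if prev < clen:
                rows.append((chrom, prev, clen))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# DHS genomic-category assignment (TSS > 5'UTR > CDS > intron > 3'UTR > intergenic)
# ---------------------------------------------------------------------------

def assign_category(dhs: pd.DataFrame, annot: GenomeAnnotation, tss_radius: int = 100) -> pd.Series:
    """Category of each DHS by its central nucleotide.

    The centre is ``start + width//2`` (left-rounded).  Precedence: within
    ``tss_radius`` bp of a TSS, then 5'UTR, CDS, intron, 3'UTR, else
    intergenic.  Total: every DHS receives exactly one category.
    """
    centers = (dhs["start"] + (dhs["end"] - dhs["start"]) // 2).to_numpy()
    chroms = dhs["chrom"].to_numpy()
    for chrom in set(chroms):
        if chrom not in annot.genome:
            raise ValueError(f"DHS on unknown chromosome {chrom!r}")
    out = np.full(len(dhs), "intergenic", dtype=object)

    tss_by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in annot.genes.groupby("chrom")}
    feature_by_chrom = {
        feat: {c: g for c, g in annot.feature_intervals(feat).groupby("chrom")}
        for feat in GENE_FEATURES
    }
    for i, (chrom, center) in enumerate(zip(chroms, centers)):
        tss = tss_by_chrom.get(chrom)
        if tss is not None and len(tss):
            j = np.searchsorted(tss, center)
            near = min(
                abs(center - tss[j - 1]) if j > 0 else np.inf,
                abs(tss[j] - center) if j < len(tss) else np.inf,
            )
            if near <= tss_radius:
                out[i] = "TSS"
                continue
        for feat in GENE_FEATURES:
            sub = feature_by_chrom[feat].get(chrom)
            if sub is None:
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            j = np.searchsorted(starts, center, side="right") - 1
            hit = (ends[: j + 1] > center).any() if j >= 0 else False
            if hit:
                out[i] = _FEATURE_TO_CATEGORY[feat]
                break
    return pd.Series(out, index=dhs.index, name="category")


# ---------------------------------------------------------------------------
# Interval-overlap significance under a binomial placement null
# ---------------------------------------------------------------------------

def overlap_binomial(
    query: pd.DataFrame, subject: pd.DataFrame, genome: Genome
) -> tuple[float, float]:
    """Fraction of query intervals overlapping any subject (>=1 bp) and the
    upper-tail binomial p-value.

    The success probability is the fraction of the genome covered by the
    merged subject set — the simplest exchangeable-placement null.
    """
    if genome.total_size <= 0:
        raise ValueError("zero-length genome")
    n = len(query)
    if n == 0:
        raise ValueError("empty query set")
    merged = merge_intervals(subject)
    q = coverage_fraction(merged, genome)
    hits = int(overlaps_any(query, merged, min_overlap=1).sum())
    pval = float(stats.binom.sf(hits - 1, n, q)) if hits > 0 else 1.0
    return hits / n, pval


# ---------------------------------------------------------------------------
# Conservation of elements vs matched random non-coding placements
# ---------------------------------------------------------------------------

def _interval_means(score_track: dict[str, np.ndarray], df: pd.DataFrame) -> np.ndarray:
    means = np.empty(len(df))
    for i, (chrom, s, e) in enumerate(zip(df["chrom"], df["start"], df["end"])):
        means[i] = float(np.mean(score_track[chrom][int(s) : int(e)]))
    return means


def _median_ci(values: np.ndarray, rng: np.random.Generator, n_boot: int = 1000) -> dict:
    med = float(np.median(values))
    boots = np.median(
        rng.choice(values, size=(n_boot, len(values)), replace=True), axis=1
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"median": med, "ci_low": float(lo), "ci_high": float(hi)}


def conservation_compare(
    ddes: pd.DataFrame,
    score_track: dict[str, np.ndarray],
    genome: Genome,
    seed: int,
    allowed: pd.DataFrame | None = None,
    n_boot: int = 1000,
) -> dict:
    """Median per-element mean conservation with 95% bootstrap CIs, for the
    element set and a size-matched random set placed uniformly in ``allowed``
    (non-coding) sequence.
    """
    if len(ddes) == 0:
        raise ValueError("empty element list")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dde_means = _interval_means(score_track, ddes)

    if allowed is None:
        allowed = pd.DataFrame(
            [(c, 0, genome.length(c)) for c in genome], columns=["chrom", "start", "end"]
        )
    allowed = sort_intervals(merge_intervals(allowed))
    seg_len = (allowed["end"] - allowed["start"]).to_numpy()
    probs = seg_len / seg_len.sum()
    sizes = (ddes["end"] - ddes["start"]).to_numpy()
    rows = []
    for size in sizes:
        fit = seg_len >= size
        p = np.where(fit, probs, 0.0)
        p = p / p.sum()
        j = rng.choice(len(allowed), p=p)
        seg = allowed.iloc[j]
        start = int(rng.integers(seg["start"], seg["end"] - size + 1))
        rows.append((seg["chrom"], start, start + int(size)))
    random_df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    rand_means = _interval_means(score_track, random_df)
    return {
        "elements": _median_ci(dde_means, rng, n_boot),
        "random": _median_ci(rand_means, rng, n_boot),
    }


# ---------------------------------------------------------------------------
# Hypergeometric expression-term enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrichment(b: int, B: int, n: int, N: int) -> float:
    """P(X >= b) for X ~ Hypergeometric(N, B, n): the chance of drawing at
    least ``b`` genes carrying a term when ``B`` of ``N`` genes carry it and
    ``n`` genes are drawn without replacement."""
    if not (0 <= b <= min(B, n)) or B > N or n > N:
        raise ValueError(f"inconsistent counts b={b}, B={B}, n={n}, N={N}")
    if b == 0:
        return 1.0
    return float(stats.hypergeom.sf(b - 1, N, B, n))


def term_enrichment_table(
    member_genes: list[str], annot: GenomeAnnotation
) -> pd.DataFrame:
    """Hypergeometric enrichment of every annotation term within a gene set."""
    if annot.gene_terms is None:
        raise ValueError("annotation carries no gene terms")
    N = len(annot.genes)
    n = len(set(member_genes))
    members = set(member_genes)
    rows = []
    for term, sub in annot.gene_terms.groupby("term"):
        carriers = set(sub["gene_id"])
        b = len(carriers & members)
        B = len(carriers)
        rows.append((term, b, B, n, N, hypergeom_enrichment(b, B, n, N)))
    return pd.DataFrame(rows, columns=["term", "b", "B", "n", "N", "p_value"])


# ---------------------------------------------------------------------------
# Core-promoter accessibility profiles and clustering
# ---------------------------------------------------------------------------

def promoter_window(tss: int, strand: str, upstream: int = 60, downstream: int = 40):
    """Genomic [start, end) of the oriented core promoter -upstream..+downstream."""
    if strand == "+":
        return tss - upstream, tss + downstream
    return tss - downstream, tss + upstream


def promoter_profiles(
    tracks: dict[int, DensityTrack], annot: GenomeAnnotation,
    upstream: int = 60, downstream: int = 40,
) -> pd.DataFrame:
    """Per-gene, per-stage peak (max bin) density over the -60..+40 core
    promoter, strand-oriented.  Returns a gene_id-indexed DataFrame with one
    column per stage."""
    missing = [s for s in STAGES if s not in tracks]
    if missing:
        raise ValueError(f"missing density tracks for stages {missing}")
    out = {}
    for stage in STAGES:
        track = tracks[stage]
        vals = []
        for _, g in annot.genes.iterrows():
            if pd.isna(g["tss"]):
                raise ValueError(f"gene {g['gene_id']} has no TSS")
            lo, hi = promoter_window(int(g["tss"]), g["strand"], upstream, downstream)
            arr = track.values[g["chrom"]]
            mids = track.bin_mids(g["chrom"])
            sel = (mids >= lo) & (mids < hi)
            vals.append(float(arr[sel].max()) if sel.any() else 0.0)
        out[stage] = vals
    return pd.DataFrame(out, index=annot.genes["gene_id"].to_numpy())


def cluster_promoters(
    profiles: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    motif_matrix: pd.DataFrame | None = None,
    trend_ratio: float = 1.5,
) -> dict:
    """k-means clustering of unit-max-normalised promoter profiles.

    Each cluster is assigned a metacluster by the trend of its mean profile:
    ``up`` if the stage-14 mean exceeds ``trend_ratio`` times the stage-5
    mean, ``down`` for the reverse, else ``constitutive``.  When a motif
    presence matrix is supplied, per-cluster motif fractions and enrichment
    ratios over the genome-wide fraction are reported.
    """
    mat = profiles.to_numpy(dtype=float)
    maxes = mat.max(axis=1)
    keep = maxes > 0
    norm = mat[keep] / maxes[keep][:, None]
    if k > norm.shape[0]:
        raise ValueError(f"k={k} exceeds the {norm.shape[0]} non-zero profiles")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(norm)
    assign = pd.DataFrame(
        {"gene_id": profiles.index[keep], "cluster": labels}
    )
    cluster_means = pd.DataFrame(
        km.cluster_centers_, columns=list(profiles.columns)
    )
    meta = []
    for _, row in cluster_means.iterrows():
        early, late = row[STAGES[0]], row[STAGES[-1]]
        if late > trend_ratio * early:
            meta.append("up")
        elif early > trend_ratio * late:
            meta.append("down")
        else:
            meta.append("constitutive")
    cluster_means["metacluster"] = meta
    assign["metacluster"] = assign["cluster"].map(dict(enumerate(meta)))

    motif_stats = None
    if motif_matrix is not None:
        genome_frac = motif_matrix.mean(axis=0)
        rows = []
        for c in range(k):
            members = assign.loc[assign["cluster"] == c, "gene_id"]
            sub = motif_matrix.reindex(members).fillna(False)
            for motif in motif_matrix.columns:
                frac = float(sub[motif].mean()) if len(sub) else 0.0
                gw = float(genome_frac[motif])
                rows.append((c, motif, frac, frac / gw if gw > 0 else np.nan))
        motif_stats = pd.DataFrame(rows, columns=["cluster", "motif", "fraction", "enrichment"])
    return {"assignments": assign, "cluster_means": cluster_means, "motif_stats": motif_stats}


# ---------------------------------------------------------------------------
# Peri-exonic accessibility clustering
# ---------------------------------------------------------------------------

def eligible_exons(
    annot: GenomeAnnotation, min_exon_len: int = 320, min_flank: int = 300
) -> pd.DataFrame:
    """CDS exons of at least ``min_exon_len`` bp with at least ``min_flank``
    bp of uninterrupted intron flanking both boundaries."""
    feats = annot.features
    rows = []
    for gene_id, sub in feats.groupby("gene_id", sort=False):
        cds = sub[sub["feature"] == "cds"].sort_values("start")
        introns = sub[sub["feature"] == "intron"].sort_values("start")
        for _, ex in cds.iterrows():
            if ex["end"] - ex["start"] < min_exon_len:
                continue
            up = introns[introns["end"] == ex["start"]]
            down = introns[introns["start"] == ex["end"]]
            if len(up) == 0 or len(down) == 0:
                continue
            if (up.iloc[0]["end"] - up.iloc[0]["start"]) < min_flank:
                continue
            if (down.iloc[0]["end"] - down.iloc[0]["start"]) < min_flank:
                continue
            rows.append(
                (gene_id, ex["chrom"], sub.iloc[0]["strand"], int(ex["start"]), int(ex["end"]))
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])


def _boundary_profile(track: DensityTrack, chrom: str, boundary: int, strand: str,
                      flank: int, step: int) -> np.ndarray:
    """Density sampled at ``step``-bp increments across +/- flank of a
    boundary, oriented along the direction of transcription."""
    offsets = np.arange(-flank, flank + step, step)
    if strand == "-":
        offsets = -offsets
    positions = boundary + offsets
    arr = track.values[chrom]
    idx = np.clip(positions // track.bin_size, 0, len(arr) - 1)
    return arr[idx].astype(float)


def periexonic_analysis(
    tracks: dict[int, DensityTrack],
    annot: GenomeAnnotation,
    min_exon_len: int = 320,
    min_flank: int = 300,
    k: int = 4,
    expr_threshold: float = 25.0,
    step: int = 20,
    seed: int = 0,
) -> dict:
    """Cluster strand-aligned peri-exonic accessibility and relate clusters to
    early (pre-zygotic) expression.

    Exons pass the length/flank filters, get boundary-aligned density arrays
    (mean across stages) at 20-bp steps over +/-300 bp of both boundaries,
    and the 5'-boundary arrays are k-means clustered.  Per cluster the
    fraction of exons with expression above ``expr_threshold`` is reported.
    Returns an empty result when no exon passes the filters.
    """
    exons = eligible_exons(annot, min_exon_len, min_flank)
    if len(exons) == 0:
        return {"exons": exons, "clusters": None, "elevated_fraction": None}
    mean_vals = {
        chrom: np.mean([tracks[s].values[chrom] for s in STAGES], axis=0)
        for chrom in annot.genome
    }
    mean_track = DensityTrack(
        genome=annot.genome,
        bin_size=tracks[STAGES[0]].bin_size,
        window=tracks[STAGES[0]].window,
        values=mean_vals,
    )
    five, three = [], []
    for _, ex in exons.iterrows():
        b5 = ex["start"] if ex["strand"] == "+" else ex["end"]
        b3 = ex["end"] if ex["strand"] == "+" else ex["start"]
        five.append(_boundary_profile(mean_track, ex["chrom"], int(b5), ex["strand"], min_flank, step))
        three.append(_boundary_profile(mean_track, ex["chrom"], int(b3), ex["strand"], min_flank, step))
    five = np.vstack(five)
    three = np.vstack(three)
    k_eff = min(k, len(exons))
    km = KMeans(n_clusters=k_eff, random_state=seed, n_init=10)
    labels = km.fit_predict(five)
    exons = exons.copy()
    exons["cluster"] = labels

    expr = None
    if annot.exon_expression is not None:
        key = ["chrom", "start", "end"]
        expr = exons.merge(annot.exon_expression[key + ["expression"]], on=key, how="left")
        expr["expression"] = expr["expression"].fillna(0.0)
        exons["expression"] = expr["expression"].to_numpy()
    elevated = None
    if expr is not None:
        elevated = (
            exons.assign(elevated=exons["expression"] > expr_threshold)
            .groupby("cluster")["elevated"]
            .mean()
        )
    return {
        "exons": exons,
        "profiles_5p": five,
        "profiles_3p": three,
        "clusters": km,
        "elevated_fraction": elevated,
    }


# ---------------------------------------------------------------------------
# Minimal IUPAC consensus matcher (plumbing; motif presence is normally input)
# ---------------------------------------------------------------------------

def motif_match(sequence: str, consensus: str) -> bool:
    """Whether an IUPAC consensus occurs anywhere in ``sequence``."""
    if not consensus:
        raise ValueError("empty consensus")
    seq = sequence.upper()
    if re.search(r"[^ACGT]", seq):
        raise ValueError("sequence contains characters outside A/C/G/T")
    try:
        pattern = "".join(IUPAC[c] for c in consensus.upper())
    except KeyError as err:
        raise ValueError(f"invalid IUPAC code {err.args[0]!r}") from None
    return re.search(pattern, seq) is not None
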