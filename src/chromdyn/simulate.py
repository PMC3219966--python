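"""Synthetic multi-stage DNaseI cleavage data with planted truth.

The generator emulates the statistical structure of a staged embryo DNaseI
experiment at desk scale: a homogeneous Poisson background of cleavage tags,
~150-bp enriched sites whose intensity is modulated across five developmental
stages (5, 9, 10, 11, 14), two independent replicates per stage, plus toy
gene annotations, promoter-motif labels, exon expression values and a
conservation-style score track.  Every planted feature is recorded in a
:class:`TruthTable` so downstream callers can be scored against known truth.

All randomness flows from one integer seed through a documented
``numpy.random.SeedSequence`` splitting scheme: stream 0 = tags (keyed by
stage index and replicate), stream 1 = annotation, stream 2 = conservation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotate import CORE_PROMOTER_MOTIFS, GenomeAnnotation
from .density import STAGES, TagSet
from .genome import Genome

#: Relative per-stage intensity profiles for the planted truth classes.
CLASS_PROFILES: dict[str, tuple[float, ...]] = {
    "stage5": (1.0, 0.0, 0.0, 0.0, 0.0),
    "stage9": (0.0, 1.0, 0.0, 0.0, 0.0),
    "stage10": (0.0, 0.0, 1.0, 0.0, 0.0),
    "stage11": (0.0, 0.0, 0.0, 1.0, 0.0),
    "stage14": (0.0, 0.0, 0.0, 0.0, 1.0),
    "early": (1.0, 0.8, 0.5, 0.25, 0.1),
    "late": (0.1, 0.25, 0.5, 0.8, 1.0),
    "mixed": (1.0, 0.3, 0.05, 0.3, 1.0),
    "constitutive": (1.0, 1.0, 1.0, 1.0, 1.0),
}

_TAG_STREAM, _ANNOT_STREAM, _CONS_STREAM = 0, 1, 2


@dataclass(frozen=True)
class PlantedSite:
    """A planted accessible site with a stage-intensity profile.

    ``stage_profile`` holds five non-negative relative intensities for stages
    (5, 9, 10, 11, 14); ``shape`` is ``unimodal`` (one ~150-bp bump) or
    ``camelback`` (two bumps 150 bp apart with a central trough, the
    morphology of a subset of early promoters).
    """

    chrom: str
    start: int
    end: int
    truth_class: str
    stage_profile: tuple[float, ...]
    shape: str = "unimodal"

    def __post_init__(self) -> None:
        if self.end - self.start < 150:
            raise ValueError("planted sites must be at least 150 bp wide")
        if len(self.stage_profile) != len(STAGES):
            raise ValueError("stage_profile needs one intensity per stage")
        if any(not math.isfinite(v) or v < 0 for v in self.stage_profile):
            raise ValueError("stage intensities must be finite and non-negative")
        if self.shape not in ("unimodal", "camelback"):
            raise ValueError(f"unknown site shape {self.shape!r}")

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    ``background_rate`` is expected tags per bp; ``site_enrichment`` is the
    fold-enrichment of added cleavage intensity over background at a site's
    peak (scaled per stage by the site's profile).  A single integer ``seed``
    fixes all randomness.
    """

    genome: Genome
    background_rate: float = 0.05
    planted_sites: tuple[PlantedSite, ...] = ()
    site_enrichment: float = 5.0
    replicates_per_stage: int = 2
    seed: int = 0
    n_genes: int = 50
    motif_fractions: tuple[tuple[str, float], ...] = tuple(
        (m, f) for m, f in zip(CORE_PROMOTER_MOTIFS, (0.15, 0.3, 0.25, 0.2, 0.15,
                                                      0.1, 0.1, 0.1, 0.1, 0.1))
    )
    regulator_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.background_rate < 0 or self.site_enrichment < 0:
            raise ValueError("rates must be non-negative")
        if self.replicates_per_stage < 1:
            raise ValueError("need at least one replicate per stage")

    def with_sites(self, sites) -> "SimulationConfig":
        return replace(self, planted_sites=tuple(sites))


@dataclass
class TruthTable:
    """Planted truth for scoring: site intervals/classes plus gene, motif and
    expression assignments."""

    sites: pd.DataFrame
    genes: pd.DataFrame | None = None
    motifs: pd.DataFrame | None = None
    exon_expression: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.sites) and self.sites["site_id"].duplicated().any():
            raise ValueError("planted sites must appear exactly once")


def sites_truth_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(config.planted_sites):
        rows.append(
            (f"site{i:04d}", s.chrom, s.start, s.end, s.truth_class, s.shape)
            + tuple(s.stage_profile)
        )
    cols = ["site_id", "chrom", "start", "end", "truth_class", "shape"] + [
        f"profile_{s}" for s in STAGES
    ]
    return pd.DataFrame(rows, columns=cols)


def _rng_for(config: SimulationConfig, stream: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream, *key)))


def simulate_tags(config: SimulationConfig, stage: int, replicate: int) -> TagSet:
    """Draw one stage/replicate's cleavage tags as an inhomogeneous Poisson
    process: uniform background plus per-site bumps.

    Site bumps are Gaussian (sd = width/4, so +/-2 sd spans the site) for
    ``unimodal`` sites, or a balanced mixture of two Gaussians 150 bp apart
    (sd = width/8) for ``camelback`` sites.  The added intensity at the bump
    peak is ``site_enrichment * background_rate * stage_profile[stage]``.
    Replicates are independent draws under the same intensity; identical
    (config, stage, replicate) yields identical output.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    if not (0 <= replicate < config.replicates_per_stage):
        raise ValueError(f"replicate {replicate} out of range")
    stage_idx = STAGES.index(stage)
    rng = _rng_for(config, _TAG_STREAM, stage_idx, replicate)
    positions: dict[str, np.ndarray] = {}
    for chrom in config.genome:
        clen = config.genome.length(chrom)
        n_bg = rng.poisson(config.background_rate * clen)
        parts = [rng.integers(0, clen, size=n_bg)]
        for site in config.planted_sites:
            if site.chrom != chrom:
                continue
            amp = (
                config.site_enrichment
                * config.background_rate
                * site.stage_profile[stage_idx]
            )
            if amp <= 0:
                continue
            width = site.end - site.start
            if site.shape == "unimodal":
                sd = width / 4.0
                lam = amp * math.sqrt(2 * math.pi) * sd
                n = rng.poisson(lam)
                draws = rng.normal(site.center, sd, size=n)
            else:  # camelback: two modes 150 bp apart
                sd = width / 8.0
                lam = amp * math.sqrt(2 * math.pi) * sd * 2
                n = rng.poisson(lam)
                modes = np.where(rng.random(n) < 0.5, site.center - 75, site.center + 75)
                draws = rng.normal(modes, sd)
            draws = np.rint(draws).astype(np.int64)
            parts.append(draws[(draws >= 0) & (draws < clen)])
        pos = np.concatenate(parts)
        positions[chrom] = np.sort(pos)
    return TagSet(stage=stage, replicate=replicate, positions=positions)


def simulate_all_tags(config: SimulationConfig) -> dict[int, list[TagSet]]:
    """All stages and replicates, keyed by stage."""
    return {
        stage: [simulate_tags(config, stage, r) for r in range(config.replicates_per_stage)]
        for stage in STAGES
    }


# ---------------------------------------------------------------------------
# Toy gene annotation
# ---------------------------------------------------------------------------

_TERMS = (
    "blastoderm", "ectoderm", "mesoderm", "endoderm",
    "nervous_system", "muscle", "epidermis", "gut",
)


def make_annotation(config: SimulationConfig) -> tuple[GenomeAnnotation, TruthTable]:
    """Place non-overlapping toy gene models and auxiliary truth labels.

    Each gene carries a 5'UTR, three CDS exons separated by introns (the
    middle exon long enough, with long enough flanking introns, to pass the
    peri-exonic filters), and a 3'UTR; strand is random.  A configurable
    fraction of promoters carries each core-promoter motif; CDS exons get
    early-expression values; genes get regulator flags and expression-pattern
    terms.  All assignments are recorded in the returned truth table.
    """
    rng = _rng_for(config, _ANNOT_STREAM)
    genome = config.genome
    n_genes = config.n_genes

    gene_rows, feat_rows, exon_rows = [], [], []
    gene_idx = 0
    chroms = genome.names
    per_chrom = [n_genes // len(chroms)] * len(chroms)
    for i in range(n_genes % len(chroms)):
        per_chrom[i] += 1
    for chrom, quota in zip(chroms, per_chrom):
        clen = genome.length(chrom)
        cursor = int(rng.integers(1000, 3000))
        placed = 0
        while placed < quota:
            u5 = int(rng.integers(150, 300))
            exon_lens = [int(rng.integers(350, 450)) for _ in range(3)]
            intron_lens = [int(rng.integers(400, 800)) for _ in range(2)]
            u3 = int(rng.integers(200, 400))
            span = u5 + sum(exon_lens) + sum(intron_lens) + u3
            if cursor + span > clen - 1000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{gene_idx:04d}"
            # lay parts left-to-right; on '-' the roles mirror
            parts = (
                [("five_utr", u5)]
                + [x for pair in zip(
                    [("cds", L) for L in exon_lens],
                    [("intron", L) for L in intron_lens] + [None],
                ) for x in pair if x is not None]
                + [("three_utr", u3)]
            )
            if strand == "-":
                parts = [(f, L) for f, L in reversed(parts)]
            pos = cursor
            for feat, L in parts:
                feat_rows.append((gid, chrom, strand, feat, pos, pos + L))
                if feat == "cds":
                    exon_rows.append((gid, chrom, pos, pos + L))
                pos += L
            tss = cursor if strand == "+" else pos - 1
            regulator = bool(rng.random() < config.regulator_fraction)
            gene_rows.append((gid, chrom, strand, cursor, pos, tss, regulator))
            cursor = pos + int(rng.integers(1500, 4000))
            placed += 1
            gene_idx += 1
    if gene_idx < n_genes:
        raise ValueError(
            f"genome too small: placed {gene_idx} of {n_genes} requested genes"
        )

    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss", "regulator"]
    )
    features = pd.DataFrame(
        feat_rows, columns=["gene_id", "chrom", "strand", "feature", "start", "end"]
    )
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])

    if n_genes == 0:
        motifs = pd.DataFrame(columns=list(CORE_PROMOTER_MOTIFS))
        exons["expression"] = pd.Series(dtype=float)
        terms = pd.DataFrame(columns=["gene_id", "term"])
    else:
        motifs = pd.DataFrame(
            {m: rng.random(n_genes) < frac for m, frac in config.motif_fractions},
            index=genes["gene_id"].to_numpy(),
        )
        exons["expression"] = np.round(rng.lognormal(mean=np.log(15.0), sigma=1.0,
                                                     size=len(exons)), 3)
        term_rows = []
        for gid in genes["gene_id"]:
            k = int(rng.integers(1, 3))
            for t in rng.choice(_TERMS, size=k, replace=False):
                term_rows.append((gid, str(t)))
        terms = pd.DataFrame(term_rows, columns=["gene_id", "term"])

    annot = GenomeAnnotation(
        genome=genome,
        genes=genes,
        features=features,
        promoter_motifs=motifs,
        exon_expression=exons,
        gene_terms=terms,
    )
    truth = TruthTable(
        sites=sites_truth_table(config),
        genes=genes.copy(),
        motifs=motifs.copy(),
        exon_expression=exons.copy(),
    )
    return annot, truth


# ---------------------------------------------------------------------------
# Conservation-style score track
# ---------------------------------------------------------------------------

def simulate_conservation(
    genome: Genome,
    dde_truth: pd.DataFrame,
    elevated_mean: float = 0.8,
    background_mean: float = 0.2,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-base score track in [0, 1], elevated over truth intervals.

    ``dde_truth`` needs chrom/start/end columns.  With ``noise_sd = 0`` the
    track is exactly ``background_mean`` outside and ``elevated_mean`` inside
    the truth intervals.
    """
    if not (math.isfinite(elevated_mean) and math.isfinite(background_mean)):
        raise ValueError("means must be finite")
    if elevated_mean < background_mean:
        raise ValueError("elevated_mean must be >= background_mean")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_CONS_STREAM,)))
    track: dict[str, np.ndarray] = {}
    for chrom in genome:
        clen = genome.length(chrom)
        arr = np.full(clen, background_mean, dtype=np.float32)
        sub = dde_truth[dde_truth["chrom"] == chrom] if len(dde_truth) else dde_truth
        for s, e in zip(sub["start"], sub["end"]) if len(sub) else []:
            arr[int(s) : int(e)] = elevated_mean
        if noise_sd > 0:
            arr = arr + rng.normal(0.0, noise_sd, size=clen).astype(np.float32)
            arr = np.clip(arr, 0.0, 1.0)
        track[chrom] = arr
    return track


# ---------------------------------------------------------------------------
# Site placement helpers and the packaged demo configuration
# ---------------------------------------------------------------------------

def make_planted_sites(
    genome: Genome,
    class_counts: dict[str, int],
    rng: np.random.Generator,
    width: int = 150,
    min_gap: int = 2000,
    region: tuple[str, int, int] | None = None,
    shape: str = "unimodal",
) -> list[PlantedSite]:
    """Place non-overlapping sites of the requested truth classes.

    Sites are laid down left to right with random gaps of at least
    ``min_gap`` bp, restricted to ``region`` when given, with classes
    interleaved in a deterministic shuffled order.
    """
    classes = [c for c, n in class_counts.items() for _ in range(n)]
    rng.shuffle(classes)
    if region is None:
        spans = [(c, 0, genome.length(c)) for c in genome]
    else:
        spans = [region]
    sites: list[PlantedSite] = []
    total_span = sum(e - s for _, s, e in spans)
    need = len(classes) * (width + min_gap)
    if need > total_span:
        raise ValueError("not enough room to place requested sites")
    i = 0
    for chrom, lo, hi in spans:
        quota = round(len(classes) * (hi - lo) / total_span)
        if chrom == spans[-1][0]:
            quota = len(classes) - i
        cursor = lo + int(rng.integers(min_gap // 2, min_gap))
        placed = 0
        while placed < quota and i < len(classes) and cursor + width < hi:
            cls = classes[i]
            sites.append(
                PlantedSite(
                    chrom=chrom,
                    start=cursor,
                    end=cursor + width,
                    truth_class=cls,
                    stage_profile=CLASS_PROFILES[cls],
                    shape=shape,
                )
            )
            cursor += width + int(rng.integers(min_gap, 2 * min_gap))
            i += 1
            placed += 1
    if i < len(classes):
        raise ValueError("not enough room to place requested sites")
    return sites


def default_demo_config(seed: int = 0) -> SimulationConfig:
    """The packaged desk-scale demo: a 0.8-Mb two-chromosome genome with a
    mixture of planted temporal classes plus one dense 30-kb cluster of
    early-patterned sites (a dynamic-domain analogue)."""
    genome = Genome({"chr2L": 400_000, "chr2R": 400_000})
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    # roughly one site per 4 kb, half constitutive — the density regime of
    # real accessible-site maps, which the rank statistic's local windows
    # implicitly assume
    counts = {
        "stage5": 10, "stage9": 6, "stage10": 6, "stage11": 10, "stage14": 20,
        "early": 14, "late": 14, "mixed": 8, "constitutive": 72,
    }
    sites = make_planted_sites(genome, counts, rng, min_gap=2200)
    # two dense dynamic-site clusters (domain analogues): similarly patterned
    # elements packed ~5x tighter than the genomic baseline
    early_cluster = make_planted_sites(
        genome, {"early": 20}, rng, min_gap=600, region=("chr2R", 300_000, 340_000)
    )
    late_cluster = make_planted_sites(
        genome, {"late": 20}, rng, min_gap=600, region=("chr2L", 300_000, 340_000)
    )
    # drop scattered sites colliding with the planted cluster regions
    sites = [
        s for s in sites
        if not (s.end > 295_000 and s.start < 345_000)
    ]
    return SimulationConfig(
        genome=genome,
        background_rate=0.05,
        planted_sites=tuple(sites + early_cluster + late_cluster),
        site_enrichment=5.0,
        replicates_per_stage=2,
        seed=seed,
        n_genes=50,
    )
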