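"""End-to-end orchestration of the analysis stages on one configuration.

``run_pipeline`` chains simulate -> density -> hotspots -> DHS -> dynamic
elements -> dynamic domains -> annotation statistics and writes every stage
output plus a summary report (per-stage DHS counts and genome percentage,
temporal-class tabulation, stage-of-origin composition).  One global integer
seed is split deterministically per stage; the report header records the
seed and the full parameter set.  Two runs with the same configuration
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import dhs as dhs_mod
from . import domains as dom
from . import io as cio
from . import rankexp as rx
from .density import STAGES, DensityTrack, average_tracks, bin_density
from .hotspots import HotspotParams, call_hotspots
from .intervals import max_pair_overlap
from .simulate import (
    SimulationConfig,
    default_demo_config,
    make_annotation,
    simulate_all_tags,
    simulate_conservation,
)

_HOTSPOT_STREAM, _DDD_STREAM, _CONS_STREAM, _CLUSTER_STREAM = 3, 4, 5, 6


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters with their documented method defaults
    (20-bp bins, 150-bp density window, 250-bp scan window over a 50-kb
    background, 1% region FDR, 75-bp replicate concordance, BH q = 0.05,
    10-kb domain radius, alpha = 0.05)."""

    seed: int = 0
    bin_size: int = 20
    window: int = 150
    scan_window: int = 250
    background_span: int = 50_000
    fdr: float = 0.01
    merge_gap: int = 250
    min_overlap: int = 75
    q_threshold: float = 0.05
    local_window: int = 10_001
    radius: int = 10_000
    n_boot: int = 10_000
    alpha: float = 0.05
    k_dde_clusters: int = 8
    k_promoters: int = 10
    k_exons: int = 4
    expr_threshold: float = 25.0
    tss_gene_bin: int = 200

    @classmethod
    def demo(cls, seed: int = 0) -> "RunConfig":
        """Desk-scale parameters matched to the packaged demo genome.

        The rank-expectation local window must stay well below the number of
        elevated bins so that top-of-ranking windows are dominated by
        comparably accessible bins; at the demo's 40,000-bin scale that means
        1,001 bins (the library default of 10,001 is proportioned to a full
        ~120-Mb genome).
        """
        return cls(seed=seed, local_window=1_001)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        params = cio.read_config(path)
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(params) - valid
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**params)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sub_seed(seed: int, stream: int, *key: int) -> int:
    state = np.random.SeedSequence(seed, spawn_key=(stream, *key)).generate_state(1)[0]
    return int(state % (2**31))


def run_pipeline(
    config: RunConfig,
    out_dir,
    sim_config: SimulationConfig | None = None,
) -> dict:
    """Execute the full pipeline and write the report bundle to ``out_dir``.

    When no simulation configuration is given, the packaged demo (0.8-Mb
    two-chromosome genome with planted temporal classes) seeded from
    ``config.seed`` is used.  Returns a dict of in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sim_config is None:
        sim_config = default_demo_config(config.seed)
    genome = sim_config.genome
    cio.write_config(
        {"seed": config.seed, **{k: v for k, v in config.to_dict().items() if k != "seed"}},
        out / "params.yaml",
    )

    # --- simulate -----------------------------------------------------------
    annot, truth = make_annotation(sim_config)
    tags = simulate_all_tags(sim_config)
    cio.write_table(truth.sites, out / "truth_sites.tsv")
    cio.write_gff(annot, out / "annotation.gff")

    # --- density ------------------------------------------------------------
    tracks: dict[int, list[DensityTrack]] = {}
    for stage in STAGES:
        tracks[stage] = []
        for rep, ts in enumerate(tags[stage]):
            track = bin_density(ts, genome, config.bin_size, config.window)
            track.stage = stage
            tracks[stage].append(track)
            cio.write_bedgraph(track, out / f"density_stage{stage}_rep{rep}.bedGraph")
    stage_mean_tracks = {}
    for stage in STAGES:
        mt = average_tracks(tracks[stage])
        mt.stage = stage
        stage_mean_tracks[stage] = mt

    # --- hotspots and DHSs --------------------------------------------------
    params = HotspotParams(
        scan_window=config.scan_window,
        background_span=config.background_span,
        fdr=config.fdr,
        merge_gap=config.merge_gap,
    )
    hotspot_diag = {}
    per_stage_dhs = {}
    per_stage_regions = {}
    for stage in STAGES:
        rep_dhs = []
        for rep, ts in enumerate(tags[stage]):
            regions, threshold, diag = call_hotspots(
                ts, genome, params,
                seed=_sub_seed(config.seed, _HOTSPOT_STREAM, STAGES.index(stage), rep),
            )
            hotspot_diag[(stage, rep)] = diag
            cio.write_bed(regions, out / f"regions_stage{stage}_rep{rep}.bed")
            rep_dhs.append(dhs_mod.call_dhs_peaks(tracks[stage][rep], regions))
            if rep == 0:
                per_stage_regions[stage] = regions
        concordant = dhs_mod.replicate_concordant(
            rep_dhs[0], rep_dhs[1], min_overlap=config.min_overlap
        )
        per_stage_dhs[stage] = concordant
        cio.write_bed(concordant, out / f"dhs_stage{stage}.bed")
    consensus = dhs_mod.stage_of_origin(dhs_mod.union_consensus(per_stage_dhs))
    cio.write_table(consensus, out / "consensus_dhs.tsv")
    origin = dhs_mod.origin_composition(consensus)
    cio.write_table(origin, out / "origin_composition.tsv")

    # --- dynamic elements ---------------------------------------------------
    ddes = rx.find_ddes(
        tracks, q_threshold=config.q_threshold, local_window=config.local_window
    )
    tabulation = rx.tabulate_classes(ddes) if len(ddes) else pd.DataFrame(
        columns=["temporal_class", "count", "percentage"]
    )
    cio.write_bed(ddes, out / "ddes.bed")
    cio.write_table(tabulation, out / "class_tabulation.tsv")
    clusters = None
    if len(ddes) >= 2:
        k = min(config.k_dde_clusters, len(ddes))
        clusters = rx.cluster_profiles(
            ddes, k, seed=_sub_seed(config.seed, _CLUSTER_STREAM)
        )
        labelled = ddes.copy()
        labelled["cluster"] = clusters["labels"]
        cio.write_table(labelled, out / "dde_clusters.tsv")

    # --- dynamic domains ----------------------------------------------------
    ddds = pd.DataFrame()
    rho_vals = np.empty(0)
    neighbor = {}
    tss_ranking = pd.DataFrame()
    if len(ddes):
        density = dom.dde_density(ddes, genome, radius=config.radius, bin_size=config.bin_size)
        null = dom.ddd_peak_null(
            ddes, genome, radius=config.radius, n_boot=config.n_boot,
            seed=_sub_seed(config.seed, _DDD_STREAM),
        )
        ddds = dom.call_ddds(
            density, null, genome, alpha=config.alpha, bin_size=config.bin_size, annot=annot
        )
        cio.write_table(ddds, out / "ddds.tsv")
        rho_vals = dom.dde_rhos(ddes)
        neighbor = {
            lag: dom.neighbor_pattern_test(rho_vals, lag=lag) for lag in (1, 2, 3)
        }
        tss_ranking = dom.tss_dde_density_ranking(
            annot.genes, density, bin_size_genes=config.tss_gene_bin,
            bin_size_bp=config.bin_size,
        )
        cio.write_table(tss_ranking, out / "tss_dde_ranking.tsv")

    # --- annotation statistics ---------------------------------------------
    categories = pd.Series(dtype=object)
    if len(consensus):
        categories = ann.assign_category(consensus, annot)
        cat_counts = categories.value_counts().reindex(ann.CATEGORY_ORDER, fill_value=0)
        cio.write_table(
            cat_counts.rename_axis("category").reset_index(name="count"),
            out / "dhs_categories.tsv",
        )
    prom = ann.promoter_profiles(stage_mean_tracks, annot)
    promoter_result = None
    n_nonzero = int((prom.to_numpy().max(axis=1) > 0).sum())
    if n_nonzero >= 2:
        promoter_result = ann.cluster_promoters(
            prom, k=min(config.k_promoters, n_nonzero),
            seed=_sub_seed(config.seed, _CLUSTER_STREAM, 1),
            motif_matrix=annot.promoter_motifs,
        )
        cio.write_table(promoter_result["assignments"], out / "promoter_clusters.tsv")
        if promoter_result["motif_stats"] is not None:
            cio.write_table(promoter_result["motif_stats"], out / "promoter_motif_stats.tsv")
    peri = ann.periexonic_analysis(
        stage_mean_tracks, annot, k=config.k_exons,
        expr_threshold=config.expr_threshold,
        seed=_sub_seed(config.seed, _CLUSTER_STREAM, 2),
    )
    if peri["elevated_fraction"] is not None:
        cio.write_table(
            peri["elevated_fraction"].rename("elevated_fraction").reset_index(),
            out / "periexonic_elevated.tsv",
        )
    crm_overlap = None
    if len(truth.sites):
        all_regions = pd.concat(list(per_stage_regions.values()), ignore_index=True)
        if len(all_regions):
            frac, pval = ann.overlap_binomial(truth.sites, all_regions, genome)
            crm_overlap = {"fraction": frac, "p_value": pval}
    conservation = None
    if len(ddes):
        cons_track = simulate_conservation(
            genome, truth.sites, seed=_sub_seed(config.seed, _CONS_STREAM)
        )
        if len(annot.cds_intervals()):
            noncoding = ddes[max_pair_overlap(ddes, annot.cds_intervals()) < 1]
        else:
            noncoding = ddes
        if len(noncoding):
            conservation = ann.conservation_compare(
                noncoding, cons_track, genome,
                seed=_sub_seed(config.seed, _CONS_STREAM, 1),
                allowed=annot.noncoding_intervals(),
            )

    _write_summary(
        out / "summary.txt", config, genome, per_stage_dhs, consensus, origin,
        tabulation, hotspot_diag, ddds, neighbor, crm_overlap, conservation,
    )
    return {
        "annotation": annot,
        "truth": truth,
        "tracks": tracks,
        "per_stage_dhs": per_stage_dhs,
        "consensus": consensus,
        "origin": origin,
        "ddes": ddes,
        "tabulation": tabulation,
        "clusters": clusters,
        "ddds": ddds,
        "rho": rho_vals,
        "neighbor": neighbor,
        "tss_ranking": tss_ranking,
        "categories": categories,
        "promoters": promoter_result,
        "periexonic": peri,
        "crm_overlap": crm_overlap,
        "conservation": conservation,
        "hotspot_diag": hotspot_diag,
    }


def _write_summary(path, config, genome, per_stage_dhs, consensus, origin,
                   tabulation, hotspot_diag, ddds, neighbor, crm_overlap,
                   conservation) -> None:
    with open(path, "w") as fh:
        fh.write("chromdyn pipeline summary\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write("parameters:\n")
        for k, v in sorted(config.to_dict().items()):
            fh.write(f"  {k}: {v}\n")
        fh.write(f"genome: {', '.join(genome.names)} ({genome.total_size} bp)\n\n")

        fh.write("Per-stage DHS landscape (replicate-concordant)\n")
        fh.write("stage\tdhs_count\tpercent_of_genome\n")
        for stage in STAGES:
            df = per_stage_dhs.get(stage, pd.DataFrame())
            bp = int((df["end"] - df["start"]).sum()) if len(df) else 0
            fh.write(f"{stage}\t{len(df)}\t{100.0 * bp / genome.total_size:.2f}\n")
        if len(consensus):
            bp = int((consensus["end"] - consensus["start"]).sum())
            fh.write(f"all\t{len(consensus)}\t{100.0 * bp / genome.total_size:.2f}\n")
        fh.write("\nStage-of-origin composition (percent of stage's DHSs)\n")
        fh.write(origin.to_csv(sep="\t", index=False, float_format="%.2f"))
        fh.write("\nTemporal class tabulation\n")
        fh.write(tabulation.to_csv(sep="\t", index=False, float_format="%.2f"))
        fh.write("\nHotspot calling diagnostics\n")
        for (stage, rep), diag in sorted(hotspot_diag.items()):
            fh.write(
                f"stage {stage} rep {rep}: T={diag['threshold']:.3f} "
                f"observed={diag['n_observed_regions']} random={diag['n_random_regions']} "
                f"ratio={diag['realized_region_ratio']:.4f}\n"
            )
        fh.write(f"\nDynamic domains called: {len(ddds)}\n")
        for lag, res in neighbor.items():
            fh.write(
                f"neighbor pattern test lag {lag}: {res['successes']}/{res['n_pairs']} "
                f"p={res['p_value']:.3g}\n"
            )
        if crm_overlap is not None:
            fh.write(
                f"planted-site overlap with accessible regions: "
                f"{100 * crm_overlap['fraction']:.1f}% p={crm_overlap['p_value']:.3g}\n"
            )
        if conservation is not None:
            e, r = conservation["elements"], conservation["random"]
            fh.write(
                f"conservation medians: elements {e['median']:.3f} "
                f"[{e['ci_low']:.3f}, {e['ci_high']:.3f}] vs random {r['median']:.3f} "
                f"[{r['ci_low']:.3f}, {r['ci_high']:.3f}]\n"
            )
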