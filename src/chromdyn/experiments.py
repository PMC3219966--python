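"""Calibration and recovery experiments on planted synthetic data.

Each function builds its own simulation at the stated study conditions, runs
the relevant pipeline stage, and scores the result against the planted
truth.  These are the quantitative checks behind the package's validation
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dhs as dhs_mod
from . import domains as dom
from . import rankexp as rx
from .density import STAGES, bin_density
from .genome import Genome
from .hotspots import HotspotParams, call_hotspots
from .intervals import overlaps_any
from .simulate import (
    CLASS_PROFILES,
    PlantedSite,
    SimulationConfig,
    make_planted_sites,
    simulate_tags,
)


def _spread_sites(genome: Genome, n: int, truth_class: str, width: int = 150,
                  margin: int = 10_000) -> list[PlantedSite]:
    """n evenly spaced sites of one class across the genome."""
    sites = []
    total = genome.total_size
    step = (total - 2 * margin) // n
    offset = margin
    for chrom in genome:
        clen = genome.length(chrom)
        while offset + width < clen - margin and len(sites) < n:
            sites.append(
                PlantedSite(
                    chrom=chrom,
                    start=offset,
                    end=offset + width,
                    truth_class=truth_class,
                    stage_profile=CLASS_PROFILES[truth_class],
                )
            )
            offset += step
        offset -= clen
        offset = max(offset, margin)
    return sites


def hotspot_fdr_calibration(
    seeds=range(1, 21),
    genome_size: int = 1_000_000,
    background_rate: float = 0.05,
    fdr: float = 0.01,
) -> dict:
    """Realized random/observed region ratios on background-only simulations.

    One uniform-background tag set per seed (expected 50,000 tags on 1 Mb at
    the default rate); the realized ratio at the chosen threshold is 0 when
    no region is called.
    """
    genome = Genome({"chr": genome_size})
    params = HotspotParams(fdr=fdr)
    ratios = []
    for seed in seeds:
        config = SimulationConfig(genome=genome, background_rate=background_rate, seed=seed)
        tags = simulate_tags(config, stage=5, replicate=0)
        _, _, diag = call_hotspots(tags, genome, params, seed=seed + 100_000)
        ratios.append(diag["realized_region_ratio"])
    return {"ratios": ratios, "median_ratio": float(np.median(ratios))}


def hotspot_planted_recall(
    seeds=range(1, 21),
    genome_size: int = 1_000_000,
    background_rate: float = 0.05,
    n_sites: int = 50,
    enrichment: float = 5.0,
    fdr: float = 0.01,
) -> dict:
    """Pooled recall of planted 5x sites over replicate simulation runs.

    Each run plants ``n_sites`` constitutive sites on a fresh background and
    calls FDR-controlled regions; recall pools the planted sites of all
    runs.
    """
    genome = Genome({"chr": genome_size})
    sites = _spread_sites(genome, n_sites, "constitutive")
    truth = pd.DataFrame(
        [(s.chrom, s.start, s.end) for s in sites], columns=["chrom", "start", "end"]
    )
    params = HotspotParams(fdr=fdr)
    hits = 0
    total = 0
    per_run = []
    for seed in seeds:
        config = SimulationConfig(
            genome=genome,
            background_rate=background_rate,
            planted_sites=tuple(sites),
            site_enrichment=enrichment,
            seed=seed,
        )
        tags = simulate_tags(config, stage=5, replicate=0)
        regions, threshold, diag = call_hotspots(tags, genome, params, seed=seed + 200_000)
        recalled = overlaps_any(truth, regions, min_overlap=1)
        hits += int(recalled.sum())
        total += len(truth)
        per_run.append(float(recalled.mean()))
    return {
        "recall": hits / total,
        "per_run": per_run,
        "n_runs": len(per_run),
    }


def _stage_tracks(config: SimulationConfig):
    tracks = {}
    for stage in STAGES:
        tracks[stage] = [
            bin_density(simulate_tags(config, stage, rep), config.genome)
            for rep in range(config.replicates_per_stage)
        ]
    return tracks


def rank_expectation_null(
    seed: int = 1,
    genome_size: int = 500_000,
    background_rate: float = 0.05,
    q_threshold: float = 0.05,
    local_window: int = 5_001,
) -> dict:
    """Type-I behaviour: fraction of bins flagged when the compared stages
    share an identical (background-only) cleavage intensity."""
    genome = Genome({"chr": genome_size})
    config = SimulationConfig(genome=genome, background_rate=background_rate, seed=seed)
    a = [bin_density(simulate_tags(config, 5, r), genome) for r in range(2)]
    b = [bin_density(simulate_tags(config, 9, r), genome) for r in range(2)]
    pvals = [
        rx.rank_expectation(x.flatten()[0], y.flatten()[0], local_window=local_window)
        for x in a
        for y in b
    ]
    flags = rx.consistent_enrichment(pvals, q_threshold)
    n_tested = int((~np.isnan(pvals[0])).sum())
    return {
        "flag_fraction": float(flags.sum() / max(n_tested, 1)),
        "n_bins": n_tested,
    }


def dde_power(
    seed: int = 1,
    genome_size: int = 1_000_000,
    background_rate: float = 0.05,
    n_sites: int = 40,
    enrichment: float = 4.0,
    q_threshold: float = 0.05,
    local_window: int = 10_001,
) -> dict:
    """Recovery of planted stage-5-specific sites as correctly classified
    dynamic elements (4-fold sites by default)."""
    genome = Genome({"chr": genome_size})
    sites = _spread_sites(genome, n_sites, "stage5")
    config = SimulationConfig(
        genome=genome,
        background_rate=background_rate,
        planted_sites=tuple(sites),
        site_enrichment=enrichment,
        seed=seed,
    )
    tracks = _stage_tracks(config)
    ddes = rx.find_ddes(tracks, q_threshold=q_threshold, local_window=local_window)
    truth = pd.DataFrame(
        [(s.chrom, s.start, s.end) for s in sites], columns=["chrom", "start", "end"]
    )
    if len(ddes) == 0:
        return {"recall": 0.0, "class_accuracy": 0.0, "n_ddes": 0}
    hit = overlaps_any(truth, ddes, min_overlap=1)
    stage5_ddes = ddes[ddes["temporal_class"] == "stage5"]
    hit_correct = (
        overlaps_any(truth, stage5_ddes, min_overlap=1) if len(stage5_ddes) else np.zeros(len(truth), bool)
    )
    recalled = int(hit.sum())
    return {
        "recall": float(hit.mean()),
        "class_accuracy": float(hit_correct.sum() / recalled) if recalled else 0.0,
        "n_ddes": len(ddes),
    }


def ddd_recovery(
    seed: int = 1,
    genome_size: int = 2_000_000,
    n_cluster: int = 20,
    cluster_span: int = 30_000,
    n_boot: int = 10_000,
    alpha: float = 0.05,
) -> dict:
    """Recovery of one planted 30-kb cluster of 20 DDEs as a single domain."""
    genome = Genome({"chr": genome_size})
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cluster_start = genome_size // 2
    starts = np.sort(
        rng.choice(cluster_span // 200, size=n_cluster, replace=False) * 200
    ) + cluster_start
    ddes = pd.DataFrame(
        {"chrom": "chr", "start": starts, "end": starts + 150}
    )
    density = dom.dde_density(ddes, genome)
    null = dom.ddd_peak_null(ddes, genome, n_boot=n_boot, seed=seed + 1)
    ddds = dom.call_ddds(density, null, genome, alpha=alpha)
    overlap = (
        overlaps_any(
            pd.DataFrame(
                [("chr", cluster_start, cluster_start + cluster_span)],
                columns=["chrom", "start", "end"],
            ),
            ddds,
        )[0]
        if len(ddds)
        else False
    )
    return {"n_domains": len(ddds), "overlaps_truth": bool(overlap)}


def ddd_null_calibration(
    seeds=range(1, 21),
    genome_size: int = 2_000_000,
    n_ddes: int = 100,
    n_boot: int = 10_000,
    alpha: float = 0.05,
) -> dict:
    """False-positive runs when DDEs are scattered uniformly (no clustering)."""
    genome = Genome({"chr": genome_size})
    fp_runs = 0
    for seed in seeds:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
        starts = np.sort(rng.integers(0, genome_size - 200, size=n_ddes))
        ddes = pd.DataFrame({"chrom": "chr", "start": starts, "end": starts + 150})
        density = dom.dde_density(ddes, genome)
        null = dom.ddd_peak_null(ddes, genome, n_boot=n_boot, seed=seed + 10_000)
        ddds = dom.call_ddds(density, null, genome, alpha=alpha)
        if len(ddds):
            fp_runs += 1
    return {"n_runs": len(list(seeds)), "false_positive_runs": fp_runs}


def origin_recovery(
    seed: int = 1,
    genome_size: int = 1_000_000,
    n_sites: int = 60,
    carried_fraction: float = 0.55,
    enrichment: float = 6.0,
) -> dict:
    """Stage-of-origin recovery when a known fraction of stage-14 sites were
    planted from stage 5 (the developmental-propagation readout)."""
    genome = Genome({"chr": genome_size})
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(8,)))
    n_carried = round(n_sites * carried_fraction)
    counts = {"constitutive": n_carried, "stage14": n_sites - n_carried}
    sites = make_planted_sites(genome, counts, rng, min_gap=8000)
    config = SimulationConfig(
        genome=genome, planted_sites=tuple(sites), site_enrichment=enrichment, seed=seed
    )
    params = HotspotParams()
    per_stage = {}
    for stage in STAGES:
        rep_dhs = []
        for rep in range(2):
            tags = simulate_tags(config, stage, rep)
            track = bin_density(tags, genome)
            track.stage = stage
            regions, _, _ = call_hotspots(
                tags, genome, params, seed=seed + 300_000 + 10 * STAGES.index(stage) + rep
            )
            rep_dhs.append(dhs_mod.call_dhs_peaks(track, regions))
        per_stage[stage] = dhs_mod.replicate_concordant(rep_dhs[0], rep_dhs[1])
    consensus = dhs_mod.stage_of_origin(dhs_mod.union_consensus(per_stage))
    truth = pd.DataFrame(
        [(s.chrom, s.start, s.end) for s in sites], columns=["chrom", "start", "end"]
    )
    at14 = consensus[consensus["present_14"]]
    at14 = at14[overlaps_any(at14, truth, min_overlap=1)]
    if len(at14) == 0:
        return {"origin5_fraction": float("nan"), "n_stage14": 0}
    frac = float((at14["origin_stage"] == 5).mean())
    return {"origin5_fraction": frac, "n_stage14": len(at14)}
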