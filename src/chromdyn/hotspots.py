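"""FDR-controlled accessible-region calling via a binomial scan statistic.

For each cleavage tag, the number of tags in a 250-bp window centred on it is
compared with the expectation under a binomial model of the surrounding 50 kb:
with ``n_L`` background tags and success probability ``p = W / L_effective``,

    z = (n_w - n_L * p) / sqrt(n_L * p * (1 - p)).

The calling threshold ``T`` is set empirically: the smallest observed z value
such that a matched uniform-random tag set yields at most ``fdr`` times as
many scores >= T as the experimental set does.  Tags with z >= T are merged
into accessible regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import TagSet
from .genome import Genome


class EmptyBackground(Exception):
    """Raised when a scan position has no tags in its background window.

    The z-score is undefined there; callers should skip the position.
    """


@dataclass(frozen=True)
class HotspotParams:
    """Scan-statistic parameters.

    ``scan_window`` (W) and ``background_span`` (L) are in bp; ``fdr`` is the
    target fraction of random-set calls; ``merge_gap`` is the maximum distance
    between qualifying tags merged into one region (defaults to W, which
    reproduces tag contiguity at the scan scale).  ``dedupe`` optionally
    collapses identical cleavage positions before scanning.
    """

    scan_window: int = 250
    background_span: int = 50_000
    fdr: float = 0.01
    merge_gap: int = 250
    dedupe: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")
        if self.scan_window >= self.background_span:
            raise ValueError("scan window must be smaller than background span")
        if self.scan_window <= 0 or self.merge_gap < 0:
            raise ValueError("invalid window/merge_gap")


def _window_counts(pos: np.ndarray, at: np.ndarray, span: float, clen: int, truncate: bool):
    """Tag counts in span-bp windows centred at ``at``, truncated at [0, clen)."""
    at = np.asarray(at, dtype=np.float64)
    lo = at - span / 2.0
    hi = at + span / 2.0
    if truncate:
        lo = np.maximum(lo, 0.0)
        hi = np.minimum(hi, float(clen))
    counts = np.searchsorted(pos, np.ceil(hi)) - np.searchsorted(pos, np.ceil(lo))
    return counts, hi - lo


def zscores_at(
    tags: TagSet, genome: Genome, params: HotspotParams, chrom: str, at: np.ndarray
) -> np.ndarray:
    """Vectorised scan z-scores at positions ``at`` on one chromosome.

    Positions with an empty (or degenerate) background window get NaN.
    """
    pos = tags.chrom_tags(chrom)
    if params.dedupe:
        pos = np.unique(pos)
    clen = genome.length(chrom)
    n_w, _ = _window_counts(pos, at, params.scan_window, clen, truncate=False)
    n_l, l_eff = _window_counts(pos, at, params.background_span, clen, truncate=True)
    p = params.scan_window / l_eff
    var = n_l * p * (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (n_w - n_l * p) / np.sqrt(var)
    z = np.asarray(z, dtype=np.float64)
    z[(n_l == 0) | (var <= 0)] = np.nan
    return z


def scan_z(tags: TagSet, genome: Genome, params: HotspotParams, chrom: str, at: int) -> float:
    """Enrichment z-score of the scan window centred at one position.

    Raises :class:`EmptyBackground` when no tag falls in the (truncated)
    background window, signalling that the position should be skipped.
    """
    z = zscores_at(tags, genome, params, chrom, np.array([at]))[0]
    if np.isnan(z):
        raise EmptyBackground(f"{chrom}:{at} has an empty background window")
    return float(z)


def tag_zscores(tags: TagSet, genome: Genome, params: HotspotParams) -> dict[str, np.ndarray]:
    """z-score of every tag's own scan window, per chromosome."""
    out = {}
    for chrom in genome:
        pos = tags.chrom_tags(chrom)
        if params.dedupe:
            pos = np.unique(pos)
        out[chrom] = zscores_at(tags, genome, params, chrom, pos)
    return out


def fdr_threshold(observed_z, random_z, fdr: float) -> float:
    """Empirical FDR threshold T over candidate observed z values.

    Returns the smallest observed z with
    ``|{random >= T}| / |{observed >= T}| <= fdr``, or ``+inf`` when no
    candidate qualifies (zero calls).  NaN scores are dropped.
    """
    obs = np.sort(np.asarray(observed_z, dtype=np.float64))
    obs = obs[~np.isnan(obs)]
    if len(obs) == 0:
        raise ValueError("observed z list is empty")
    rand = np.sort(np.asarray(random_z, dtype=np.float64))
    rand = rand[~np.isnan(rand)]
    candidates = np.unique(obs)
    n_obs_ge = len(obs) - np.searchsorted(obs, candidates, side="left")
    n_rand_ge = len(rand) - np.searchsorted(rand, candidates, side="left")
    ok = n_rand_ge <= fdr * n_obs_ge
    if not ok.any():
        return float("inf")
    return float(candidates[ok.argmax()])


def _region_count_events(pos: np.ndarray, z: np.ndarray, merge_gap: int):
    """(z, delta) events describing the region count as tags activate.

    Tags are activated in descending z order; activating a tag creates a new
    region (+1), extends one (0), or bridges two (-1) depending on whether an
    already-active tag lies within ``merge_gap`` on either side.  The number
    of regions formed by tags with z >= T is the sum of deltas of events with
    z >= T.
    """
    ok = ~np.isnan(z)
    pos = pos[ok]
    zz = z[ok]
    order = np.argsort(-zz, kind="stable")
    active = np.zeros(len(pos), dtype=bool)
    parent = np.arange(len(pos))

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    ev_z = np.empty(len(pos))
    ev_d = np.empty(len(pos), dtype=np.int64)
    for n, i in enumerate(order):
        left = -1
        j = i - 1
        while j >= 0 and pos[i] - pos[j] <= merge_gap:
            if active[j]:
                left = j
                break
            j -= 1
        right = -1
        j = i + 1
        while j < len(pos) and pos[j] - pos[i] <= merge_gap:
            if active[j]:
                right = j
                break
            j += 1
        active[i] = True
        roots = {find(j) for j in (left, right) if j >= 0}
        delta = 1 - len(roots)  # new region, extension, or bridge
        for r in roots:
            parent[r] = i
        ev_z[n] = zz[i]
        ev_d[n] = delta
    return ev_z, ev_d


def _region_counts_at(events: list[tuple[np.ndarray, np.ndarray]], thresholds: np.ndarray):
    """Region counts at each threshold, from per-chromosome event streams."""
    ez = np.concatenate([e[0] for e in events]) if events else np.empty(0)
    ed = np.concatenate([e[1] for e in events]) if events else np.empty(0, dtype=np.int64)
    order = np.argsort(-ez, kind="stable")
    ez = ez[order]
    ed = ed[order]
    cum = np.concatenate([[0], np.cumsum(ed)])
    # events with z >= T: ez is descending; count via searchsorted on -ez
    k = np.searchsorted(-ez, -np.asarray(thresholds), side="right")
    return cum[k]


def region_fdr_threshold(
    tags: TagSet,
    rand_tags: TagSet,
    genome: Genome,
    params: HotspotParams,
    obs_z: dict[str, np.ndarray],
    rand_z: dict[str, np.ndarray],
) -> float:
    """FDR threshold with *region-level* counting.

    Candidate thresholds are the observed tag z values; at each candidate the
    number of merged regions formed by qualifying observed tags is compared
    with the number formed by qualifying random tags, and the smallest T with
    ``random_regions <= fdr * observed_regions`` is returned (+inf when none
    qualifies).  This matches defining accessible regions as tag collections
    and controlling the FDR on region counts.
    """
    def events_for(ts: TagSet, zmap):
        evs = []
        for chrom in genome:
            pos = ts.chrom_tags(chrom)
            if params.dedupe:
                pos = np.unique(pos)
            evs.append(_region_count_events(pos, zmap[chrom], params.merge_gap))
        return evs

    obs_flat = np.concatenate([obs_z[c] for c in genome])
    obs_flat = obs_flat[~np.isnan(obs_flat)]
    if len(obs_flat) == 0:
        raise ValueError("observed z list is empty")
    candidates = np.unique(obs_flat)
    n_obs = _region_counts_at(events_for(tags, obs_z), candidates)
    n_rand = _region_counts_at(events_for(rand_tags, rand_z), candidates)
    ok = (n_obs > 0) & (n_rand <= params.fdr * n_obs)
    if not ok.any():
        return float("inf")
    return float(candidates[ok.argmax()])


def uniform_random_tags(tags: TagSet, genome: Genome, rng: np.random.Generator) -> TagSet:
    """Uniform-random tag set matching per-chromosome tag totals (the FDR null)."""
    positions = {
        chrom: np.sort(rng.integers(0, genome.length(chrom), size=len(tags.chrom_tags(chrom))))
        for chrom in genome
    }
    return TagSet(stage=tags.stage, replicate=tags.replicate, positions=positions)


def call_accessible_regions(
    tags: TagSet,
    genome: Genome,
    params: HotspotParams,
    threshold: float,
    zscores: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Merge tags with z >= threshold into accessible regions.

    Qualifying tags within ``merge_gap`` bp of each other are merged; each
    region spans first to last qualifying tag, expanded by W/2 on both sides
    (clipped to the chromosome).  Returns a DataFrame with columns
    ``chrom, start, end, max_z, tag_count``.
    """
    if zscores is None:
        zscores = tag_zscores(tags, genome, params)
    half = params.scan_window // 2
    rows = []
    for chrom in genome:
        pos = tags.chrom_tags(chrom)
        if params.dedupe:
            pos = np.unique(pos)
        z = zscores[chrom]
        keep = ~np.isnan(z) & (z >= threshold)
        if not keep.any():
            continue
        qpos = pos[keep]
        qz = z[keep]
        breaks = np.flatnonzero(np.diff(qpos) > params.merge_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(qpos) - 1]])
        clen = genome.length(chrom)
        for a, b in zip(starts, ends):
            lo = max(0, int(qpos[a]) - half)
            hi = min(clen, int(qpos[b]) + half)
            n_in = int(np.searchsorted(pos, hi) - np.searchsorted(pos, lo))
            rows.append((chrom, lo, hi, float(qz[a : b + 1].max()), n_in))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "max_z", "tag_count"])


def call_hotspots(
    tags: TagSet,
    genome: Genome,
    params: HotspotParams,
    seed: int,
) -> tuple[pd.DataFrame, float, dict]:
    """End-to-end hotspot calling for one tag set.

    Scans the observed tags, builds a matched uniform-random tag set from
    ``seed``, picks the FDR threshold, and calls regions.  Returns
    ``(regions, threshold, diagnostics)`` where diagnostics reports the
    realized random/observed region counts at the chosen threshold.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    obs_z = tag_zscores(tags, genome, params)
    rand_tags = uniform_random_tags(tags, genome, rng)
    rand_z = tag_zscores(rand_tags, genome, params)
    threshold = region_fdr_threshold(tags, rand_tags, genome, params, obs_z, rand_z)
    regions = call_accessible_regions(tags, genome, params, threshold, zscores=obs_z)
    rand_regions = call_accessible_regions(rand_tags, genome, params, threshold, zscores=rand_z)
    diag = {
        "threshold": threshold,
        "n_observed_regions": len(regions),
        "n_random_regions": len(rand_regions),
        "realized_region_ratio": (len(rand_regions) / len(regions)) if len(regions) else 0.0,
    }
    return regions, threshold, diag
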