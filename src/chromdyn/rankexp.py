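"""The rank-expectation differential statistic and dynamic-element calling.

To ask whether signal A is enriched over signal B at 20-bp resolution, the
bins of B are ranked from low to high (ties broken by genomic order) and A
is permuted into that order, giving A'.  In A', a bin sits among bins whose
B-scores resemble its own; if A greatly exceeds B somewhere, that bin's A'
value is an outlier against its local neighbourhood.  Each position is
scored by a Gaussian z against the local median and MAD (scaled by 1.4826
for normal consistency) of a large centred window of A', and a one-sided
upper-tail p-value is mapped back to genomic bins.

Each ordered stage pair has four replicate cross-comparisons; a bin shows
"consistent enrichment" when at least three of the four are significant
under Benjamini-Hochberg control.  Adjacent bins with identical enrichment
signatures across all 20 ordered stage pairs merge into developmentally
dynamic elements (DDEs), which are then assigned a temporal class and can be
clustered by their five-stage profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from ._rolling import rolling_median_mad
from .density import STAGES, DensityTrack, average_tracks

#: Gaussian-consistency constant: 1.4826 * MAD estimates a normal sigma.
MAD_SCALE = 1.4826

#: All 20 ordered stage pairs (s, t) meaning "s enriched over t".
ORDERED_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (s, t) for s in STAGES for t in STAGES if s != t
)

#: Temporal classes in reporting order.
CLASS_ORDER = ("stage5", "stage9", "stage10", "stage11", "stage14", "early", "late", "mixed")


def rank_expectation(
    a: np.ndarray,
    b: np.ndarray,
    local_window: int = 10_001,
    exclude_both_zero: bool = True,
) -> np.ndarray:
    """Per-bin one-sided p-values for "a enriched over b".

    Bins where both signals are zero are excluded from ranking (the genome is
    mostly empty; massive zero ties would swamp the local windows) and get
    NaN; pass ``exclude_both_zero=False`` to keep them.  Where the local MAD
    is zero the z-score is defined as 0 (p = 0.5).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("signals must be 1-D and of equal length")
    if local_window % 2 == 0:
        raise ValueError("local_window must be odd")
    if local_window < 101:
        raise ValueError("local_window must be at least 101 bins")
    mask = np.ones(len(a), dtype=bool) if not exclude_both_zero else ~((a == 0) & (b == 0))
    out = np.full(len(a), np.nan)
    ai = a[mask]
    bi = b[mask]
    if len(ai) == 0:
        return out
    order = np.argsort(bi, kind="stable")
    aprime = ai[order]
    med, mad = rolling_median_mad(aprime, local_window)
    s = MAD_SCALE * mad
    z = np.where(s > 0, (aprime - med) / np.where(s > 0, s, 1.0), 0.0)
    p_prime = stats.norm.sf(z)
    p_masked = np.empty(len(ai))
    p_masked[order] = p_prime
    out[mask] = p_masked
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaN entries pass through."""
    p = np.asarray(p, dtype=np.float64)
    out = np.full(len(p), np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def bh_significant(p: np.ndarray, q_threshold: float) -> np.ndarray:
    q = bh_adjust(p)
    return np.where(np.isnan(q), False, q <= q_threshold)


def consistent_enrichment(pvals: list[np.ndarray], q_threshold: float = 0.05) -> np.ndarray:
    """Per-bin flag: at least 3 of the 4 replicate cross-comparisons are
    BH-significant at ``q_threshold``."""
    if len(pvals) != 4:
        raise ValueError(f"need the 4 replicate cross-comparisons, got {len(pvals)}")
    votes = np.zeros(len(pvals[0]), dtype=np.int64)
    for p in pvals:
        votes += bh_significant(p, q_threshold).astype(np.int64)
    return votes >= 3


def stage_pair_flags(
    tracks: dict[int, list[DensityTrack]],
    q_threshold: float = 0.05,
    local_window: int = 10_001,
) -> dict[tuple[int, int], np.ndarray]:
    """Consistent-enrichment flags for all 20 ordered stage pairs.

    ``tracks[stage]`` holds the replicate density tracks of a stage; the four
    measurements for pair (s, t) are rank_expectation(s_i, t_j) over replicate
    combinations.
    """
    flat = {
        s: [t.flatten()[0] for t in reps] for s, reps in tracks.items()
    }
    flags = {}
    for s, t in ORDERED_PAIRS:
        pvals = [
            rank_expectation(a, b, local_window=local_window)
            for a in flat[s]
            for b in flat[t]
        ]
        flags[(s, t)] = consistent_enrichment(pvals, q_threshold)
    return flags


def classify_temporal(enrich: dict[tuple[int, int], bool], densities: dict[int, float]) -> str:
    """Temporal class of one element from its enrichment matrix and per-stage
    densities.

    Stage-s-specific when s is enriched over every other stage; otherwise
    early (peak density in stages 5-10 with no later-over-earlier
    enrichment), late (peak in stages 11-14 with no earlier-over-later
    enrichment), else mixed.
    """
    if not enrich:
        raise ValueError("empty enrichment matrix")
    for s in STAGES:
        if all(enrich.get((s, t), False) for t in STAGES if t != s):
            return f"stage{s}"
    dens = np.array([densities[s] for s in STAGES])
    if dens.sum() <= 0:
        return "mixed"
    peak = STAGES[int(np.argmax(dens))]
    later_over_earlier = any(
        enrich.get((x, y), False)
        for i, x in enumerate(STAGES)
        for j, y in enumerate(STAGES)
        if i > j
    )
    earlier_over_later = any(
        enrich.get((x, y), False)
        for i, x in enumerate(STAGES)
        for j, y in enumerate(STAGES)
        if i < j
    )
    if peak in (5, 9, 10) and not later_over_earlier:
        return "early"
    if peak in (11, 14) and not earlier_over_later:
        return "late"
    return "mixed"


def merge_dde_bins(
    flags: dict[tuple[int, int], np.ndarray],
    tracks: dict[int, list[DensityTrack]],
) -> pd.DataFrame:
    """Merge adjacent 20-bp bins with identical enrichment signatures into
    DDEs, attaching per-stage mean densities and a temporal class.

    Returns a DataFrame with chrom/start/end, ``signature`` (20-character
    0/1 string in :data:`ORDERED_PAIRS` order), per-stage densities ``d5 ..
    d14`` and ``temporal_class``.
    """
    missing = [p for p in ORDERED_PAIRS if p not in flags]
    if missing:
        raise ValueError(f"flags missing for stage pairs {missing[:3]}...")
    ref = tracks[STAGES[0]][0]
    _, slices = ref.flatten()
    stage_means = {s: average_tracks(reps).flatten()[0] for s, reps in tracks.items()}
    sig = np.stack([flags[p] for p in ORDERED_PAIRS], axis=1)
    codes = sig.astype(np.int64) @ (1 << np.arange(len(ORDERED_PAIRS), dtype=np.int64))
    changed = sig.any(axis=1)
    bin_size = ref.bin_size

    rows = []
    for chrom in ref.genome:
        sl = slices[chrom]
        ch_changed = changed[sl]
        ch_codes = codes[sl]
        idx = np.flatnonzero(ch_changed)
        if len(idx) == 0:
            continue
        new_run = np.ones(len(idx), dtype=bool)
        new_run[1:] = (np.diff(idx) != 1) | (ch_codes[idx[1:]] != ch_codes[idx[:-1]])
        run_ids = np.cumsum(new_run) - 1
        for run in range(run_ids[-1] + 1):
            members = idx[run_ids == run]
            b0, b1 = int(members[0]), int(members[-1])
            code = int(ch_codes[b0])
            signature = "".join(
                "1" if (code >> k) & 1 else "0" for k in range(len(ORDERED_PAIRS))
            )
            enrich = {
                pair: bool((code >> k) & 1) for k, pair in enumerate(ORDERED_PAIRS)
            }
            dens = {
                s: float(stage_means[s][sl][b0 : b1 + 1].mean()) for s in STAGES
            }
            rows.append(
                (
                    chrom,
                    b0 * bin_size,
                    (b1 + 1) * bin_size,
                    signature,
                    *[dens[s] for s in STAGES],
                    classify_temporal(enrich, dens),
                )
            )
    cols = (
        ["chrom", "start", "end", "signature"]
        + [f"d{s}" for s in STAGES]
        + ["temporal_class"]
    )
    return pd.DataFrame(rows, columns=cols)


def find_ddes(
    tracks: dict[int, list[DensityTrack]],
    q_threshold: float = 0.05,
    local_window: int = 10_001,
) -> pd.DataFrame:
    """Full dynamic-element calling: 80 rank-expectation comparisons, 3-of-4
    voting per ordered stage pair, signature merging and classification."""
    flags = stage_pair_flags(tracks, q_threshold=q_threshold, local_window=local_window)
    return merge_dde_bins(flags, tracks)


def tabulate_classes(ddes, total: int | None = None) -> pd.DataFrame:
    """Per-class counts and percentages of total (2 decimals).

    Accepts a DDE DataFrame (with ``temporal_class``) or a mapping of class
    name to count — the latter reproduces reference-table arithmetic from
    printed counts.  ``total`` overrides the denominator when the listed
    classes are known not to be exhaustive (percentages then sum to <= 100).
    """
    if isinstance(ddes, pd.DataFrame):
        if len(ddes) == 0:
            raise ValueError("no elements to tabulate")
        counts = ddes["temporal_class"].value_counts().to_dict()
    else:
        counts = dict(ddes)
        if not counts:
            raise ValueError("no elements to tabulate")
    if total is None:
        total = sum(counts.values())
    elif total < sum(counts.values()):
        raise ValueError("total cannot be smaller than the summed counts")
    order = [c for c in CLASS_ORDER if c in counts] + [
        c for c in counts if c not in CLASS_ORDER
    ]
    rows = [(c, counts[c], round(100.0 * counts[c] / total, 2)) for c in order]
    return pd.DataFrame(rows, columns=["temporal_class", "count", "percentage"])


def cluster_profiles(ddes: pd.DataFrame, k: int, seed: int = 0) -> dict:
    """k-means clustering of unit-max-normalised five-stage DDE profiles,
    with clusters relabelled by the stage of their mean profile's peak."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ddes):
        raise ValueError(f"k={k} exceeds {len(ddes)} elements")
    prof = ddes[[f"d{s}" for s in STAGES]].to_numpy(dtype=float)
    maxes = prof.max(axis=1)
    maxes[maxes == 0] = 1.0
    norm = prof / maxes[:, None]
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw_labels = km.fit_predict(norm)
    centers = km.cluster_centers_
    # order clusters by the stage of peak mean accessibility, then peak index
    peak_stage = centers.argmax(axis=1)
    rank = np.lexsort((np.arange(k), peak_stage))
    relabel = np.empty(k, dtype=np.int64)
    relabel[rank] = np.arange(k)
    labels = relabel[raw_labels]
    mean_profiles = pd.DataFrame(
        centers[rank], columns=[f"d{s}" for s in STAGES]
    )
    mean_profiles.index.name = "cluster"
    return {"labels": labels, "mean_profiles": mean_profiles}
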