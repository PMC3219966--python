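"""DHS peak calling, replicate concordance and the cross-stage consensus.

Within each accessible region, 150-bp hypersensitive-site peaks are placed
greedily on local maxima of the binned density track (multiple DHSs per
region allowed; a later, lower peak is skipped when its 150-bp footprint
would overlap an accepted one).  Stage-level DHSs must overlap a DHS from
the other replicate by at least 75 bp; concordant partners merge to their
interval union.  The cross-stage union of non-intersecting DHSs is the
final consensus list, with per-stage presence flags and a stage of temporal
origin (the earliest stage at which the site is present).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .density import STAGES, DensityTrack
from .intervals import max_pair_overlap, sort_intervals

DHS_WIDTH = 150


def call_dhs_peaks(track: DensityTrack, regions: pd.DataFrame) -> pd.DataFrame:
    """150-bp DHS peaks inside accessible regions.

    Candidate peaks are plateau local maxima of the binned density within
    each region (leftmost bin of an equal-value run wins ties); candidates
    are accepted greedily by descending density, skipping any whose 150-bp
    DHS (centred on the peak bin midpoint) would overlap an accepted DHS.
    The DHS centre stays inside the region but the interval may extend past
    the region boundary.  All-zero regions yield no DHS.
    """
    half = DHS_WIDTH // 2
    bs = track.bin_size
    rows = []
    for region_id, reg in regions.iterrows():
        chrom = reg["chrom"]
        arr = track.values[chrom]
        b0 = int(reg["start"]) // bs
        b1 = min((int(reg["end"]) - 1) // bs, len(arr) - 1)
        vals = np.asarray(arr[b0 : b1 + 1], dtype=float)
        if len(vals) == 0 or vals.max() <= 0:
            continue
        # plateau local maxima within the region
        candidates = []
        i = 0
        n = len(vals)
        while i < n:
            j = i
            while j + 1 < n and vals[j + 1] == vals[i]:
                j += 1
            left = vals[i - 1] if i > 0 else -np.inf
            right = vals[j + 1] if j + 1 < n else -np.inf
            if vals[i] > 0 and vals[i] >= left and vals[i] >= right:
                candidates.append((i, vals[i]))
            i = j + 1
        candidates.sort(key=lambda c: (-c[1], c[0]))
        accepted: list[tuple[int, int, float]] = []
        clen = track.genome.length(chrom)
        for bi, dens in candidates:
            mid = int((b0 + bi) * bs + bs // 2)
            s, e = mid - half, mid + half
            if s < 0 or e > clen:
                s = max(0, min(s, clen - DHS_WIDTH))
                e = s + DHS_WIDTH
            if any(s < ae and e > as_ for as_, ae, _ in accepted):
                continue
            accepted.append((s, e, dens))
        for s, e, dens in sorted(accepted):
            rows.append((chrom, s, e, track_stage(track), float(dens), region_id))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "stage", "peak_density", "source_region"]
    )


def track_stage(track: DensityTrack) -> int | None:
    return getattr(track, "stage", None)


def replicate_concordant(
    dhs_a: pd.DataFrame, dhs_b: pd.DataFrame, min_overlap: int = 75
) -> pd.DataFrame:
    """DHSs supported by both replicates, merged to interval unions.

    A DHS from either replicate is kept iff it overlaps some DHS of the
    other replicate by at least ``min_overlap`` bp; overlapping kept
    intervals are union-merged.  Symmetric in the replicate labels.
    """
    keep_a = dhs_a[max_pair_overlap(dhs_a, dhs_b) >= min_overlap]
    keep_b = dhs_b[max_pair_overlap(dhs_b, dhs_a) >= min_overlap]
    kept = pd.concat([keep_a, keep_b], ignore_index=True)
    if len(kept) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "stage", "peak_density"])
    stage = kept["stage"].iloc[0] if "stage" in kept else None
    kept = sort_intervals(kept)
    rows = []
    for chrom, sub in kept.groupby("chrom", sort=False):
        cur_s = cur_e = None
        cur_d = 0.0
        for _, row in sub.iterrows():
            if cur_s is None or row["start"] >= cur_e:
                if cur_s is not None:
                    rows.append((chrom, cur_s, cur_e, stage, cur_d))
                cur_s, cur_e = int(row["start"]), int(row["end"])
                cur_d = float(row.get("peak_density", 0.0))
            else:
                cur_e = max(cur_e, int(row["end"]))
                cur_d = max(cur_d, float(row.get("peak_density", 0.0)))
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, stage, cur_d))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "stage", "peak_density"])


def union_consensus(per_stage: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Cross-stage union of DHSs with per-stage presence flags.

    Overlapping DHSs from different stages merge transitively into one
    consensus record spanning their union; presence flags mark every stage
    contributing an overlapping DHS.
    """
    frames = []
    for stage, df in per_stage.items():
        if len(df):
            sub = df[["chrom", "start", "end"]].copy()
            sub["stage"] = stage
            frames.append(sub)
    cols = ["chrom", "start", "end"] + [f"present_{s}" for s in STAGES]
    if not frames:
        return pd.DataFrame(columns=cols)
    allsites = sort_intervals(pd.concat(frames, ignore_index=True))
    rows = []
    for chrom, sub in allsites.groupby("chrom", sort=False):
        cur_s = cur_e = None
        cur_stages: set[int] = set()
        for _, row in sub.iterrows():
            if cur_s is None or row["start"] >= cur_e:
                if cur_s is not None:
                    rows.append((chrom, cur_s, cur_e, cur_stages))
                cur_s, cur_e = int(row["start"]), int(row["end"])
                cur_stages = {int(row["stage"])}
            else:
                cur_e = max(cur_e, int(row["end"]))
                cur_stages.add(int(row["stage"]))
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, cur_stages))
    out = pd.DataFrame(
        [
            (c, s, e) + tuple(stage in st for stage in STAGES)
            for c, s, e, st in rows
        ],
        columns=cols,
    )
    return out


def stage_of_origin(consensus: pd.DataFrame) -> pd.DataFrame:
    """Attach ``origin_stage`` (earliest stage present) to a consensus list
    and leave per-stage presence flags untouched."""
    flags = consensus[[f"present_{s}" for s in STAGES]].to_numpy(dtype=bool)
    if len(consensus) and not flags.any(axis=1).all():
        raise ValueError("consensus record with no presence flag")
    origins = [STAGES[int(np.argmax(row))] for row in flags]
    out = consensus.copy()
    out["origin_stage"] = origins
    return out


def origin_composition(consensus: pd.DataFrame) -> pd.DataFrame:
    """Per-stage origin composition: of the DHSs present at each stage, the
    percentage originating at each earlier-or-equal stage."""
    if "origin_stage" not in consensus:
        consensus = stage_of_origin(consensus)
    rows = []
    for stage in STAGES:
        present = consensus[consensus[f"present_{stage}"]]
        n = len(present)
        for origin in STAGES:
            if STAGES.index(origin) > STAGES.index(stage):
                continue
            cnt = int((present["origin_stage"] == origin).sum())
            rows.append((stage, origin, cnt, round(100.0 * cnt / n, 2) if n else 0.0))
    return pd.DataFrame(rows, columns=["stage", "origin_stage", "count", "percentage"])
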