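"""Interval arithmetic on BED-style (chrom, start, end) DataFrames.

These helpers implement the handful of interval operations the pipeline needs
(merging, coverage, pairwise overlap queries) directly on sorted numpy arrays.
All coordinates are 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import Genome

BED_COLUMNS = ["chrom", "start", "end"]


def empty_intervals(extra: list[str] | None = None) -> pd.DataFrame:
    cols = BED_COLUMNS + (extra or [])
    return pd.DataFrame({c: pd.Series(dtype=object if c == "chrom" else "int64") for c in cols})


def validate_intervals(df: pd.DataFrame, genome: Genome | None = None) -> None:
    """Raise ``ValueError`` on malformed intervals (end <= start, out of bounds)."""
    if len(df) == 0:
        return
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"empty or inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    if genome is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in genome:
                raise ValueError(f"interval on unknown chromosome {chrom!r}")
            if sub["start"].min() < 0 or sub["end"].max() > genome.length(chrom):
                raise ValueError(f"interval outside chromosome bounds on {chrom!r}")


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Union-merge intervals; two intervals merge when separated by <= ``gap`` bp.

    With the default ``gap=0`` only overlapping or book-ended intervals merge.
    Pass ``gap=-1`` to merge strictly overlapping intervals only.
    """
    if len(df) == 0:
        return empty_intervals()
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    for chrom, sub in sort_intervals(df[BED_COLUMNS]).groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= gap:
                cur_e = max(cur_e, int(e))
            else:
                out_chrom.append(chrom)
                out_start.append(cur_s)
                out_end.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        out_chrom.append(chrom)
        out_start.append(cur_s)
        out_end.append(cur_e)
    return pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})


def total_covered_bp(df: pd.DataFrame) -> int:
    merged = merge_intervals(df)
    if len(merged) == 0:
        return 0
    return int((merged["end"] - merged["start"]).sum())


def coverage_fraction(df: pd.DataFrame, genome: Genome) -> float:
    """Fraction of the genome covered by the union of ``df``."""
    return total_covered_bp(df) / genome.total_size


def max_pair_overlap(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """For each query interval, the largest overlap (bp) with any *single*
    subject interval.  Zero where nothing overlaps."""
    result = np.zeros(len(query), dtype=np.int64)
    if len(query) == 0 or len(subject) == 0:
        return result
    subj = sort_intervals(subject[BED_COLUMNS])
    by_chrom = {c: g for c, g in subj.groupby("chrom", sort=False)}
    for i, (chrom, qs, qe) in enumerate(zip(query["chrom"], query["start"], query["end"])):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = int(np.searchsorted(ends, qs, side="right"))
        hi = int(np.searchsorted(starts, qe, side="left"))
        if hi > lo:
            ov = np.minimum(ends[lo:hi], qe) - np.maximum(starts[lo:hi], qs)
            result[i] = max(0, int(ov.max()))
    return result


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame, min_overlap: int = 1) -> np.ndarray:
    """Boolean per query: does it overlap some single subject by >= min_overlap bp?"""
    return max_pair_overlap(query, subject) >= min_overlap


def coverage_prefix(intervals: pd.DataFrame, chrom: str):
    """Return ``(starts, ends, cumlen)`` for evaluating covered-bp prefix sums.

    ``intervals`` must be disjoint on each chromosome (merge first if unsure).
    ``covered_bp_between`` consumes the tuple.
    """
    sub = intervals[intervals["chrom"] == chrom]
    sub = sub.sort_values("start", kind="stable")
    starts = sub["start"].to_numpy(dtype=np.int64)
    ends = sub["end"].to_numpy(dtype=np.int64)
    lens = ends - starts
    cum = np.concatenate([[0], np.cumsum(lens)])
    return starts, ends, cum


def covered_bp_upto(prefix, x: np.ndarray) -> np.ndarray:
    """Covered bp in [0, x) for a vector of positions ``x``."""
    starts, ends, cum = prefix
    x = np.asarray(x, dtype=np.int64)
    idx = np.searchsorted(ends, x, side="right")       # intervals fully left of x
    base = cum[idx]
    partial = np.zeros_like(base)
    inside = idx < len(starts)
    if inside.any():
        s = starts[idx[inside]]
        partial_in = np.maximum(0, x[inside] - s)
        partial = partial.astype(np.int64)
        partial[inside] = partial_in
    return base + partial
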