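"""Cleavage tag sets and binned sliding-window density tracks.

The raw observable is a :class:`TagSet`: per-chromosome sorted arrays of
single-base DNaseI cleavage positions for one developmental stage and one
replicate.  Density is summarised on a fixed 20-bp grid: each bin's score is
the number of tags falling in a 150-bp window centred on the bin midpoint
(right-half-open).  This track is the substrate for DHS peak calling, the
rank-expectation differential statistic, promoter profiles and peri-exonic
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import Genome

#: Developmental stages profiled, in temporal order.
STAGES: tuple[int, ...] = (5, 9, 10, 11, 14)

DEFAULT_BIN_SIZE = 20
DEFAULT_WINDOW = 150


@dataclass
class TagSet:
    """One stage/replicate's cleavage positions on a genome.

    ``positions`` maps chromosome name to a sorted int64 array of 0-based
    cleavage coordinates.  Duplicate positions are allowed (independent
    cleavage events can map to the same base).
    """

    stage: int
    replicate: int
    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError("tag positions must be 1-D")
            if len(arr) and (np.diff(arr) < 0).any():
                arr = np.sort(arr, kind="stable")
            clean[chrom] = arr
        self.positions = clean

    @property
    def n_tags(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def chrom_tags(self, chrom: str) -> np.ndarray:
        return self.positions.get(chrom, np.empty(0, dtype=np.int64))

    def deduplicated(self) -> "TagSet":
        """Copy with identical cleavage positions collapsed to one tag."""
        return TagSet(
            self.stage,
            self.replicate,
            {c: np.unique(p) for c, p in self.positions.items()},
        )

    def validate(self, genome: Genome) -> None:
        for chrom, pos in self.positions.items():
            if chrom not in genome:
                raise ValueError(f"tags on unknown chromosome {chrom!r}")
            if len(pos) and (pos[0] < 0 or pos[-1] >= genome.length(chrom)):
                raise ValueError(f"tag position outside {chrom!r} bounds")


@dataclass
class DensityTrack:
    """Per-20-bp-bin sliding-window tag counts.

    Bin ``i`` on a chromosome covers ``[i*bin_size, (i+1)*bin_size)`` and its
    score counts tags ``t`` with ``mid - window/2 <= t < mid + window/2``
    where ``mid = i*bin_size + bin_size/2``.
    """

    genome: Genome
    bin_size: int = DEFAULT_BIN_SIZE
    window: int = DEFAULT_WINDOW
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def n_bins(self, chrom: str) -> int:
        return -(-self.genome.length(chrom) // self.bin_size)

    def bin_mids(self, chrom: str) -> np.ndarray:
        n = self.n_bins(chrom)
        return np.arange(n) * self.bin_size + self.bin_size / 2.0

    def bin_of(self, chrom: str, position: int) -> int:
        """Index of the bin containing a base position."""
        return int(position) // self.bin_size

    def flatten(self) -> tuple[np.ndarray, dict[str, slice]]:
        """Concatenate chromosome arrays in genome order.

        Returns the flat array and a map of chromosome -> slice into it.
        """
        parts = []
        slices: dict[str, slice] = {}
        offset = 0
        for chrom in self.genome:
            arr = self.values[chrom]
            slices[chrom] = slice(offset, offset + len(arr))
            offset += len(arr)
            parts.append(arr)
        return np.concatenate(parts), slices

    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


def bin_density(
    tags: TagSet,
    genome: Genome,
    bin_size: int = DEFAULT_BIN_SIZE,
    window: int = DEFAULT_WINDOW,
) -> DensityTrack:
    """Compute the binned sliding-window density track for one tag set.

    Each bin's count is the number of tags within ``window`` bp of the bin
    midpoint, half-open on the right.  Deterministic.

    Raises
    ------
    ValueError
        If ``window < bin_size`` or either is non-positive.
    """
    if bin_size <= 0 or window <= 0:
        raise ValueError("bin_size and window must be positive")
    if window < bin_size:
        raise ValueError(f"window ({window}) must be >= bin_size ({bin_size})")
    half = window / 2.0
    values: dict[str, np.ndarray] = {}
    for chrom in genome:
        n = -(-genome.length(chrom) // bin_size)
        mids = np.arange(n) * bin_size + bin_size / 2.0
        pos = tags.chrom_tags(chrom)
        lo = np.searchsorted(pos, np.ceil(mids - half), side="left")
        hi = np.searchsorted(pos, np.ceil(mids + half), side="left")
        values[chrom] = (hi - lo).astype(np.int64)
    return DensityTrack(genome=genome, bin_size=bin_size, window=window, values=values)


def average_tracks(tracks: list[DensityTrack]) -> DensityTrack:
    """Mean of several same-shape tracks (e.g. the two replicates of a stage)."""
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if t.bin_size != first.bin_size or t.genome.names != first.genome.names:
            raise ValueError("tracks must share binning and genome")
    values = {
        chrom: np.mean([t.values[chrom] for t in tracks], axis=0)
        for chrom in first.genome
    }
    return DensityTrack(
        genome=first.genome, bin_size=first.bin_size, window=first.window, values=values
    )
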