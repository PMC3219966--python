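"""Genome coordinate system shared by every pipeline stage.

All genomic intervals in this package are 0-based, half-open ``[start, end)``
(the BED convention).  A :class:`Genome` is nothing more than an ordered map
from chromosome name to length; it stands in for the reference assembly
against which cleavage tags, density bins, and interval calls are expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Genome:
    """An ordered collection of chromosomes with fixed lengths.

    Parameters
    ----------
    chrom_lengths
        Mapping of chromosome name to length in base pairs.  Insertion order
        is the canonical chromosome order used when tracks are flattened
        genome-wide.
    """

    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("genome must declare at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_size(self) -> int:
        """Summed length of all declared chromosomes, in bp."""
        return sum(self.chrom_lengths.values())

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def __iter__(self):
        return iter(self.chrom_lengths)
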