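"""Genomic intervals: 0-based, half-open, stranded.

GFF3 is 1-based inclusive on disk; everything internal uses 0-based
half-open coordinates and converts back to 1-based only in user-facing
reports.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        """Half-open membership test for a 0-based position."""
        return chrom == self.chrom and self.start <= pos < self.end

    @classmethod
    def from_gff3(cls, chrom: str, start_1based: int, end_1based: int,
                  strand: str = "+") -> "GenomicInterval":
        """Build from GFF3's 1-based inclusive coordinates."""
        return cls(chrom, start_1based - 1, end_1based, strand)

    def to_gff3(self) -> tuple[int, int]:
        """Return (start, end) in 1-based inclusive convention."""
        return self.start + 1, self.end
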