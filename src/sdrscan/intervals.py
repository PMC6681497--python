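"""Genomic interval primitives.

All internal coordinates are 0-based, half-open ``[start, end)`` on the
forward strand of the sequence they refer to.  Conversion to the 1-based
inclusive convention happens only at GFF3 export time.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware interval on a named contig (0-based, half-open)."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.contig_id, self.start + offset, self.end + offset, self.strand
        )

    def to_gff3(self) -> tuple[int, int]:
        """Return (start, end) in GFF3 1-based inclusive coordinates."""
        return self.start + 1, self.end

    @staticmethod
    def from_gff3(contig_id: str, start1: int, end1: int, strand: str = "+") -> "GenomicInterval":
        """Build from GFF3 1-based inclusive coordinates."""
        return GenomicInterval(contig_id, start1 - 1, end1, strand)


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """Half-open overlap test for bare coordinate pairs."""
    return a_start < b_end and b_start < a_end
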