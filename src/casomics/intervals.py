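"""Genomic intervals and interval arithmetic.

All coordinates inside the package are 0-based half-open ([start, end)).
File formats that use other conventions (VCF, GFF3: 1-based) are converted
exactly once, at parse time, by :mod:`casomics.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(VALID_STRANDS)}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """True if the 0-based position lies inside the interval."""
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals per chromosome.

    Strand is dropped (merged intervals are unstranded). The result is
    sorted and disjoint, so summed lengths never double-count a base.
    """
    out: list[GenomicInterval] = []
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    for iv in by_pos:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total merged base-pair length covered by the intervals."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def subtract_intervals(
    universe: Sequence[GenomicInterval], holes: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Subtract `holes` from `universe`; both are merged first."""
    merged_u = merge_intervals(universe)
    merged_h = merge_intervals(holes)
    out: list[GenomicInterval] = []
    for u in merged_u:
        cursor = u.start
        for h in merged_h:
            if h.chrom != u.chrom or h.end <= cursor or h.start >= u.end:
                continue
            if h.start > cursor:
                out.append(GenomicInterval(u.chrom, cursor, h.start))
            cursor = max(cursor, h.end)
            if cursor >= u.end:
                break
        if cursor < u.end:
            out.append(GenomicInterval(u.chrom, cursor, u.end))
    return out
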