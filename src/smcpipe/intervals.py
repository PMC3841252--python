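"""Coordinate types and interval algebra shared by every stage.

All coordinates are 0-based, half-open (BED convention). Distances between
intervals are edge-to-edge gaps, matching the merge semantics used for
enhancer stitching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True, slots=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``.

    Ordering is (chrom, start, end, strand), so sorted lists of intervals
    are in browser order within a chromosome.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 if the intervals overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def distance_to_point(self, pos: int) -> int:
        """Distance from a base position to the interval (0 if inside)."""
        if self.start <= pos < self.end:
            return 0
        return self.start - pos if pos < self.start else pos - (self.end - 1)


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene with its transcription start site and genomic span."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    span: GenomicInterval = field(compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be +/-, got {self.strand!r}")
        if not (self.span.start <= self.tss < self.span.end):
            raise ValueError(
                f"TSS {self.tss} of {self.gene_id} outside span "
                f"[{self.span.start},{self.span.end})"
            )
        if self.chrom != self.span.chrom:
            raise ValueError("gene chrom differs from span chrom")


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose edge-to-edge gap is at most ``gap`` bp.

    Returns the minimal sorted list of disjoint intervals covering the
    input; strand is dropped (merged spans are unstranded). Idempotent:
    merging the output again with the same gap changes nothing.
    """
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    items = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in items:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= gap
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def _intersect_two(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of two sorted disjoint interval lists (sweep)."""
    out: list[GenomicInterval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        x, y = a[i], b[j]
        if x.chrom != y.chrom:
            if (x.chrom, x.start) < (y.chrom, y.start):
                i += 1
            else:
                j += 1
            continue
        lo = max(x.start, y.start)
        hi = min(x.end, y.end)
        if lo < hi:
            out.append(GenomicInterval(x.chrom, lo, hi))
        if x.end <= y.end:
            i += 1
        else:
            j += 1
    return out


def intersect_all(
    sets: Sequence[Iterable[GenomicInterval]],
) -> list[GenomicInterval]:
    """Maximal intervals covered by at least one interval from EVERY set.

    This is the co-occupancy operation: e.g. enhancers are the bases jointly
    occupied by OCT4, SOX2 and NANOG. Each input set is merged (gap 0)
    before the boolean AND.
    """
    if len(sets) == 0:
        raise ValueError("intersect_all requires at least one set")
    result = merge_intervals(sets[0], 0)
    for s in sets[1:]:
        result = _intersect_two(result, merge_intervals(s, 0))
    return result


def covered_bases(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered by the union of the intervals."""
    return sum(len(iv) for iv in merge_intervals(intervals, 0))


def nearest_tss(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    max_distance: int,
) -> str | None:
    """Gene whose TSS is closest to ``region``, or None beyond ``max_distance``.

    Distance is 0 when the TSS falls inside the region. Ties are broken by
    the lexicographically smaller gene_id, so the assignment is
    deterministic.
    """
    if not genes:
        raise ValueError("gene list is empty")
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != region.chrom:
            continue
        d = region.distance_to_point(g.tss)
        key = (d, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None or best[0] > max_distance:
        return None
    return best[1]
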