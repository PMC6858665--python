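"""Genomic interval algebra.

All coordinates in this package are 0-based, half-open ``[start, end)`` on a
named chromosome.  Conversion from 1-based inclusive conventions (GTF,
RepeatMasker ``.out``) happens only at I/O boundaries, never here.  Strand is
carried for record keeping but every overlap computation is strand-agnostic,
matching the orientation-free way repeat masking treats the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)``.

    Raises ``ValueError`` on construction if ``start >= end``, coordinates are
    negative, the chromosome name is empty, or the strand is not one of
    ``+ - .``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


def _check_single_chrom(intervals: Sequence[GenomicInterval]) -> None:
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse intervals on one chromosome into a sorted, disjoint union.

    The per-base union is preserved exactly; adjacent (book-ended) intervals
    are merged.  Empty input yields an empty list.
    """
    if not intervals:
        return []
    _check_single_chrom(intervals)
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[tuple[int, int]] = []
    cur_s, cur_e = ordered[0].start, ordered[0].end
    for iv in ordered[1:]:
        if iv.start <= cur_e:
            cur_e = max(cur_e, iv.end)
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = iv.start, iv.end
    merged.append((cur_s, cur_e))
    chrom = ordered[0].chrom
    return [GenomicInterval(chrom, s, e) for s, e in merged]


def interval_overlap_bp(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Number of bases in ``union(a) & union(b)``, counted once per base."""
    if not a or not b:
        return 0
    _check_single_chrom(list(a) + list(b))
    ma, mb = merge_intervals(a), merge_intervals(b)
    total = 0
    i = j = 0
    while i < len(ma) and j < len(mb):
        lo = max(ma[i].start, mb[j].start)
        hi = min(ma[i].end, mb[j].end)
        if lo < hi:
            total += hi - lo
        if ma[i].end <= mb[j].end:
            i += 1
        else:
            j += 1
    return total


def subtract_intervals(
    universe: GenomicInterval, covered: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Gaps of ``universe`` not covered by ``covered`` (used to derive introns)."""
    inside = [
        GenomicInterval(universe.chrom, max(iv.start, universe.start), min(iv.end, universe.end))
        for iv in covered
        if iv.chrom == universe.chrom and iv.start < universe.end and iv.end > universe.start
    ]
    gaps: list[GenomicInterval] = []
    pos = universe.start
    for iv in merge_intervals(inside):
        if iv.start > pos:
            gaps.append(GenomicInterval(universe.chrom, pos, iv.start))
        pos = max(pos, iv.end)
    if pos < universe.end:
        gaps.append(GenomicInterval(universe.chrom, pos, universe.end))
    return gaps


@dataclass
class TranscriptModel:
    """One (spliced) transcript: exon structure plus optional sequence."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{self.transcript_id}: exons on mixed chrom/strand")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= exon length sum {self.length}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)


@dataclass
class Gene:
    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    @property
    def introns(self) -> list[GenomicInterval]:
        """Within-gene complement of the (merged) exons."""
        if not self.exons:
            return []
        return subtract_intervals(self.span, self.exons)


@dataclass
class GeneAnnotation:
    genes: list[Gene]

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.span.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.span.start, g.gene_id))
        return out


@dataclass
class TEAnnotation:
    """TE intervals labelled with a superfamily (e.g. ``LTR/Gypsy``)."""

    records: list[tuple[GenomicInterval, str]]

    def superfamilies(self) -> list[str]:
        return sorted({fam for _, fam in self.records})

    def by_chrom(self) -> dict[str, list[tuple[GenomicInterval, str]]]:
        out: dict[str, list[tuple[GenomicInterval, str]]] = {}
        for iv, fam in self.records:
            out.setdefault(iv.chrom, []).append((iv, fam))
        for lst in out.values():
            lst.sort(key=lambda r: (r[0].start, r[0].end, r[1]))
        return out

    def total_bp_by_superfamily(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for iv, fam in self.records:
            out[fam] = out.get(fam, 0) + len(iv)
        return out
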