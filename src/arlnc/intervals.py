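"""Interval arithmetic shared by the classification modules.

All intervals are 0-based half-open on the genome. These helpers operate on
:class:`~arlnc.io_formats.TranscriptModel` objects and implement the
primitive geometric predicates (exonic overlap, intron containment,
head-to-head / tail-to-tail adjacency) that the class-code and
genomic-location rules are built from.
"""

from __future__ import annotations

from .io_formats import TranscriptModel

__all__ = [
    "intervals_overlap_bp",
    "exonic_overlap_bp",
    "span_overlap_bp",
    "contained_in_single_intron",
    "gap_between",
    "is_divergent",
    "is_convergent",
]


def intervals_overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def exonic_overlap_bp(t1: TranscriptModel, t2: TranscriptModel) -> int:
    """Total overlap (bp) between the exon sets of two transcripts."""
    if t1.chrom != t2.chrom:
        return 0
    total = 0
    # exon lists are short; the quadratic sweep is fine and obvious
    for e1 in t1.exons:
        for e2 in t2.exons:
            total += intervals_overlap_bp(e1, e2)
    return total


def span_overlap_bp(t1: TranscriptModel, t2: TranscriptModel) -> int:
    if t1.chrom != t2.chrom:
        return 0
    return intervals_overlap_bp((t1.start, t1.end), (t2.start, t2.end))


def contained_in_single_intron(query: TranscriptModel,
                               host: TranscriptModel) -> bool:
    """True if the query span lies fully inside one intron of the host."""
    if query.chrom != host.chrom:
        return False
    return any(
        a <= query.start and query.end <= b for a, b in host.introns
    )


def gap_between(t1: TranscriptModel, t2: TranscriptModel) -> int | None:
    """Gap (bp) between two non-overlapping spans; None if they overlap or
    sit on different chromosomes."""
    if t1.chrom != t2.chrom:
        return None
    if span_overlap_bp(t1, t2) > 0:
        return None
    if t1.end <= t2.start:
        return t2.start - t1.end
    return t1.start - t2.end


def _left_right(t1: TranscriptModel, t2: TranscriptModel):
    return (t1, t2) if t1.start <= t2.start else (t2, t1)


def is_divergent(t1: TranscriptModel, t2: TranscriptModel,
                 window: int = 1000) -> bool:
    """Head-to-head arrangement: opposite strands, no span overlap, and the
    two 5' ends (TSS) within *window* bp facing each other."""
    if t1.chrom != t2.chrom or t1.strand == t2.strand:
        return False
    if span_overlap_bp(t1, t2) > 0:
        return False
    left, right = _left_right(t1, t2)
    # bodies must extend apart: left transcript on '-', right on '+'
    if left.strand != "-" or right.strand != "+":
        return False
    return abs(right.tss - left.tss) <= window


def is_convergent(t1: TranscriptModel, t2: TranscriptModel,
                  window: int = 1000) -> bool:
    """Tail-to-tail arrangement: opposite strands, no span overlap, and the
    two 3' ends (TES) within *window* bp facing each other."""
    if t1.chrom != t2.chrom or t1.strand == t2.strand:
        return False
    if span_overlap_bp(t1, t2) > 0:
        return False
    left, right = _left_right(t1, t2)
    # bodies point toward each other: left on '+', right on '-'
    if left.strand != "+" or right.strand != "-":
        return False
    return abs(right.tes - left.tes) <= window
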