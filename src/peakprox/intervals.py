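"""Strand-aware interval arithmetic.

Everything downstream (control filtering, window counting, overlap
summaries) reduces to the predicates here.  The production path merges the
subject set per chromosome and binary-searches it; a quadratic all-pairs
oracle (:func:`overlap_mask_bruteforce`) is kept alongside for equivalence
testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .models import GeneRecord, GenomicInterval, PeakSet


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 bp on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def midpoint(a: GenomicInterval) -> int:
    """floor((start + end) / 2): the reference point used for all distances."""
    return (a.start + a.end) // 2


def signed_tss_distance(point: int, gene: GeneRecord, chrom: str | None = None) -> int:
    """Strand-aware distance from a point to a gene's TSS.

    Negative = upstream (5' of the TSS), positive = downstream, 0 = at the
    TSS.  ``chrom``, when given, must match the gene's chromosome.
    """
    if chrom is not None and chrom != gene.chrom:
        raise ValueError(
            f"point on {chrom!r} but gene {gene.gene_id} is on {gene.chrom!r}"
        )
    return point - gene.tss if gene.strand == "+" else gene.tss - point


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open spans into a sorted disjoint list."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def merged_chrom_spans(
    intervals: Iterable[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) arrays of the merged union of intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, spans in by_chrom.items():
        merged = merge_spans(spans)
        out[chrom] = (
            np.array([s for s, _ in merged], dtype=np.int64),
            np.array([e for _, e in merged], dtype=np.int64),
        )
    return out


def overlap_mask(
    query: Sequence[GenomicInterval] | PeakSet,
    subject: Sequence[GenomicInterval] | PeakSet,
) -> np.ndarray:
    """Boolean mask over ``query``: True where >= 1 subject interval overlaps.

    Overlap against the merged union of the subject set is equivalent to
    overlap against any individual subject interval, so each query needs a
    single binary search into the disjoint merged spans.
    """
    spans = merged_chrom_spans(subject)
    mask = np.zeros(len(query), dtype=bool)
    for i, iv in enumerate(query):
        if iv.chrom not in spans:
            continue
        starts, ends = spans[iv.chrom]
        j = int(np.searchsorted(starts, iv.end, side="left"))
        mask[i] = j > 0 and ends[j - 1] > iv.start
    return mask


def overlap_mask_bruteforce(
    query: Sequence[GenomicInterval] | PeakSet,
    subject: Sequence[GenomicInterval] | PeakSet,
) -> np.ndarray:
    """All-pairs oracle for :func:`overlap_mask`; quadratic, for testing."""
    return np.array(
        [any(overlaps(q, s) for s in subject) for q in query], dtype=bool
    )


@dataclass
class OverlapCount:
    """Result of counting query intervals touched by a subject set."""

    count: int
    mask: np.ndarray
    flagged: list[GenomicInterval]


def count_overlapping(query: PeakSet, subject: PeakSet) -> OverlapCount:
    """Count query intervals overlapped (>= 1 bp) by at least one subject interval.

    Each query interval is counted at most once no matter how many subject
    intervals touch it.
    """
    mask = overlap_mask(query, subject)
    flagged = [iv for iv, m in zip(query, mask) if m]
    return OverlapCount(count=int(mask.sum()), mask=mask, flagged=flagged)
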