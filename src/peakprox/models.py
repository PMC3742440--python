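"""Core containers: genomes, intervals, peak sets, genes and gene lists.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  A gene's transcription start site (TSS) is the strand-aware
5' base of the transcript body, so ``tss == tx_start`` on the + strand and
``tss == tx_end - 1`` on the - strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence

VALID_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome name -> length (bp) map for a (possibly synthetic) assembly."""

    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("GenomeModel requires at least one chromosome")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")

    @property
    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __getitem__(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]


@dataclass
class GenomicInterval:
    """A half-open genomic interval, e.g. one ChIP-seq peak.

    ``extra`` carries any BED columns beyond the canonical six, untouched,
    so that reading and re-writing a file is lossless.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """An ordered collection of peaks from one condition."""

    label: str
    intervals: list[GenomicInterval]
    genome: Optional[GenomeModel] = None

    def __post_init__(self) -> None:
        if self.genome is not None:
            for iv in self.intervals:
                if iv.chrom not in self.genome:
                    raise ValueError(
                        f"interval on unknown chromosome {iv.chrom!r} "
                        f"(peak set {self.label!r})"
                    )
                if iv.end > self.genome[iv.chrom]:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} extends past "
                        f"chromosome end {self.genome[iv.chrom]}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def subset(self, keep: Sequence[bool], label: Optional[str] = None) -> "PeakSet":
        """New PeakSet with the intervals where ``keep`` is true, order preserved."""
        if len(keep) != len(self.intervals):
            raise ValueError("mask length must equal number of intervals")
        ivs = [iv for iv, k in zip(self.intervals, keep) if k]
        return PeakSet(label or self.label, ivs, self.genome)


@dataclass(frozen=True)
class GeneRecord:
    """One transcript with a strand-aware TSS and a half-open body."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tx_start >= self.tx_end:
            raise ValueError(f"gene {self.gene_id}: require tx_start < tx_end")
        if not (self.tx_start <= self.tss < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: tss outside [tx_start, tx_end)")
        if self.strand == "+" and self.tss != self.tx_start:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss == tx_start")
        if self.strand == "-" and self.tss != self.tx_end - 1:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss == tx_end - 1")


@dataclass
class GeneList:
    """A labeled cell-type gene list (e.g. the top oligodendrocyte genes)."""

    label: str
    genes: list[GeneRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(
                    f"duplicate gene_id {g.gene_id!r} in list {self.label!r}"
                )
            seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)


class ProximityCategory(str, Enum):
    """Mutually exclusive peak-to-gene relationship classes."""

    UPSTREAM_0_1K = "upstream_0_1k"
    UPSTREAM_1_20K = "upstream_1_20k"
    UPSTREAM_20_100K = "upstream_20_100k"
    GENE_BODY = "gene_body"
    DOWNSTREAM_WITHIN_100K = "downstream_within_100k"
    NONE = "none"
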