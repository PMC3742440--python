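"""Readers and writers for the plain-text formats the pipeline touches.

BED (UCSC dialect, 0-based half-open, ``track``/``browser``/``#`` lines
tolerated), seven-column TSV gene tables, FASTA, and UCSC ``chrom.sizes``
files.  Writing back a canonical BED6 read with :func:`read_bed` reproduces
the file byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from Bio import SeqIO

from .models import GeneList, GeneRecord, GenomeModel, GenomicInterval, PeakSet

PathLike = Union[str, Path]

GENE_TABLE_COLUMNS = [
    "gene_id",
    "chrom",
    "strand",
    "tss",
    "tx_start",
    "tx_end",
    "list_label",
]

_SEQUENCE_ALPHABET = frozenset("ACGTN")


def read_bed(
    path: PathLike,
    genome: Optional[GenomeModel] = None,
    label: Optional[str] = None,
) -> PeakSet:
    """Read a BED3+ file into a :class:`PeakSet`.

    Columns 4-6 populate name/score/strand when present; further columns are
    preserved verbatim in ``GenomicInterval.extra``.  Malformed lines raise
    ``ValueError`` naming the line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            if genome is not None and chrom not in genome:
                raise ValueError(
                    f"{path}:{lineno}: chromosome {chrom!r} not in supplied genome"
                )
            name = fields[3] if len(fields) > 3 else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            extra = tuple(fields[6:])
            intervals.append(
                GenomicInterval(chrom, start, end, name, score, strand, extra)
            )
    return PeakSet(label or path.stem, intervals, genome)


def _format_score(score: float) -> str:
    # %g trims trailing zeros so "37.5" and "16" survive a round trip
    return format(score, "g")


def _bed_columns(iv: GenomicInterval) -> int:
    if iv.extra:
        return 6 + len(iv.extra)
    if iv.strand != ".":
        return 6
    if iv.score is not None:
        return 5
    if iv.name is not None:
        return 4
    return 3


def write_bed(peaks: PeakSet, path: PathLike) -> None:
    """Write a PeakSet as BED with a uniform column count (the widest
    populated interval decides; shorter rows are padded with '.')."""
    path = Path(path)
    n_cols = max((_bed_columns(iv) for iv in peaks), default=3)
    with path.open("w") as fh:
        for iv in peaks:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if n_cols >= 4:
                fields.append(iv.name if iv.name is not None else ".")
            if n_cols >= 5:
                fields.append(_format_score(iv.score) if iv.score is not None else ".")
            if n_cols >= 6:
                fields.append(iv.strand)
            fields.extend(iv.extra)
            fields.extend("." for _ in range(n_cols - len(fields)))
            fh.write("\t".join(fields) + "\n")


def read_gene_table(path: PathLike) -> list[GeneList]:
    """Read a 7-column TSV gene table, grouped by ``list_label``.

    Rows must satisfy the GeneRecord invariants (strand-consistent TSS inside
    the body); lists appear in first-occurrence order, rows in file order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing gene-table columns {missing}")
    lists: dict[str, list[GeneRecord]] = {}
    for row in df.itertuples(index=False):
        rec = GeneRecord(
            gene_id=str(row.gene_id),
            chrom=str(row.chrom),
            strand=str(row.strand),
            tss=int(row.tss),
            tx_start=int(row.tx_start),
            tx_end=int(row.tx_end),
        )
        lists.setdefault(str(row.list_label), []).append(rec)
    return [GeneList(label, genes) for label, genes in lists.items()]


def write_gene_table(gene_lists: list[GeneList], path: PathLike) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "tx_start": g.tx_start,
            "tx_end": g.tx_end,
            "list_label": gl.label,
        }
        for gl in gene_lists
        for g in gl.genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Read FASTA into ``(seq_id, sequence)`` pairs, uppercased.

    Only A/C/G/T/N are accepted; empty records or other characters raise
    ``ValueError`` naming the record.
    """
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {rec.id!r}")
        bad = set(seq) - _SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains illegal characters {sorted(bad)}"
            )
        out.append((rec.id, seq))
    return out


def write_fasta(records: list[tuple[str, str]], path: PathLike, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path: PathLike) -> GenomeModel:
    """Read a UCSC-style two-column ``chrom.sizes`` file."""
    sizes: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            if fields[0] in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {fields[0]!r}")
            sizes[fields[0]] = int(fields[1])
    return GenomeModel(sizes)


def write_chrom_sizes(genome: GenomeModel, path: PathLike) -> None:
    with Path(path).open("w") as fh:
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_json(obj: object, path: PathLike) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
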