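"""Peak-to-TSS proximity analysis.

The analysis asks whether ChIP-seq peaks for a transcription factor fall
near the TSSs of one cell type's signature genes more often than a uniform
placement of the same peaks over the genome would predict.  Stages:

1. filter treatment peaks against a negative-control peak set;
2. deduplicate gene lists to unique TSSs;
3. count peaks whose midpoint lies within +/- ``window`` bp of each TSS;
4. compare observed per-list counts with the uniform-genome expectation
   (fold enrichment + chi-squared tests);
5. build strand-aware TSS-relative incidence histograms;
6. summarize overlap between peak sets for different factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    count_overlapping,
    merge_spans,
    midpoint,
    overlap_mask,
    signed_tss_distance,
)
from .models import (
    GeneList,
    GeneRecord,
    GenomeModel,
    GenomicInterval,
    PeakSet,
    ProximityCategory,
)

DEFAULT_WINDOW = 100_000
UPSTREAM_NEAR = 1_000
UPSTREAM_MID = 20_000


# ---------------------------------------------------------------------------
# control filter and gene dedup
# ---------------------------------------------------------------------------

def filter_against_control(
    treatment: PeakSet, control: PeakSet
) -> tuple[PeakSet, PeakSet]:
    """Partition treatment peaks into (retained, removed) by control overlap.

    A treatment peak with >= 1 bp overlap with any control peak is treated
    as a false positive and removed; the rest are retained.  The two outputs
    partition the input exactly.
    """
    if (
        treatment.genome is not None
        and control.genome is not None
        and treatment.genome.chrom_sizes != control.genome.chrom_sizes
    ):
        raise ValueError("treatment and control peak sets are on different genomes")
    mask = overlap_mask(treatment, control)
    retained = treatment.subset(~mask, label=f"{treatment.label}.retained")
    removed = treatment.subset(mask, label=f"{treatment.label}.removed")
    return retained, removed


def dedup_unique_tss(genes: GeneList) -> GeneList:
    """Keep one representative per identical (chrom, tss, strand), input order.

    Mirrors restricting the analysis to genes with a unique TSS so that
    multi-isoform genes are not over-represented.
    """
    seen: set[tuple[str, int, str]] = set()
    kept: list[GeneRecord] = []
    for g in genes:
        key = (g.chrom, g.tss, g.strand)
        if key not in seen:
            seen.add(key)
            kept.append(g)
    return GeneList(genes.label, kept)


# ---------------------------------------------------------------------------
# per-gene window counting
# ---------------------------------------------------------------------------

@dataclass
class PeaksPerGene:
    """Per-gene peak counts within +/- window of the TSS, plus list totals."""

    window: int
    per_gene: dict[str, int]
    tally: dict[str, int]  # genes with 0 / 1 / 2 / >=3 peaks
    distinct_peaks: int  # peaks within any window of the list, counted once
    assignments: int  # peak-gene pairs (a peak may serve several genes)


def _peak_points(peaks: PeakSet, peak_point: str) -> None:
    if peak_point not in ("midpoint", "any-overlap"):
        raise ValueError(f"unknown peak_point mode {peak_point!r}")


def peaks_per_gene(
    peaks: PeakSet,
    genes: GeneList,
    window: int = DEFAULT_WINDOW,
    peak_point: str = "midpoint",
) -> PeaksPerGene:
    """Count peaks within ``window`` bp of each gene's TSS (closed boundary).

    In the default ``midpoint`` mode a peak is assigned to a gene iff
    ``|signed_tss_distance(midpoint(peak), gene)| <= window``; in
    ``any-overlap`` mode any 1-bp overlap between the peak and the
    ``[tss - window, tss + window]`` span counts.  A peak may be assigned to
    several genes, but contributes once to the list-level distinct total.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    _peak_points(peaks, peak_point)

    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, iv in enumerate(peaks):
        by_chrom.setdefault(iv.chrom, []).append((midpoint(iv), iv.start, iv.end))
    chrom_arrays = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        mids = np.array([r[0] for r in rows], dtype=np.int64)
        starts = np.array([r[1] for r in rows], dtype=np.int64)
        ends = np.array([r[2] for r in rows], dtype=np.int64)
        chrom_arrays[chrom] = (mids, starts, ends)

    per_gene: dict[str, int] = {}
    distinct: set[tuple[str, int, int]] = set()
    assignments = 0
    for g in genes:
        n = 0
        if g.chrom in chrom_arrays:
            mids, starts, ends = chrom_arrays[g.chrom]
            if peak_point == "midpoint":
                lo = int(np.searchsorted(mids, g.tss - window, side="left"))
                hi = int(np.searchsorted(mids, g.tss + window, side="right"))
                n = hi - lo
                for s, e in zip(starts[lo:hi], ends[lo:hi]):
                    distinct.add((g.chrom, int(s), int(e)))
            else:
                hit = (starts <= g.tss + window) & (ends > g.tss - window)
                n = int(hit.sum())
                for s, e in zip(starts[hit], ends[hit]):
                    distinct.add((g.chrom, int(s), int(e)))
        per_gene[g.gene_id] = n
        assignments += n

    tally = {"0": 0, "1": 0, "2": 0, "3+": 0}
    for n in per_gene.values():
        tally["3+" if n >= 3 else str(n)] += 1
    return PeaksPerGene(
        window=window,
        per_gene=per_gene,
        tally=tally,
        distinct_peaks=len(distinct),
        assignments=assignments,
    )


# ---------------------------------------------------------------------------
# proximity categories
# ---------------------------------------------------------------------------

def categorize(
    peak: GenomicInterval, gene: GeneRecord, window: int = DEFAULT_WINDOW
) -> ProximityCategory:
    """Classify a peak relative to one gene by its midpoint.

    Precedence: a midpoint inside the gene body is GENE_BODY regardless of
    TSS distance; otherwise upstream distances bin at 1 kb / 20 kb / window,
    and downstream midpoints past the 3' end within ``window`` are
    DOWNSTREAM_WITHIN_100K.  Bin boundaries are closed toward the TSS.
    """
    if peak.chrom != gene.chrom:
        return ProximityCategory.NONE
    m = midpoint(peak)
    if gene.tx_start <= m < gene.tx_end:
        return ProximityCategory.GENE_BODY
    d = signed_tss_distance(m, gene)
    if d < 0:
        u = -d
        if u <= UPSTREAM_NEAR:
            return ProximityCategory.UPSTREAM_0_1K
        if u <= UPSTREAM_MID:
            return ProximityCategory.UPSTREAM_1_20K
        if u <= window:
            return ProximityCategory.UPSTREAM_20_100K
        return ProximityCategory.NONE
    past_3prime = m >= gene.tx_end if gene.strand == "+" else m < gene.tx_start
    if d > 0 and past_3prime and d <= window:
        return ProximityCategory.DOWNSTREAM_WITHIN_100K
    return ProximityCategory.NONE


def category_table(
    peaks: PeakSet, genes: GeneList, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Long table of every in-window (peak, gene) pair with its category."""
    rows = []
    for g in genes:
        for iv in peaks:
            if iv.chrom != g.chrom:
                continue
            cat = categorize(iv, g, window=window)
            if cat is ProximityCategory.NONE:
                continue
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "peak": iv.name or f"{iv.chrom}:{iv.start}-{iv.end}",
                    "category": cat.value,
                    "distance": signed_tss_distance(midpoint(iv), g),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "peak", "category", "distance"])


def genes_per_category(table: pd.DataFrame, genes: GeneList) -> dict[str, int]:
    """Number of genes with >= 1 peak in each category (a gene may appear in several)."""
    out = {c.value: 0 for c in ProximityCategory if c is not ProximityCategory.NONE}
    if len(table):
        for cat, sub in table.groupby("category"):
            out[str(cat)] = sub["gene_id"].nunique()
    return out


# ---------------------------------------------------------------------------
# uniform background model and enrichment test
# ---------------------------------------------------------------------------

def uniform_background(n_peaks: int, genome: GenomeModel) -> tuple[float, float]:
    """(density in peaks/bp, mean spacing in bp) for uniformly placed peaks."""
    if n_peaks <= 0:
        raise ValueError("n_peaks must be positive")
    total = genome.total_size
    return n_peaks / total, total / n_peaks


def _window_spans(
    genes: GeneList, window: int, genome: Optional[GenomeModel]
) -> dict[str, list[tuple[int, int]]]:
    """Merged, chromosome-clipped +/-window spans around each unique TSS."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in dedup_unique_tss(genes):
        start = max(0, g.tss - window)
        end = g.tss + window + 1  # closed +/-window in half-open coordinates
        if genome is not None:
            end = min(end, genome[g.chrom])
        by_chrom.setdefault(g.chrom, []).append((start, end))
    return {c: merge_spans(s) for c, s in by_chrom.items()}


def window_span_total(
    genes: GeneList,
    window: int = DEFAULT_WINDOW,
    genome: Optional[GenomeModel] = None,
    merge_windows: bool = False,
) -> int:
    """Total bp of the TSS windows for a list.

    The naive span (default) is ``unique TSSs x 2 x window``, ignoring
    window overlap between nearby genes and chromosome edges — the
    back-of-envelope uniform model.  ``merge_windows=True`` returns the
    merged-union span instead.
    """
    unique = dedup_unique_tss(genes)
    if not merge_windows:
        return len(unique) * 2 * window
    spans = _window_spans(unique, window, genome)
    return sum(e - s for chrom_spans in spans.values() for s, e in chrom_spans)


def expected_count(
    n_peaks: int,
    genome: GenomeModel,
    genes: GeneList,
    window: int = DEFAULT_WINDOW,
    merge_windows: bool = False,
) -> float:
    """Expected number of peaks in a list's TSS windows under uniform placement."""
    if len(genes) == 0:
        return 0.0
    density, _ = uniform_background(n_peaks, genome)
    span = window_span_total(genes, window=window, genome=genome, merge_windows=merge_windows)
    return density * span


@dataclass
class ListEnrichment:
    observed: int
    expected: float
    fold: float
    chi2_statistic: float
    degrees_of_freedom: int
    p_value: float


@dataclass
class EnrichmentReport:
    """Observed vs uniform-expected peak counts, per list and jointly.

    The joint goodness-of-fit scales the uniform-model expectations to the
    observed total, so it asks whether peaks *distribute* among the lists'
    windows as their spans predict (df = n_lists - 1); the per-list tests
    compare each count against its absolute uniform expectation (df = 1).
    """

    per_list: dict[str, ListEnrichment]
    joint_statistic: float
    joint_df: int
    joint_p_value: float

    def to_dict(self) -> dict:
        return {
            "per_list": {
                label: vars(r).copy() for label, r in self.per_list.items()
            },
            "joint": {
                "chi2_statistic": self.joint_statistic,
                "degrees_of_freedom": self.joint_df,
                "p_value": self.joint_p_value,
            },
        }


def enrichment_test(
    observed: Mapping[str, int], expected: Mapping[str, float]
) -> EnrichmentReport:
    """Fold enrichment and chi-squared tests of observed vs expected counts."""
    labels = list(observed)
    if set(labels) != set(expected):
        raise ValueError("observed and expected must cover the same lists")
    obs = np.array([observed[l] for l in labels], dtype=float)
    exp = np.array([expected[l] for l in labels], dtype=float)
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")

    per_list = {}
    for label, o, e in zip(labels, obs, exp):
        stat = (o - e) ** 2 / e
        per_list[label] = ListEnrichment(
            observed=int(o),
            expected=float(e),
            fold=float(o / e),
            chi2_statistic=float(stat),
            degrees_of_freedom=1,
            p_value=float(stats.chi2.sf(stat, 1)),
        )

    exp_scaled = exp * obs.sum() / exp.sum()
    joint_stat = float(((obs - exp_scaled) ** 2 / exp_scaled).sum())
    joint_df = max(len(labels) - 1, 1)
    joint_p = float(stats.chi2.sf(joint_stat, joint_df)) if len(labels) > 1 else 1.0
    if len(labels) == 1:
        joint_stat, joint_df, joint_p = 0.0, 0, 1.0
    return EnrichmentReport(
        per_list=per_list,
        joint_statistic=joint_stat,
        joint_df=joint_df,
        joint_p_value=joint_p,
    )


def proximity_enrichment(
    peaks: PeakSet,
    gene_lists: Sequence[GeneList],
    genome: GenomeModel,
    window: int = DEFAULT_WINDOW,
    merge_windows: bool = False,
    peak_point: str = "midpoint",
) -> EnrichmentReport:
    """End-to-end: distinct in-window peak counts per list vs uniform model."""
    observed = {}
    expected = {}
    for gl in gene_lists:
        unique = dedup_unique_tss(gl)
        observed[gl.label] = peaks_per_gene(
            peaks, unique, window=window, peak_point=peak_point
        ).distinct_peaks
        expected[gl.label] = expected_count(
            len(peaks), genome, unique, window=window, merge_windows=merge_windows
        )
    return enrichment_test(observed, expected)


# ---------------------------------------------------------------------------
# TSS-relative incidence histogram
# ---------------------------------------------------------------------------

@dataclass
class TSSHistogram:
    """Signed-distance histogram of peak incidence around a list's TSSs."""

    bin_edges: np.ndarray  # len n_bins + 1, from -range to +range
    counts: np.ndarray  # int per bin
    n_genes: int
    normalization: str = "counts"

    @property
    def values(self) -> np.ndarray:
        if self.normalization == "per-gene":
            return self.counts / max(self.n_genes, 1)
        return self.counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "count": self.counts,
                "value": self.values,
            }
        )


def tss_histogram(
    peaks: PeakSet,
    genes: GeneList,
    distance_range: int = DEFAULT_WINDOW,
    bin_width: int = 5_000,
    normalization: str = "counts",
) -> TSSHistogram:
    """Bin signed peak-midpoint distances to each gene's TSS.

    Strand-aware: upstream is always negative.  Bins are closed toward the
    TSS, so a distance exactly on an edge falls in the bin nearer the TSS,
    and ``|d| == distance_range`` is still counted.
    """
    if distance_range <= 0 or bin_width <= 0 or (2 * distance_range) % bin_width:
        raise ValueError("bin_width must divide 2 * distance_range")
    n_half = distance_range // bin_width
    n_bins = 2 * n_half
    counts = np.zeros(n_bins, dtype=np.int64)

    mids_lists: dict[str, list[int]] = {}
    for iv in peaks:
        mids_lists.setdefault(iv.chrom, []).append(midpoint(iv))
    mids_by_chrom = {
        c: np.sort(np.array(v, dtype=np.int64)) for c, v in mids_lists.items()
    }

    for g in genes:
        mids = mids_by_chrom.get(g.chrom)
        if mids is None or not len(mids):
            continue
        lo = int(np.searchsorted(mids, g.tss - distance_range, side="left"))
        hi = int(np.searchsorted(mids, g.tss + distance_range, side="right"))
        for m in mids[lo:hi]:
            d = signed_tss_distance(int(m), g)
            if d < 0:
                b = (d + distance_range) // bin_width  # left-closed upstream bins
            elif d == 0:
                b = n_half  # at the TSS: first downstream bin
            else:
                b = n_half + (d + bin_width - 1) // bin_width - 1  # right-closed
            counts[int(b)] += 1

    edges = np.arange(-distance_range, distance_range + bin_width, bin_width)
    return TSSHistogram(
        bin_edges=edges, counts=counts, n_genes=len(genes), normalization=normalization
    )


def plot_tss_histogram(hist: TSSHistogram, path, title: str = "") -> None:
    """Bar plot of a TSS-relative incidence histogram (written to ``path``)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2.0
    width = float(hist.bin_edges[1] - hist.bin_edges[0])
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(centers / 1000.0, hist.values, width=width / 1000.0 * 0.9, color="#4060a0")
    ax.set_xlabel("distance from TSS (kb)")
    ax.set_ylabel("peaks per gene" if hist.normalization == "per-gene" else "peaks")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# multi-factor peak overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapSummary:
    """How much of peak set A is touched by sets B (and optionally C)."""

    n_a: int
    count_ab: int
    fraction_ab: float
    count_ac: Optional[int] = None
    fraction_ac: Optional[float] = None
    triple_count: Optional[int] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items() if v is not None}


def overlap_summary(
    a: PeakSet, b: PeakSet, c: Optional[PeakSet] = None
) -> OverlapSummary:
    """Fractions of A peaks overlapped by B (and C), plus the triple count.

    The triple count is the number of A peaks overlapped by at least one B
    peak *and* at least one C peak.
    """
    mask_b = overlap_mask(a, b)
    n_a = len(a)
    out = OverlapSummary(
        n_a=n_a,
        count_ab=int(mask_b.sum()),
        fraction_ab=float(mask_b.mean()) if n_a else 0.0,
    )
    if c is not None:
        mask_c = overlap_mask(a, c)
        out.count_ac = int(mask_c.sum())
        out.fraction_ac = float(mask_c.mean()) if n_a else 0.0
        out.triple_count = int((mask_b & mask_c).sum())
    return out
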