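"""Synthetic genomes, gene lists, peak sets and sequences with known truth.

The generator emulates the study design the pipeline analyzes: a
multi-chromosome genome, three disjoint cell-type gene lists, a peak set
whose density within +/- ``window`` of one list's TSSs exceeds the uniform
background by a configurable fold, a matched control condition for the
overlap filter, and fixed-length sequences with a consensus motif planted
at a configurable rate and central positional bias.

All randomness flows through ``numpy.random.Generator`` objects derived
from ``SimConfig.seed`` plus a per-stage constant; there is no global
random state, and identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .intervals import merge_spans
from .models import GeneList, GeneRecord, GenomeModel, GenomicInterval, PeakSet
from .motifs import Motif, as_motif, expand_iupac, revcomp

_STAGE_GENES = 1
_STAGE_PEAKS = 2
_STAGE_CONTROL = 3
_STAGE_SEQS = 4

_LETTERS = np.array(list("ACGT"))
DEFAULT_LIST_LABELS = ("neuron", "astrocyte", "oligodendrocyte")


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Defaults mirror the analyzed study at desk scale: a 250 Mb genome
    (10 x 25 Mb), three disjoint 100-gene cell-type lists, 2,000 peaks with
    a 3-fold density excess within +/-100 kb of the oligodendrocyte-list
    TSSs, and 500 bp sequences carrying the CTGGYAC consensus in 80% of
    sequences with a tight (sd 10 bp) central bias.
    """

    seed: int = 0
    n_chroms: int = 10
    chrom_length: int = 25_000_000
    n_lists: int = 3
    genes_per_list: int = 100
    n_peaks: int = 2_000
    peak_width: Union[int, tuple[int, int]] = (200, 800)
    enrichment_fold: float = 3.0
    window: int = 100_000
    n_sequences: int = 100
    seq_length: int = 500
    motif: str = "CTGGYAC"
    plant_rate: float = 0.8
    central_sd: float = 10.0
    control_overlap_count: int = 17
    control_decoys: int = 0
    gene_body_min: int = 5_000
    gene_body_max: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate must be in [0, 1]")
        if self.enrichment_fold < 1.0:
            raise ValueError("enrichment_fold must be >= 1")
        for name in ("n_chroms", "chrom_length", "n_lists", "genes_per_list",
                     "window", "seq_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_peaks < 0 or self.n_sequences < 0:
            raise ValueError("counts must be non-negative")

    def list_labels(self) -> list[str]:
        if self.n_lists == len(DEFAULT_LIST_LABELS):
            return list(DEFAULT_LIST_LABELS)
        return [f"list_{i + 1}" for i in range(self.n_lists)]


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside generated data."""

    seed: int
    params: dict
    peak_truth: Optional[dict] = None
    control_truth: Optional[dict] = None
    sequence_truth: Optional[list[dict]] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def _config_echo(config: SimConfig) -> dict:
    return dataclasses.asdict(config)


# ---------------------------------------------------------------------------
# genome and gene lists
# ---------------------------------------------------------------------------

def make_genome_and_genes(config: SimConfig) -> tuple[GenomeModel, list[GeneList]]:
    """Uniform random TSSs with a minimum inter-TSS spacing, random strands,
    5-100 kb gene bodies, partitioned into disjoint labeled lists."""
    genome = GenomeModel(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )
    rng = _rng(config, _STAGE_GENES)
    n_genes = config.n_lists * config.genes_per_list
    min_spacing = 2 * config.window // 10
    if n_genes * min_spacing * 2 > genome.total_size:
        raise ValueError("genome too small for the requested number of genes")

    chroms = list(genome.chrom_sizes)
    placed: dict[str, list[int]] = {c: [] for c in chroms}
    records: list[tuple[str, int, str, int]] = []  # chrom, tss, strand, body
    attempts = 0
    max_attempts = 1000 * n_genes
    while len(records) < n_genes:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("could not place genes with the required TSS spacing")
        chrom = chroms[int(rng.integers(len(chroms)))]
        clen = genome[chrom]
        tss = int(rng.integers(0, clen))
        body = int(rng.integers(config.gene_body_min, config.gene_body_max + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+" and tss + body > clen:
            continue
        if strand == "-" and tss + 1 - body < 0:
            continue
        if any(abs(tss - t) < min_spacing for t in placed[chrom]):
            continue
        placed[chrom].append(tss)
        records.append((chrom, tss, strand, body))

    labels = config.list_labels()
    lists = []
    for li, label in enumerate(labels):
        genes = []
        for gi in range(config.genes_per_list):
            chrom, tss, strand, body = records[li * config.genes_per_list + gi]
            if strand == "+":
                tx_start, tx_end = tss, tss + body
            else:
                tx_start, tx_end = tss + 1 - body, tss + 1
            genes.append(
                GeneRecord(
                    gene_id=f"{label}_g{gi:03d}",
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    tx_start=tx_start,
                    tx_end=tx_end,
                )
            )
        lists.append(GeneList(label, genes))
    return genome, lists


# ---------------------------------------------------------------------------
# peaks with planted TSS-proximal enrichment
# ---------------------------------------------------------------------------

def _genome_offsets(genome: GenomeModel) -> tuple[list[str], np.ndarray]:
    chroms = list(genome.chrom_sizes)
    sizes = np.array([genome[c] for c in chroms], dtype=np.int64)
    return chroms, np.concatenate([[0], np.cumsum(sizes)])


def _global_to_chrom(
    positions: np.ndarray, chroms: list[str], bounds: np.ndarray
) -> list[tuple[str, int]]:
    idx = np.searchsorted(bounds, positions, side="right") - 1
    return [(chroms[i], int(p - bounds[i])) for i, p in zip(idx, positions)]


def _list_window_spans(
    genes: GeneList, window: int, genome: GenomeModel
) -> list[tuple[str, int, int]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        s = max(0, g.tss - window)
        e = min(genome[g.chrom], g.tss + window + 1)
        by_chrom.setdefault(g.chrom, []).append((s, e))
    out = []
    for chrom in sorted(by_chrom):
        for s, e in merge_spans(by_chrom[chrom]):
            out.append((chrom, s, e))
    return out


def simulate_peaks(
    config: SimConfig,
    genome: GenomeModel,
    lists: Sequence[GeneList],
    target_label: str,
) -> tuple[PeakSet, SyntheticTruth]:
    """Uniform background peaks plus targeted peaks near the target list's TSSs.

    With fold f, background peak count n_bg and targeted count n_t chosen so
    that the expected within-window density for the target list is f times
    the background density n_bg / G:

        density_target = (n_bg * W_T / G + n_t) / W_T = f * n_bg / G
        => n_t = (f - 1) * n_bg * W_T / G,  n_bg = n_total - n_t
        => n_t = (f - 1) * n_total * W_T / (G + (f - 1) * W_T)

    where W_T is the merged span of the +/-window windows around the target
    TSSs and G the genome size.  Targeted peak midpoints are uniform over
    that merged span (flat, matching the expectation model under test).
    """
    labels = [gl.label for gl in lists]
    if target_label not in labels:
        raise ValueError(f"unknown target list {target_label!r}")
    f = config.enrichment_fold
    if f < 1.0:
        raise ValueError("enrichment_fold must be >= 1")
    rng = _rng(config, _STAGE_PEAKS)
    G = genome.total_size
    target = lists[labels.index(target_label)]
    segments = _list_window_spans(target, config.window, genome)
    seg_lens = np.array([e - s for _, s, e in segments], dtype=np.int64)
    W_T = int(seg_lens.sum())

    n_total = config.n_peaks
    n_t = int(round((f - 1.0) * n_total * W_T / (G + (f - 1.0) * W_T)))
    n_bg = n_total - n_t

    chroms, bounds = _genome_offsets(genome)
    mids = _global_to_chrom(rng.integers(0, G, size=n_bg), chroms, bounds)
    if n_t:
        seg_bounds = np.concatenate([[0], np.cumsum(seg_lens)])
        pos = rng.integers(0, W_T, size=n_t)
        idx = np.searchsorted(seg_bounds, pos, side="right") - 1
        mids += [
            (segments[i][0], int(segments[i][1] + p - seg_bounds[i]))
            for i, p in zip(idx, pos)
        ]

    if isinstance(config.peak_width, tuple):
        lo, hi = config.peak_width
        widths = rng.integers(lo, hi + 1, size=n_total)
    else:
        widths = np.full(n_total, int(config.peak_width), dtype=np.int64)

    rows = []
    for (chrom, mid), w in zip(mids, widths):
        w = int(w)
        clen = genome[chrom]
        half = w // 2
        mid = min(max(mid, half), clen - (w - half))
        rows.append((chrom, mid - half, mid - half + w))
    rows.sort()
    intervals = [
        GenomicInterval(chrom, s, e, name=f"pk_{i:05d}")
        for i, (chrom, s, e) in enumerate(rows)
    ]
    peaks = PeakSet("treatment", intervals, genome)

    # realized per-list statistics against the true background density n_bg/G
    bg_density = n_bg / G if n_bg else n_total / G
    mids_by_chrom: dict[str, list[int]] = {}
    for iv in intervals:
        mids_by_chrom.setdefault(iv.chrom, []).append((iv.start + iv.end) // 2)
    mids_arr = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in mids_by_chrom.items()}
    realized = {}
    for gl in lists:
        spans = _list_window_spans(gl, config.window, genome)
        span_total = sum(e - s for _, s, e in spans)
        count = 0
        for chrom, s, e in spans:
            arr = mids_arr.get(chrom)
            if arr is not None:
                count += int(
                    np.searchsorted(arr, e, side="left")
                    - np.searchsorted(arr, s, side="left")
                )
        density = count / span_total if span_total else 0.0
        realized[gl.label] = {
            "window_span": span_total,
            "peaks_in_windows": count,
            "density": density,
            "fold_vs_background": density / bg_density if bg_density else 0.0,
        }

    truth = SyntheticTruth(
        seed=config.seed,
        params=_config_echo(config),
        peak_truth={
            "target_label": target_label,
            "n_peaks": n_total,
            "n_targeted": n_t,
            "n_background": n_bg,
            "target_window_span": W_T,
            "background_density": bg_density,
            "per_list": realized,
        },
    )
    return peaks, truth


def simulate_control(config: SimConfig, peaks: PeakSet) -> PeakSet:
    """Control peaks overlapping exactly ``control_overlap_count`` treatment peaks.

    Each constructed control peak is nested inside a treatment peak that
    itself overlaps no other treatment peak, so the downstream overlap
    filter removes exactly the planted count.  Optional decoy control peaks
    overlap nothing.
    """
    k = config.control_overlap_count
    if k > len(peaks):
        raise ValueError("control_overlap_count exceeds the number of peaks")
    rng = _rng(config, _STAGE_CONTROL)
    genome = peaks.genome

    # candidates: treatment peaks isolated from all other treatment peaks
    ivs = sorted(peaks, key=lambda iv: (iv.chrom, iv.start, iv.end))
    isolated = []
    for i, iv in enumerate(ivs):
        prev_ok = i == 0 or ivs[i - 1].chrom != iv.chrom or ivs[i - 1].end <= iv.start
        next_ok = (
            i == len(ivs) - 1
            or ivs[i + 1].chrom != iv.chrom
            or iv.end <= ivs[i + 1].start
        )
        if prev_ok and next_ok:
            isolated.append(iv)
    if len(isolated) < k:
        raise ValueError("not enough isolated treatment peaks to plant control overlaps")
    chosen_idx = rng.choice(len(isolated), size=k, replace=False)
    controls = []
    for j, ci in enumerate(sorted(int(i) for i in chosen_idx)):
        iv = isolated[ci]
        third = max(iv.length // 3, 1)
        s = iv.start + third
        e = min(s + third, iv.end)
        controls.append(GenomicInterval(iv.chrom, s, max(e, s + 1), name=f"ctl_{j:04d}"))

    if config.control_decoys and genome is not None:
        chroms, bounds = _genome_offsets(genome)
        occupied = sorted(
            [(iv.chrom, iv.start, iv.end) for iv in peaks]
            + [(iv.chrom, iv.start, iv.end) for iv in controls]
        )
        made = 0
        while made < config.control_decoys:
            chrom, pos = _global_to_chrom(
                rng.integers(0, genome.total_size, size=1), chroms, bounds
            )[0]
            w = 300
            s, e = pos, min(pos + w, genome[chrom])
            if e <= s:
                continue
            if any(c == chrom and s < oe and os_ < e for c, os_, oe in occupied):
                continue
            controls.append(
                GenomicInterval(chrom, s, e, name=f"decoy_{made:04d}")
            )
            occupied.append((chrom, s, e))
            occupied.sort()
            made += 1

    controls.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return PeakSet("control", controls, genome)


# ---------------------------------------------------------------------------
# sequences with a planted motif
# ---------------------------------------------------------------------------

def simulate_sequences(
    config: SimConfig,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """I.i.d. uniform-ACGT sequences, a fraction carrying one motif instance.

    Planted instances realize degenerate positions uniformly, land on a
    random strand, and are centered at an offset drawn from a normal around
    the sequence midpoint with sd ``central_sd`` (clipped to valid offsets).
    """
    motif = as_motif(config.motif)
    m = len(motif)
    L = config.seq_length
    if L <= m:
        raise ValueError("seq_length must exceed the motif length")
    rng = _rng(config, _STAGE_SEQS)
    words = sorted(expand_iupac(motif))

    records: list[tuple[str, str]] = []
    plants: list[dict] = []
    for i in range(config.n_sequences):
        seq_id = f"seq_{i:04d}"
        letters = _LETTERS[rng.integers(0, 4, size=L)]
        entry: dict = {"seq_id": seq_id, "planted": False}
        if rng.random() < config.plant_rate:
            offset = int(round(rng.normal((L - m) / 2.0, config.central_sd)))
            offset = min(max(offset, 0), L - m)
            word = words[int(rng.integers(len(words)))]
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = word if strand == "+" else revcomp(word)
            letters[offset : offset + m] = list(inserted)
            entry.update(planted=True, offset=offset, strand=strand, word=word)
        records.append((seq_id, "".join(letters)))
        plants.append(entry)

    truth = SyntheticTruth(
        seed=config.seed, params=_config_echo(config), sequence_truth=plants
    )
    return records, truth


def shuffle_sequences(
    records: Sequence[tuple[str, str]], seed: int
) -> list[tuple[str, str]]:
    """Per-sequence letter permutation: preserves composition, destroys motifs."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    out = []
    for seq_id, seq in records:
        letters = np.array(list(seq))
        rng.shuffle(letters)
        out.append((f"{seq_id}_shuf", "".join(letters)))
    return out
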