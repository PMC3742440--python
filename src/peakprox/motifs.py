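"""IUPAC consensus motif scanning and enrichment statistics.

Covers the motif side of the analysis: double-strand scanning for a
degenerate consensus (e.g. CTGGYAC, where Y = C or T), a central-enrichment
test of the best site per sequence against a uniform-position null, a
spaced-pair statistic for fixed-gap co-occurrence (evidence of multimeric
binding), and a discriminative exact-k-mer discovery stage with one-letter
IUPAC generalization.

An ``N`` in a sequence never matches any motif letter — masked bases must
not create hits.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASES_TO_IUPAC = {frozenset(v): k for k, v in IUPAC.items()}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Motif:
    """A consensus pattern over the IUPAC nucleotide alphabet."""

    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("motif must be non-empty")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC characters {sorted(bad)}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)

    def __str__(self) -> str:
        return self.iupac


MotifLike = Union[Motif, str]


def as_motif(motif: MotifLike) -> Motif:
    return motif if isinstance(motif, Motif) else Motif(motif)


def expand_iupac(motif: MotifLike) -> set[str]:
    """All exact m-mers matching the consensus (Cartesian expansion)."""
    m = as_motif(motif)
    return {"".join(p) for p in itertools.product(*(IUPAC[c] for c in m.iupac))}


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement (Y<->R, W<->W, ...)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``offset`` is the first base in forward coordinates,
    ``matched`` the m-mer as read on the hit strand."""

    seq_id: str
    offset: int
    strand: str
    matched: str


def _pattern(motif: Motif) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported; character
    # classes contain only ACGT, so N in the sequence can never match
    return re.compile("(?=(" + "".join(f"[{IUPAC[c]}]" for c in motif.iupac) + "))")


def scan(
    sequence: str,
    motif: MotifLike,
    both_strands: bool = True,
    seq_id: str = "",
) -> list[MotifHit]:
    """All occurrences of the consensus in a sequence, ordered by (offset, strand).

    Reverse-strand hits are reported at their forward offset; a window hits
    the minus strand when its reverse complement matches the motif, i.e.
    when the window matches ``revcomp(motif)`` read forward.
    """
    m = as_motif(motif)
    seq = sequence.upper()
    if len(seq) < len(m):
        return []
    hits = [
        MotifHit(seq_id, mo.start(), "+", mo.group(1))
        for mo in _pattern(m).finditer(seq)
    ]
    if both_strands:
        rc = Motif(revcomp(m.iupac))
        hits.extend(
            MotifHit(seq_id, mo.start(), "-", revcomp(mo.group(1)))
            for mo in _pattern(rc).finditer(seq)
        )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_bruteforce(
    sequence: str, motif: MotifLike, both_strands: bool = True, seq_id: str = ""
) -> list[MotifHit]:
    """Oracle for :func:`scan`: test every offset against the expanded m-mer set."""
    m = as_motif(motif)
    words = expand_iupac(m)
    seq = sequence.upper()
    hits = []
    for o in range(len(seq) - len(m) + 1):
        window = seq[o : o + len(m)]
        if window in words:
            hits.append(MotifHit(seq_id, o, "+", window))
        if both_strands and revcomp(window) in words:
            hits.append(MotifHit(seq_id, o, "-", revcomp(window)))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _normalize_seqs(sequences: Sequence) -> list[tuple[str, str]]:
    out = []
    for i, item in enumerate(sequences):
        if isinstance(item, str):
            out.append((f"seq_{i}", item.upper()))
        else:
            sid, seq = item
            out.append((str(sid), seq.upper()))
    return out


# ---------------------------------------------------------------------------
# central enrichment
# ---------------------------------------------------------------------------

@dataclass
class CentralEnrichmentResult:
    """Binomial test of best-site positions against a uniform-position null."""

    n_sequences: int
    n_sequences_with_hit: int
    n_central: int
    central_width: int
    null_prob: float
    p_value: float


def _hit_center(hit: MotifHit, m: int) -> float:
    return hit.offset + (m - 1) / 2.0


def central_enrichment(
    sequences: Sequence,
    motif: MotifLike,
    central_width: int = 100,
    best_site: bool = True,
) -> CentralEnrichmentResult:
    """Test whether motif sites concentrate in the center of fixed-length sequences.

    For each sequence with >= 1 hit the best hit is taken (closest center to
    the sequence midpoint; ties broken + strand then leftmost); the number
    whose hit center falls within the central window of ``central_width`` bp
    is compared against a binomial null where every valid offset is equally
    likely.  ``best_site=False`` instead counts every hit against the same
    per-site null.  With no hits at all, p = 1 by convention.
    """
    m = as_motif(motif)
    seqs = _normalize_seqs(sequences)
    if not seqs:
        return CentralEnrichmentResult(0, 0, 0, central_width, 0.0, 1.0)
    lengths = {len(s) for _, s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences must all have the same length, got {sorted(lengths)}")
    L = lengths.pop()
    if central_width >= L:
        raise ValueError("central_width must be smaller than the sequence length")
    n_offsets = L - len(m) + 1
    if n_offsets <= 0:
        return CentralEnrichmentResult(len(seqs), 0, 0, central_width, 0.0, 1.0)

    seq_center = (L - 1) / 2.0
    offsets = np.arange(n_offsets)
    centers = offsets + (len(m) - 1) / 2.0
    central_offsets = np.abs(centers - seq_center) <= central_width / 2.0
    null_prob = float(central_offsets.mean())

    def is_central(hit: MotifHit) -> bool:
        return abs(_hit_center(hit, len(m)) - seq_center) <= central_width / 2.0

    n_with_hit = 0
    n_central = 0
    n_sites = 0
    n_sites_central = 0
    for sid, seq in seqs:
        hits = scan(seq, m, both_strands=True, seq_id=sid)
        if not hits:
            continue
        n_with_hit += 1
        n_sites += len(hits)
        n_sites_central += sum(is_central(h) for h in hits)
        best = min(
            hits,
            key=lambda h: (
                abs(_hit_center(h, len(m)) - seq_center),
                0 if h.strand == "+" else 1,
                h.offset,
            ),
        )
        if is_central(best):
            n_central += 1

    if best_site:
        trials, successes = n_with_hit, n_central
    else:
        trials, successes = n_sites, n_sites_central
    p = 1.0 if trials == 0 else float(stats.binom.sf(successes - 1, trials, null_prob))
    return CentralEnrichmentResult(
        n_sequences=len(seqs),
        n_sequences_with_hit=n_with_hit,
        n_central=n_central if best_site else n_sites_central,
        central_width=central_width,
        null_prob=null_prob,
        p_value=min(max(p, 0.0), 1.0),
    )


# ---------------------------------------------------------------------------
# spaced-pair statistic
# ---------------------------------------------------------------------------

@dataclass
class SpacingReport:
    """Counts of motif co-occurrences at each inter-motif gap, with a
    Bonferroni-adjusted binomial test of the modal gap."""

    counts: np.ndarray  # index = gap in bp, 0..max_gap
    best_gap: Optional[int]
    n_pairs: int
    p_value: float


def spaced_pair(
    sequences: Sequence,
    primary: MotifLike,
    secondary: MotifLike,
    max_gap: int = 10,
) -> SpacingReport:
    """Tally primary/secondary hit pairs by the number of bases strictly
    between the two matches (either order on the sequence).

    Overlapping matches (negative gap) are ignored.  Under the null the
    qualifying pairs spread uniformly over the ``max_gap + 1`` gap bins; the
    modal bin is tested with a binomial upper tail, Bonferroni-multiplied by
    the number of bins.  When primary and secondary are the same motif each
    unordered hit pair is counted once.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    p_m = as_motif(primary)
    s_m = as_motif(secondary)
    same = p_m.iupac == s_m.iupac
    counts = np.zeros(max_gap + 1, dtype=np.int64)

    for sid, seq in _normalize_seqs(sequences):
        p_hits = scan(seq, p_m, both_strands=True, seq_id=sid)
        s_hits = p_hits if same else scan(seq, s_m, both_strands=True, seq_id=sid)
        if same:
            pairs = itertools.combinations(p_hits, 2)
        else:
            pairs = itertools.product(p_hits, s_hits)
        for h1, h2 in pairs:
            # h1 is always a primary hit, h2 a secondary hit (identical when same)
            if h1.offset <= h2.offset:
                left, right, left_len = h1, h2, len(p_m)
            else:
                left, right, left_len = h2, h1, len(s_m)
            gap = right.offset - (left.offset + left_len)
            if 0 <= gap <= max_gap:
                counts[gap] += 1

    n_pairs = int(counts.sum())
    if n_pairs == 0:
        return SpacingReport(counts=counts, best_gap=None, n_pairs=0, p_value=1.0)
    best_gap = int(np.argmax(counts))
    null_p = 1.0 / (max_gap + 1)
    tail = float(stats.binom.sf(int(counts[best_gap]) - 1, n_pairs, null_p))
    p = min(1.0, tail * (max_gap + 1))
    return SpacingReport(counts=counts, best_gap=best_gap, n_pairs=n_pairs, p_value=p)


# ---------------------------------------------------------------------------
# discriminative k-mer discovery
# ---------------------------------------------------------------------------

@dataclass
class DiscoveredMotif:
    """One motif reported by the discriminative search."""

    iupac: str
    pos_count: int
    neg_count: int
    fisher_p: float
    e_value: float


def canonical_kmer(kmer: str) -> str:
    """Strand-collapsed representative: the lexicographically smaller of the
    k-mer and its reverse complement (palindromes map to themselves)."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _seq_kmer_set(seq: str, ks: Sequence[int]) -> frozenset:
    out = set()
    for k in ks:
        for o in range(len(seq) - k + 1):
            w = seq[o : o + k]
            if "N" not in w:
                out.add(canonical_kmer(w))
    return frozenset(out)


def _fisher_greater(a: int, b: int, n_pos: int, n_neg: int) -> float:
    """One-sided Fisher exact p for enrichment in positives: P(X >= a) with
    margins fixed at (n_pos, n_neg) set sizes and a+b containing sequences."""
    return float(stats.hypergeom.sf(a - 1, n_pos + n_neg, a + b, n_pos))


def _contains_motif(kmer_set: frozenset, expansions: set[str]) -> bool:
    return any(canonical_kmer(w) in kmer_set for w in expansions)


def _motif_counts(
    expansions: set[str], pos_sets: list[frozenset], neg_sets: list[frozenset]
) -> tuple[int, int]:
    canon = {canonical_kmer(w) for w in expansions}
    a = sum(1 for s in pos_sets if s & canon)
    b = sum(1 for s in neg_sets if s & canon)
    return a, b


def _generalize(
    best: str,
    best_p: float,
    present: set[str],
    pos_sets: list[frozenset],
    neg_sets: list[frozenset],
    variant_alpha: float = 0.05,
) -> tuple[str, int, int, float]:
    """Try merging the best exact k-mer with one-mismatch neighbours into a
    motif with a single IUPAC ambiguity letter, keeping the merge only when
    it improves the Fisher p-value.

    Only neighbours that are themselves enriched (individual Fisher p below
    ``variant_alpha``) may join, so a chance-level variant cannot ride along
    with a strong word and over-degenerate the motif.
    """
    n_pos, n_neg = len(pos_sets), len(neg_sets)
    a0, b0 = _motif_counts({best}, pos_sets, neg_sets)
    champion = (best, a0, b0, best_p)

    def _enriched(word: str) -> bool:
        if canonical_kmer(word) not in present:
            return False
        a, b = _motif_counts({word}, pos_sets, neg_sets)
        return _fisher_greater(a, b, n_pos, n_neg) < variant_alpha

    for pos in range(len(best)):
        letters = {best[pos]}
        variants = [
            x
            for x in "ACGT"
            if x != best[pos] and _enriched(best[:pos] + x + best[pos + 1 :])
        ]
        current_p = best_p
        current = None
        while variants:
            trials = []
            for x in variants:
                trial_letters = letters | {x}
                expansions = {best[:pos] + l + best[pos + 1 :] for l in trial_letters}
                a, b = _motif_counts(expansions, pos_sets, neg_sets)
                trials.append((_fisher_greater(a, b, n_pos, n_neg), x, a, b, trial_letters))
            trials.sort(key=lambda t: (t[0], t[1]))
            p, x, a, b, trial_letters = trials[0]
            if p >= current_p:
                break
            letters = trial_letters
            current_p = p
            current = (a, b, p)
            variants.remove(x)
        if current is not None and current_p < champion[3]:
            code = _BASES_TO_IUPAC[frozenset(letters)]
            iupac = best[:pos] + code + best[pos + 1 :]
            champion = (iupac, current[0], current[1], current[2])
    return champion


def discover(
    positives: Sequence,
    negatives: Sequence,
    k_range: Sequence[int] = (6, 7, 8),
    rounds: int = 2,
) -> list[DiscoveredMotif]:
    """Discriminative motif discovery by exact k-mer counting.

    Every strand-collapsed exact k-mer present in the positive set is scored
    by a one-sided Fisher exact test of positive-vs-negative sequence
    counts.  The best exact word is then generalized by merging one-mismatch
    neighbours into a single IUPAC ambiguity letter whenever the merge
    improves the p-value (e.g. CTGGCAC + CTGGTAC -> CTGGYAC).  The reported
    E-value is a Bonferroni-style surrogate, p x number of candidates
    evaluated.  After each reported motif, sequences containing it are
    masked out and one further round is run.
    """
    pos = [s for _, s in _normalize_seqs(positives)]
    neg = [s for _, s in _normalize_seqs(negatives)]
    if not pos or not neg:
        raise ValueError("both sequence sets must be non-empty")
    ks = sorted(set(int(k) for k in k_range))

    results: list[DiscoveredMotif] = []
    for _ in range(max(rounds, 1)):
        if not pos or not neg:
            break
        pos_sets = [_seq_kmer_set(s, ks) for s in pos]
        neg_sets = [_seq_kmer_set(s, ks) for s in neg]
        pos_counts: dict[str, int] = {}
        for s in pos_sets:
            for w in s:
                pos_counts[w] = pos_counts.get(w, 0) + 1
        if not pos_counts:
            break
        neg_counts: dict[str, int] = {}
        for s in neg_sets:
            for w in s:
                if w in pos_counts:
                    neg_counts[w] = neg_counts.get(w, 0) + 1

        candidates = sorted(pos_counts)
        a = np.array([pos_counts[w] for w in candidates])
        b = np.array([neg_counts.get(w, 0) for w in candidates])
        n_pos, n_neg = len(pos_sets), len(neg_sets)
        pvals = stats.hypergeom.sf(a - 1, n_pos + n_neg, a + b, n_pos)
        n_candidates = len(candidates)

        order = np.lexsort((np.array(candidates, dtype=object), pvals))
        best_idx = int(order[0])
        best = candidates[best_idx]
        best_p = float(pvals[best_idx])

        present = set(candidates)
        iupac, a_m, b_m, p_m = _generalize(best, best_p, present, pos_sets, neg_sets)
        results.append(
            DiscoveredMotif(
                iupac=iupac,
                pos_count=a_m,
                neg_count=b_m,
                fisher_p=p_m,
                e_value=p_m * n_candidates,
            )
        )

        expansions = expand_iupac(iupac)
        canon = {canonical_kmer(w) for w in expansions}
        pos = [s for s, ks_ in zip(pos, pos_sets) if not ks_ & canon]
        neg = [s for s, ks_ in zip(neg, neg_sets) if not ks_ & canon]

    results.sort(key=lambda r: (r.e_value, r.fisher_p, r.iupac))
    return results
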