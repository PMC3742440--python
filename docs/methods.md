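# Methods

This note documents the statistical model behind `peakprox`, the choices
made where conventions genuinely differ between tools, what the synthetic
data does and does not emulate, and the problem sizes the test suite and
acceptance script run at.

## Coordinates and distances

All intervals are 0-based half-open (BED convention); gene-table TSSs are
0-based so a single internal convention holds everywhere, converted only at
I/O edges.  A gene's TSS is its strand-aware 5' base: `tss == tx_start` on
the + strand and `tss == tx_end − 1` on the − strand, and the readers
enforce this so inconsistent tables fail loudly rather than silently
shifting distances by one.

The reference point of a peak is the floor midpoint of its interval.
Published analyses are often silent on whether a peak counts by midpoint,
summit, or any overlap; the midpoint prevents a wide peak straddling a
window edge from being counted in two bins, and an `any-overlap` mode is
available behind a flag for sensitivity analysis.  Window and bin
boundaries are closed toward the TSS (a midpoint exactly `window` bp away
still counts; a distance exactly on a histogram edge joins the bin nearer
the TSS; a distance of exactly 0 joins the first downstream bin).  These
tie-breaks are arbitrary but deterministic and documented.

"Corresponding peak" in the control filter means ≥ 1 bp overlap — the
simplest reproducible reading.  A stricter reciprocal-fraction criterion
would need a threshold with no principled default at peak-call resolution.

## Proximity categories

A peak midpoint inside the gene body is GENE_BODY regardless of TSS
distance, taking precedence over the ≤ 1 kb upstream bin for peaks inside
long genes close to the TSS — "within the gene" is its own biological
category (intronic enhancers), not a distance bin.  Upstream bins break at
1 kb / 20 kb / `window`; downstream midpoints past the 3' end within
`window` of the TSS form one category.  Categories are mutually exclusive
per (peak, gene) pair; a peak may of course relate differently to
different genes.

## The uniform background and the enrichment test

Under uniform placement of `n` peaks on a genome of `G` bp, the density is
λ = n/G and the mean spacing G/n (for 2,085 peaks on 2.75 Gb: one peak per
≈ 1.32 Mb).  The default expected count for a gene list uses the naive
span — unique TSSs × 2 × window — without merging overlapping windows or
clipping at chromosome ends.  This is deliberately the back-of-envelope
model (for 200 genes, ±100 kb, 2,085 peaks on 2.75 Gb it gives 30.3
expected peaks); `merge_windows=True` uses the merged, clipped union span
instead, which is the correct denominator when observed counts are
*distinct* peaks in the union.  Gene lists are deduplicated to unique
(chrom, tss, strand) before counting so multi-isoform genes are not
over-represented; per-gene tallies (1 / 2 / ≥3 peaks) use per-gene
counting, while the list-level total counts each peak once even when it
sits in two genes' windows.  Both are reported because they answer
different questions (genes with multiple binding events vs overall binding
density).

The chi-squared machinery emits two things:

* a **joint goodness-of-fit** over the lists, with expectations scaled to
  the observed total and df = n_lists − 1.  Scaling makes the test a
  comparison of how peaks *distribute* among the lists' windows, which is
  the calibrated classical GOF: with externally fixed (unscaled)
  expectations the statistic would be ≈ χ²(n_lists), not χ²(n_lists − 1),
  and the test would over-reject under the null;
* **per-list one-sample tests** (df = 1) of each count against its
  absolute uniform expectation, plus the fold observed/expected.

Type-I calibration of the joint test is verified empirically on 200 null
simulations (see below); the observed rejection rate is slightly
conservative because in-window counts are sums of Bernoulli indicators
(variance np(1−p) < np), which is acceptable.

## Motif statistics

*Scanning.*  A consensus is matched as the set of its exact IUPAC
expansions, on both strands; reverse-strand hits are reported at their
forward offset with the matched word as read on the hit strand.  An `N` in
a sequence never matches any motif letter (including motif `N`): masked
bases must not create hits.  The production scanner compiles a regex with
a lookahead so overlapping hits are all reported; a per-offset brute-force
oracle is shipped in the package and the two are checked for equality on
random sequences.

*Central enrichment.*  One best site per sequence (the site whose center is
closest to the sequence midpoint; ties: + strand, then leftmost) is used,
approximating the best-site model of central-enrichment tools and making
the statistic robust to per-sequence hit-count differences; an all-sites
mode is available behind a flag.  The null probability is the fraction of
valid offsets whose site center lies within the central window, so the
binomial tail P(X ≥ n_central) is exact under the uniform-position null.
With zero motif-bearing sequences, p = 1 by convention.

*Spaced pairs.*  The gap between two sites is the number of bases strictly
between the matched words ("separated by 3 bp" = 3 intervening bases);
overlapping site pairs are excluded.  When primary and secondary are the
same motif, unordered pairs are counted once.  The modal gap is tested
against a uniform-over-gaps binomial null, Bonferroni-multiplied by the
number of gap bins and capped at 1.  This is a screening statistic, not a
replacement for a full spacing-analysis null that models sequence
composition.

*Discovery.*  Every strand-collapsed exact k-mer (k ∈ {6, 7, 8};
palindromes counted once) present in the positive set is scored by a
one-sided Fisher exact test (hypergeometric tail, vectorized) of the
number of positive vs negative sequences containing it.  The best word is
generalized by introducing a single IUPAC ambiguity letter: one-mismatch
neighbours may be merged only if they are individually enriched (their own
Fisher p < 0.05) and the merge improves the merged motif's p.  The
individual-enrichment gate prevents a chance-level neighbour from riding
along with a strong word and over-degenerating the consensus.  The
reported E-value is p × number of candidates evaluated — a Bonferroni
surrogate, not the exact E-value a dedicated discovery tool computes.
After a motif is reported, sequences containing it are masked out and one
further round runs, so a second independent signal can surface.

## The synthetic-data generator

The generator emulates the study design the pipeline is built for, at desk
scale: a 10 × 25 Mb genome; three disjoint cell-type lists
(neuron/astrocyte/oligodendrocyte) of 100 genes each, TSSs uniform with a
minimum spacing of 2·window/10 (20 kb), random strands, 5–100 kb bodies;
2,000 peaks of 200–800 bp (MACS-like call widths); 100 sequences of 500 bp
with the consensus planted in 80% of them, centered with sd 10 bp.  The
defaults are the conditions under which the package's claims are tested.

Targeted enrichment is planted by splitting the `n` peaks into `n_bg`
uniform background peaks and `n_t` peaks whose midpoints are uniform over
the merged ±window span `W_T` of the target list's TSSs, with

    n_t = (f − 1) · n · W_T / (G + (f − 1) · W_T)

which makes the expected in-window density exactly `f` times the *true*
background density `n_bg/G`.  The pipeline's estimator divides by the
total-peak density `n/G` instead (it cannot know how many peaks are
planted), so its expected estimate is f·G/(G + (f−1)·W_T) ≈ 2.6 for f = 3
under the default geometry — a known, documented attenuation of roughly
13%, inherent to estimating background from a peak set that contains the
signal.  Recovery is therefore assessed on the mean over 20 seeded
replicates with a ±20% band, which the attenuated estimate meets with
margin; per-seed estimates scatter with sd ≈ 0.07 around it.  Planted
peaks are placed flat within the window (not TSS-peaked), matching the
flat expectation model under test.

The control condition plants exactly `control_overlap_count` control peaks
nested inside treatment peaks that are isolated from all other treatment
peaks, so the overlap filter provably removes exactly the planted count;
optional decoy control peaks overlap nothing.

Everything is a pure function of (config, seed): each generator stage
derives its own `numpy` Generator from `SeedSequence([seed, stage])`, and
identical configs give byte-identical files.

What the generator does **not** emulate: read-level ChIP-seq artifacts
(fragment-length effects, open-chromatin "sono-seq" background, mappability
gaps), base-composition structure (backgrounds are i.i.d. uniform ACGT, and
discovery negatives are per-sequence letter shuffles preserving only
mononucleotide composition), realistic gene clustering, or TSS-peaked
binding-site distributions (a Laplace-shaped placement option would be the
natural extension for histogram-shape studies).  Passing tests show the
statistics behave correctly under their stated nulls and recover planted
signal of realistic size — not that real chromatin satisfies those nulls.

## Problem sizes used by the tests and acceptance script

Oracle equivalence runs ≥ 1,100 random instances (interval sets ≤ 40 × 3
chromosomes; sequences ≤ 400 bp over six motifs).  Type-I calibration uses
200 null replicates of the full default study (2,000 peaks, 300 genes,
250 Mb) and checks the rejection count at α = 0.05 against the exact
binomial 99% interval.  Fold recovery averages 20 replicates at f = 3;
motif recovery runs 20 replicates of discovery on 100 positives vs 100
shuffled negatives and requires rank-1 recovery of CTGGYAC (or its reverse
complement GTRCCAG) in ≥ 18, with the central-enrichment p below 1e-6 in
every run.  The whole suite completes in well under a minute on one core.

## Known limitations

* The naive expected-count model ignores window overlap and chromosome
  edges by design; with dense gene lists the merged variant should be used.
* The joint chi-squared test conditions on the observed total and so says
  nothing about absolute peak excess over the whole genome — that is what
  the per-list tests are for.
* Discovery is exact-word based; motifs with two or more degenerate
  positions are only found if one degenerate position dominates
  (generalization introduces a single IUPAC letter per motif).
* The spaced-pair and central-enrichment nulls assume position-independent
  backgrounds; strongly biased composition (CpG islands, repeats) will
  inflate significance, as it does for the tools these statistics mirror.
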