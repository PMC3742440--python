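# peakprox

ChIP-seq peak-to-TSS proximity analysis and consensus-motif statistics.

`peakprox` is for regulatory-genomics analyses that ask: *does a
transcription factor's ChIP-seq peak set concentrate around the
transcription start sites (TSSs) of one cell type's signature genes, and
does a short consensus motif explain its binding?*  The motivating use case
is a factor such as MYRF, whose peaks cluster around oligodendrocyte
(myelination) genes and which binds the degenerate consensus CTGGYAC
(Y = C or T).  The package provides the full downstream pipeline — peak
filtering against a negative-control condition, strand-aware peak/TSS
annotation, enrichment against a uniform-genome background, TSS-relative
incidence histograms, multi-factor peak overlap, and motif
scanning/centrality/spacing/discovery — plus a synthetic-data generator
with recorded ground truth so every stage is testable without downloads.

## The model

Peaks are half-open BED intervals; the reference point of a peak is its
midpoint *m*.  For a gene with TSS *t* on strand *s*, the signed distance is

    d = m − t   (s = +)        d = t − m   (s = −)

so negative is always upstream.  A peak is assigned to a gene when
|d| ≤ *W* (default *W* = 100 kb).  Under a uniform null, *n* peaks on a
genome of size *G* have density λ = n/G (one peak every G/n bp), and a list
of *k* unique TSSs is expected to attract

    E = λ · k · 2W

peaks (the naive span; a merged-window variant subtracts overlap between
nearby genes' windows).  Fold enrichment is observed/E per list; a joint
chi-squared goodness-of-fit (df = number of lists − 1, expectations scaled
to the observed total) tests whether peaks distribute among the lists'
windows as their spans predict, and per-list one-sample chi-squared tests
(df = 1) compare each count with its absolute expectation.

Motif statistics treat an IUPAC consensus as the set of its exact
expansions, scanned on both strands (an `N` in a sequence never matches).
Central enrichment takes the best site per fixed-length sequence and tests
the number falling in a central window against a binomial null with every
offset equally likely.  Spaced-pair analysis bins co-occurring site pairs by
the number of bases strictly between them and tests the modal gap
(Bonferroni-adjusted binomial).  Discovery scores every strand-collapsed
exact k-mer (k = 6–8) by a one-sided Fisher exact test of
positive-vs-negative sequence counts, then generalizes the best word by
merging one-mismatch, individually enriched neighbours into a single IUPAC
ambiguity letter (CTGGCAC + CTGGTAC → CTGGYAC).

## Worked example

Generate a synthetic study — a 250 Mb genome, three disjoint 100-gene
cell-type lists, and 2,000 peaks planted with a 3-fold density excess within
±100 kb of the oligodendrocyte-list TSSs — then measure the enrichment:

```bash
peakprox simulate --preset fig3-enriched --seed 1 --out demo
peakprox enrich --peaks demo/peaks.bed --genes demo/genes.tsv \
    --chrom-sizes demo/chrom.sizes --merge-windows --out demo/enrichment.json
```

```
neuron: observed 165, expected 155.4, fold 1.06
astrocyte: observed 162, expected 154.9, fold 1.05
oligodendrocyte: observed 393, expected 158.1, fold 2.49
joint chi2 139.69 (df 2), p 4.63e-31
```

The two non-target lists sit at the uniform background (fold ≈ 1), the
target list carries the planted excess, and the joint test rejects
decisively.  (The estimate 2.49 sits below the planted 3 because the
planted peaks themselves inflate the total-peak background estimate; see
`docs/methods.md`.)  The motif side, on 100 sequences of 500 bp with
CTGGYAC planted in 80% of them near the center:

```bash
peakprox simulate --preset fig6-motif --seed 1 --out demo6
peakprox centrimo --fasta demo6/sequences.fa --motif CTGGYAC --out demo6/cent.json
peakprox discover --positives demo6/sequences.fa \
    --negatives demo6/negatives.fa --out demo6/disc.json
```

```
74/76 central (null 0.202), p = 8.42e-49
CTGGYAC: 76 pos / 11 neg, p = 7e-22, E = 2.49e-17
TYTCTCA: 9 pos / 4 neg, p = 8.92e-05, E = 1.63
```

74 of the 76 motif-bearing sequences have their best site in the central
100 bp (null expectation 20%), and discovery returns the planted consensus
at rank 1 with a decisive E-value; the second reported motif is at the
noise floor (E > 1).  `peakprox run --config run.yaml --out out/` chains
all stages from one YAML config and writes a self-describing
`summary.json` (parameter echo, input checksums, versions).

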