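# radip

A Python toolkit for mapping RNA–chromatin interactions from proximity-ligation
libraries in which each sequencing read is a chimera of an RNA-derived tag, an
internal bridge adaptor, and a DNA-derived tag. Such libraries — produced by
RADICL-seq-style protocols and their immunoprecipitation variants that select
contacts at a chosen histone mark (e.g. H3K27me3) — ask two questions this
package answers end to end:

1. **Which (RNA, locus) contacts exceed the non-specific background?**
2. **Which RNAs are enriched by the immunoprecipitation relative to the
   un-selected Input library?**

It is written for computational genomicists analysing caRNA
(chromatin-associated RNA) interactomes, and for method developers who need a
fully simulated, ground-truth-controlled version of such an experiment.

## What it does

- **`radip.synthetic_data`** — simulates the whole experiment: a toy genome,
  a stranded gene annotation, a ground-truth interaction table with
  exponentially distance-decayed cis contact frequencies, a trans fraction,
  and optional fold-enrichment at designated peak bins (IP condition); emits
  the chimeric FASTQ plus truth SAM alignments.
- **`radip.deconvolve`** — splits reads at the internal bridge adaptor
  (leftmost Hamming match), size-selects the 25–27 nt tags, reports QC, and
  reproduces the tag-truncation experiment (27 → 20 nt).
- **`radip.annotate`** — unique-mapping filter (MAPQ 37 on *both* tags),
  reduction of every tag to its single-nucleotide center, strand-aware
  unambiguous gene assignment for RNA tags, 25-kb bin assignment for DNA
  tags, ENCODE-style blacklist removal, distance classification
  (cis ≤ 100 kb, 100 kb–1 Mb, > 1 Mb, trans).
- **`radip.significance`** — per-RNA background as a zero-truncated negative
  binomial over the RNA's observed bins. For an observed count *x* in one bin,

  p = P(X ≥ x | X ≥ 1), X ~ NB(μ, r), Var X = μ + μ²/r,

  with (μ, r) fitted by bounded maximum likelihood robustified against
  contamination by true signal; Benjamini–Hochberg correction globally across
  all tested pairs, calls at q ≤ 0.1.
- **`radip.enrichment`** — TMM (trimmed mean of M-values) normalization, a
  common-dispersion NB exact test between replicated conditions (both checked
  against edgeR on frozen inputs), calls at adjusted P ≤ 0.1 and
  |log₂FC| ≥ 0.5, and per-condition **"Special"** RNA sets
  (enriched ∪ uniquely captured).
- **`radip.analytics`** — distance-class summaries, genome-wide bin–bin
  contact matrices, peak-centered meta-profiles (±3 kb), peak overlap
  fractions, sequencing-depth saturation curves, biotype × exon/intron
  breakdowns, and a Monte-Carlo chi-square test of sample similarity with
  p = (1 + #{sim ≥ obs}) / (B + 1).
- **`radip.pipeline` / `radip` CLI** — one seeded config chains
  `simulate → deconvolve → annotate → call → differential → summarize`,
  writing a manifest and a provenance hash; identical config + seed gives
  identical tables.

## Worked example

Calling interactions against the truncated-NB background
(`python examples/03_call_interactions.py`):

```
tested pairs: 4,500; significant at q<=0.1: 148
recall of planted 8-fold pairs: 0.67
false-discovery proportion: 0.047
gene_id   bin_id  count       mu           r            p            q
     g0  chr1:51     15 0.938978 1345.634873 2.171947e-13 1.510556e-10
     g0 chr1:143     14 0.938978 1345.634873 3.450474e-12 1.194395e-09
     g0 chr1:128     13 0.938978 1345.634873 5.123014e-11 1.356092e-08
```

30 RNAs × 150 bins of near-Poisson background counts (μ ≈ 1) carry 8-fold
planted signal in 5% of bins. The fitted background for RNA `g0` is
μ ≈ 0.94 with very large dispersion parameter r (effectively Poisson); a bin
observed 15 times has upper-tail probability ~2×10⁻¹³ and survives global BH
easily. Two thirds of the planted pairs are recovered at q ≤ 0.1 while fewer
than 5% of the calls are background.

Differential enrichment (`python examples/04_differential_enrichment.py`):

```
TMM factors: [1.092 1.072 1.125 1.113 0.892 0.889 0.914 0.941] (geometric mean 1; ...)
IP-enriched calls at adjP<=0.1, |log2FC|>=0.5: 15 (sensitivity 1.00, false calls 0)
IP Special set: 16 RNAs (15 enriched + 1 unique)
Input Special set: 2 RNAs; the two Special sets are disjoint by construction
```

The other scripts in `examples/` cover library simulation, read
deconvolution + annotation, and the orchestrated pipeline with its distance,
saturation and sample-similarity summaries.

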