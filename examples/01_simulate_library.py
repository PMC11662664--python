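"""Simulate a chimeric RNA-chromatin interaction library.

Builds a two-chromosome toy genome with a gene annotation, samples a
ground-truth interaction table with distance-decayed cis contacts and a trans
fraction, and emits the chimeric FASTQ (RNA tag + bridge adaptor + DNA tag)
with truth alignments.
"""

import tempfile

from radip import (GenomeBins, emit_reads, make_annotation, make_genome,
                   make_peaks, simulate_interactions)
from radip.deconvolve import DEFAULT_ADAPTOR

genome = make_genome(2, [600_000, 400_000], seed=1)
genes = make_annotation(genome, 50, seed=2)
bins = GenomeBins(genome.sizes, 25_000)
peaks = make_peaks(bins, 6, seed=3)

truth = simulate_interactions(genes, bins, mu0=2.0, r0=1.0,
                              decay_scale=100_000, trans_fraction=0.7,
                              peaks=peaks, enrichment_fold=4.0,
                              condition="ip", n_pairs=5_000, seed=4)

print(f"genome: {', '.join(f'{c} ({n:,} bp)' for c, n in genome.sizes.items())}")
print(f"genes placed: {len(genes)}; 25-kb bins: {bins.total_bins}")
print(f"truth support pairs: {len(truth.pairs):,}; reads: {truth.n_reads:,}")
trans = truth.pairs.loc[truth.pairs.is_trans, 'n_draws'].sum()
print(f"trans fraction of sampled events: {trans / truth.pairs.n_draws.sum():.2f}"
      " (the requested cis/trans mix)")
print(f"pairs at enriched peak bins: {len(truth.planted_enriched)}"
      " (their intensity is scaled by enrichment_fold in this IP library)")

with tempfile.TemporaryDirectory() as outdir:
    paths = emit_reads(genome, genes, truth, DEFAULT_ADAPTOR, outdir, seed=5)
    n_reads = sum(1 for _ in open(paths["fastq"])) // 4
    print(f"emitted {n_reads:,} chimeric reads "
          "(RNA tag + adaptor + DNA tag, each tag 25-27 nt)")
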