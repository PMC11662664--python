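"""Generator contracts: determinism, declared structure, generating laws."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from radip import (GenomeBins, emit_reads, make_annotation, make_genome,
                   make_peaks, simulate_interactions)
from radip.synthetic_data import GenerationError, revcomp

from conftest import ADAPTOR


class TestMakeGenome:
    def test_declared_lengths_and_alphabet(self):
        g = make_genome(2, [60_000, 40_000], seed=1)
        assert [len(s) for s in g.chroms.values()] == [60_000, 40_000]
        assert all(set(s) <= set("ACGT") for s in g.chroms.values())

    def test_deterministic_under_seed(self):
        a = make_genome(2, [10_000, 5_000], seed=1)
        b = make_genome(2, [10_000, 5_000], seed=1)
        c = make_genome(2, [10_000, 5_000], seed=2)
        assert a.chroms == b.chroms
        assert a.chroms != c.chroms

    @pytest.mark.parametrize("lengths", [[0], [-5], [10_000, 0]])
    def test_nonpositive_length_rejected(self, lengths):
        with pytest.raises(ValueError):
            make_genome(len(lengths), lengths, seed=1)

    def test_mismatched_count_rejected(self):
        with pytest.raises(ValueError):
            make_genome(3, [1_000], seed=1)


class TestMakeAnnotation:
    def test_biotype_sampling_target(self, genome):
        genes = make_annotation(
            genome, 100, {"protein_coding": 0.8, "lncRNA": 0.2}, seed=5,
            gene_length_range=(1_000, 3_000))
        n_pc = sum(g.biotype == "protein_coding" for g in genes)
        # binomial(100, 0.8): 3 sigma band around 80
        assert 68 <= n_pc <= 92

    def test_gene_structure(self, genes):
        for g in genes:
            assert g.exons[0][0] == g.start and g.exons[-1][1] == g.end
            if len(g.exons) == 1:
                assert g.exons[0] == (g.start, g.end)  # zero intronic bases
            for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
                assert e1 < s2  # intronic gap, genomic coordinate order
            assert g.strand in "+-"

    def test_no_same_strand_overlap(self, genes):
        by_key = {}
        for g in genes:
            by_key.setdefault((g.chrom, g.strand), []).append((g.start, g.end))
        for ivs in by_key.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_overcrowded_genome_raises(self):
        tiny = make_genome(1, [5_000], seed=1)
        with pytest.raises(GenerationError):
            make_annotation(tiny, 50, seed=1, gene_length_range=(2_000, 3_000))


class TestSimulateInteractions:
    def test_null_case_ip_input_exchangeable(self, genes, bins):
        """With enrichment_fold=1 the IP and Input count histograms agree
        (two-sample chi-square at alpha=0.01, a handful of seeds)."""
        rejections = 0
        n_seeds = 6
        for seed in range(n_seeds):
            a = simulate_interactions(genes, bins, n_pairs=4_000,
                                      condition="input", seed=seed)
            b = simulate_interactions(genes, bins, n_pairs=4_000,
                                      condition="ip", enrichment_fold=1.0,
                                      seed=seed + 100)
            edges = [1, 2, 3, 5, 9, np.inf]
            ha = np.histogram(a.pairs["count"], bins=edges)[0]
            hb = np.histogram(b.pairs["count"], bins=edges)[0]
            keep = (ha + hb) > 0
            _, p, _, _ = chi2_contingency(np.vstack([ha[keep], hb[keep]]))
            rejections += p < 0.01
        assert rejections <= 1

    def test_trans_fraction_matches_request(self, genes, bins):
        t = simulate_interactions(genes, bins, n_pairs=5_000,
                                  trans_fraction=0.3, seed=3)
        # fraction over sampled support draws (the cis/trans Bernoulli events)
        n_draws = t.pairs["n_draws"].sum()
        observed = t.pairs.loc[t.pairs["is_trans"], "n_draws"].sum() / n_draws
        se = np.sqrt(0.3 * 0.7 / n_draws)
        assert abs(observed - 0.3) < 4 * se

    def test_flat_mean_limit(self, genes, bins):
        """decay_scale -> inf with no trans: cis counts independent of
        distance (mean flat across near and far bins)."""
        t = simulate_interactions(genes, bins, n_pairs=20_000,
                                  decay_scale=np.inf, trans_fraction=0.0,
                                  mu0=2.0, r0=1.0, seed=4)
        assert (~t.pairs["is_trans"]).all()
        assert t.pairs["mu"].nunique() == 1

    def test_cis_mean_at_zero_distance(self, genes, bins):
        """Monte-Carlo check of the generating law: ZTNB counts at d~0 have
        mean mu/(1-P0) within 3 SE for mu0=2, r0=1."""
        t = simulate_interactions(genes, bins, n_pairs=30_000, mu0=2.0,
                                  r0=1.0, trans_fraction=0.0,
                                  decay_scale=1e12, seed=5)
        # per-draw counts are iid ZTNB(2,1) with mean mu/(1-P0) = 2/(2/3) = 3;
        # aggregated pairs sum over draws, so compare the per-draw average
        n_draws = t.pairs["n_draws"].sum()
        mean_per_draw = t.pairs["count"].sum() / n_draws
        # ZTNB(2,1) variance: E[X^2]=sum k^2 (1/3)(2/3)^{k-1} -> var = 15-9 = 6
        se = np.sqrt(6.0 / n_draws)
        assert abs(mean_per_draw - 3.0) < 3 * se

    def test_planted_enriched_only_in_ip(self, genes, bins, peaks):
        inp = simulate_interactions(genes, bins, peaks=peaks,
                                    enrichment_fold=4.0, condition="input",
                                    n_pairs=2_000, seed=6)
        ip = simulate_interactions(genes, bins, peaks=peaks,
                                   enrichment_fold=4.0, condition="ip",
                                   n_pairs=2_000, seed=6)
        assert not inp.planted_enriched
        assert ip.planted_enriched
        pair_keys = set(zip(ip.pairs["gene_id"], ip.pairs["bin_id"]))
        assert ip.planted_enriched <= pair_keys

    def test_empty_gene_set_rejected(self, bins):
        with pytest.raises(ValueError):
            simulate_interactions([], bins, n_pairs=10, seed=1)


class TestEmitReads:
    def test_exact_sequences_at_zero_error(self, genome, genes, truth, tmp_path):
        paths = emit_reads(genome, genes, truth, ADAPTOR, tmp_path,
                           error_rate=0.0, seed=7)
        tp = pd.read_csv(paths["pairs"], sep="\t")
        reads = {}
        with open(paths["fastq"]) as fh:
            lines = fh.read().splitlines()
        for i in range(0, len(lines), 4):
            reads[lines[i][1:]] = lines[i + 1]
        for row in tp.sample(50, random_state=0).itertuples():
            read = reads[row.read_id]
            rna = genome.chroms[row.rna_chrom][row.rna_start:row.rna_end]
            if row.rna_strand == "-":
                rna = revcomp(rna)
            dna = genome.chroms[row.dna_chrom][row.dna_start:row.dna_end]
            assert read == rna + ADAPTOR + dna

    def test_conservation_reads_equal_truth_pairs(self, genome, genes, truth,
                                                  tmp_path):
        paths = emit_reads(genome, genes, truth, ADAPTOR, tmp_path, seed=8)
        n_reads = sum(1 for line in open(paths["fastq"])) // 4
        assert n_reads == truth.n_reads == truth.params["n_pairs"]

    def test_fixed_tag_length(self, genome, genes, bins, tmp_path):
        t = simulate_interactions(genes, bins, n_pairs=200, seed=9)
        paths = emit_reads(genome, genes, t, ADAPTOR, tmp_path,
                           tag_len_range=(27, 27), seed=9)
        tp = pd.read_csv(paths["pairs"], sep="\t")
        assert ((tp["rna_end"] - tp["rna_start"]) == 27).all()
        assert ((tp["dna_end"] - tp["dna_start"]) == 27).all()

    def test_deterministic_fastq_bytes(self, genome, genes, truth, tmp_path):
        p1 = emit_reads(genome, genes, truth, ADAPTOR, tmp_path / "a", seed=10)
        p2 = emit_reads(genome, genes, truth, ADAPTOR, tmp_path / "b", seed=10)
        assert open(p1["fastq"], "rb").read() == open(p2["fastq"], "rb").read()

    def test_bad_adaptor_rejected(self, genome, genes, truth, tmp_path):
        from radip.synthetic_data import ConfigError
        with pytest.raises(ConfigError):
            emit_reads(genome, genes, truth, "NNNN", tmp_path, seed=1)


def test_make_peaks_within_bins(bins):
    peaks = make_peaks(bins, 6, seed=2)
    assert len(peaks) == 6
    for chrom, start, end in peaks.itertuples(index=False):
        assert 0 <= start < end <= bins.chrom_sizes[chrom]
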