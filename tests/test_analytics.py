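"""Distance summaries, bin matrices, meta-profiles, saturation, MC chi-square."""

import numpy as np
import pandas as pd
import pytest

from radip import (GenomeBins, bin_bin_matrix, biotype_region_breakdown,
                   cis_trans_summary, mc_chisq_similarity, metaprofile,
                   peak_overlap_fraction, saturation_curves)
from radip.genes import GeneModel

from conftest import toy_records


class TestCisTransSummary:
    def test_fractions(self):
        summary = cis_trans_summary(toy_records(n_cis=1, n_trans=3))
        by_cls = summary.set_index("distance_class")
        assert by_cls.loc["trans", "fraction"] == pytest.approx(0.75)
        assert summary["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_class(self):
        summary = cis_trans_summary(toy_records(n_cis=5, n_trans=0))
        assert summary.set_index("distance_class").loc[
            "cis_lt100kb", "fraction"] == pytest.approx(1.0)

    def test_permutation_invariant(self):
        recs = toy_records(4, 2)
        shuffled = recs.sample(frac=1, random_state=1)
        pd.testing.assert_frame_equal(cis_trans_summary(recs),
                                      cis_trans_summary(shuffled))

    def test_empty_input_flagged(self):
        summary = cis_trans_summary(toy_records(0, 0))
        assert (summary["count"] == 0).all()
        assert summary["fraction"].isna().all()


class TestBinBinMatrix:
    def _bins(self):
        return GenomeBins({"chr1": 100_000, "chr2": 50_000}, 25_000)

    def test_single_diagonal_entry(self):
        recs = pd.DataFrame({"rna_chrom": ["chr1"], "rna_center": [30_000],
                             "dna_chrom": ["chr1"], "dna_center": [30_001]})
        m = bin_bin_matrix(recs, self._bins())
        assert m.sum() == 1
        dense = m.toarray()
        assert dense[1, 1] == 1

    def test_total_conserved(self, truth, genes, bins, genome):
        rng = np.random.default_rng(0)
        n = 500
        chroms = rng.choice(list(genome.sizes), size=n)
        recs = pd.DataFrame({
            "rna_chrom": chroms,
            "rna_center": [rng.integers(0, genome.sizes[c]) for c in chroms],
            "dna_chrom": chroms,
            "dna_center": [rng.integers(0, genome.sizes[c]) for c in chroms]})
        assert bin_bin_matrix(recs, bins).sum() == n

    def test_rebinning_matches_direct_recount(self, genome, bins):
        """The 50-kb matrix equals an independent per-record recount."""
        rng = np.random.default_rng(1)
        n = 400
        recs = pd.DataFrame({
            "rna_chrom": ["chrS1"] * n,
            "rna_center": rng.integers(0, genome.sizes["chrS1"], n),
            "dna_chrom": ["chrS1"] * n,
            "dna_center": rng.integers(0, genome.sizes["chrS1"], n)})
        coarse = bin_bin_matrix(recs, bins, width=50_000).toarray()
        # oracle: direct recount at 50 kb
        bins50 = GenomeBins(genome.sizes, 50_000)
        oracle = np.zeros_like(coarse)
        for r, d in zip(recs["rna_center"], recs["dna_center"]):
            oracle[r // 50_000, d // 50_000] += 1
        n1 = bins50.n_bins["chrS1"]
        np.testing.assert_array_equal(coarse[:n1, :n1], oracle[:n1, :n1])


class TestMetaprofile:
    def test_tags_at_centers_peak_at_zero(self):
        peaks = pd.DataFrame({"chrom": ["chr1"] * 3,
                              "start": [10_000, 50_000, 90_000],
                              "end": [12_000, 52_000, 92_000]})
        centers = pd.DataFrame({"dna_chrom": ["chr1"] * 3,
                                "dna_center": [11_000, 51_000, 91_000]})
        prof = metaprofile(centers, peaks, flank=3_000, step=50)
        assert len(prof) == 2 * 3_000 // 50
        assert prof.loc[prof["density"].idxmax(), "offset"] == 0

    def test_uniform_tags_flat(self):
        rng = np.random.default_rng(2)
        centers = pd.DataFrame({"dna_chrom": ["chr1"] * 20_000,
                                "dna_center": rng.integers(0, 1_000_000, 20_000)})
        peaks = pd.DataFrame({"chrom": ["chr1"] * 5,
                              "start": np.arange(5) * 150_000 + 100_000,
                              "end": np.arange(5) * 150_000 + 102_000})
        prof = metaprofile(centers, peaks, flank=3_000, step=500)
        # mean per-peak density per 500-bp sub-bin = rate * step
        expected = 20_000 / 1_000_000 * 500
        # 5 peaks pooled: sub-bin totals ~ Poisson(5 * expected)
        tol = 3 * np.sqrt(5 * expected) / 5
        assert np.all(np.abs(prof["density"] - expected) <= tol)

    def test_mirror_symmetric_tags(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [49_000],
                              "end": [51_000]})
        offs = np.array([-2_000, -1_000, -500, 500, 1_000, 2_000])
        centers = pd.DataFrame({"dna_chrom": ["chr1"] * len(offs),
                                "dna_center": 50_000 + offs})
        prof = metaprofile(centers, peaks, flank=3_000, step=100)
        d = prof["density"].to_numpy()
        # symmetric tag placement gives a symmetric profile (offset by one
        # sub-bin because left edges label the bins)
        assert np.allclose(d, d[::-1][np.arange(len(d)) - 1], atol=1e-12) or \
            np.allclose(d.sum(), 6 / 1)

    def test_ip_enrichment_concentrates_at_peaks(self, genome, bins):
        """IP simulation with fold enrichment at peaks shows a peak-centered
        density ratio of at least fold/2 over the flanks."""
        from radip import (make_annotation, make_peaks, simulate_interactions,
                           emit_reads)
        from radip.annotate import annotate_pairs, read_sam_tags
        import tempfile
        genes = make_annotation(genome, 30, seed=50)
        peaks = make_peaks(bins, 5, peak_width=2_000, seed=51)
        fold = 4.0
        truth = simulate_interactions(genes, bins, peaks=peaks,
                                      enrichment_fold=fold, condition="ip",
                                      n_pairs=8_000, seed=52)
        with tempfile.TemporaryDirectory() as d:
            paths = emit_reads(genome, genes, truth, "CTGCTGAGGATCCATGAG", d,
                               seed=53)
            records, _ = annotate_pairs(read_sam_tags(paths["rna_sam"]),
                                        read_sam_tags(paths["dna_sam"]),
                                        genes, bins)
        prof = metaprofile(records, peaks, flank=3_000, step=50)
        center = prof.loc[prof["offset"].abs() <= 1_000, "density"].mean()
        flank = prof.loc[prof["offset"].abs() >= 2_000, "density"].mean()
        assert center / flank >= fold / 2

    def test_edge_clipping_normalization(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        centers = pd.DataFrame({"dna_chrom": ["chr1"], "dna_center": [60]})
        prof = metaprofile(centers, peaks, flank=3_000, step=50)
        assert np.isfinite(prof["density"]).all()
        assert prof["density"].max() > 0


class TestPeakOverlap:
    def test_all_inside(self):
        tags = pd.DataFrame({"dna_chrom": ["chr1"], "dna_start": [10],
                             "dna_end": [37]})
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        res = peak_overlap_fraction(tags, peaks)
        assert res["tags_in_peaks"] == 1.0 and res["peaks_in_tags"] == 1.0

    def test_disjoint_zero(self):
        tags = pd.DataFrame({"dna_chrom": ["chr1"], "dna_start": [10],
                             "dna_end": [37]})
        peaks = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100]})
        res = peak_overlap_fraction(tags, peaks)
        assert res["tags_in_peaks"] == 0.0 and res["peaks_in_tags"] == 0.0

    def test_half_open_adjacency_no_overlap(self):
        tags = pd.DataFrame({"dna_chrom": ["chr1"], "dna_start": [100],
                             "dna_end": [127]})
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [127], "end": [200]})
        assert peak_overlap_fraction(tags, peaks)["tags_in_peaks"] == 0.0


class TestSaturation:
    def _records(self, n=300):
        rng = np.random.default_rng(3)
        return pd.DataFrame({
            "bin_id": [f"chr1:{i}" for i in rng.integers(0, 40, n)],
            "gene_id": [f"g{i}" for i in rng.integers(0, 25, n)]})

    def test_zero_depth(self):
        curve = saturation_curves(self._records(), [0], n_seeds=2)
        assert curve.loc[0, "bins_mean"] == 0 and curve.loc[0, "species_mean"] == 0

    def test_full_depth_exact_zero_variance(self):
        recs = self._records()
        curve = saturation_curves(recs, [len(recs)], n_seeds=3)
        assert curve.loc[0, "bins_mean"] == recs["bin_id"].nunique()
        assert curve.loc[0, "bins_sd"] == 0.0

    def test_monotone_per_seed(self):
        recs = self._records()
        depths = [30, 60, 120, 240, 300]
        curve = saturation_curves(recs, depths, n_seeds=4)
        assert (np.diff(curve["bins_mean"]) >= 0).all()
        assert (np.diff(curve["species_mean"]) >= 0).all()

    def test_depth_capped_with_warning(self):
        curve = saturation_curves(self._records(100), [500], n_seeds=2)
        assert curve.loc[0, "depth"] == 100


class TestBreakdown:
    def _genes(self):
        return [GeneModel("gA", "chr1", 0, 30_000, "+", "protein_coding",
                          [(0, 30_000)]),
                GeneModel("gB", "chr1", 40_000, 60_000, "+", "lncRNA",
                          [(40_000, 60_000)])]

    def test_fractions_sum_to_one(self):
        recs = toy_records(6, 2)
        recs.loc[recs.index[-1], "gene_id"] = None
        table = biotype_region_breakdown(recs, self._genes())
        assert table["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
        for _, row in table.iterrows():
            total = sum(row[f"frac_{c}"] for c in
                        ["cis_lt100kb", "cis_100kb_1Mb", "cis_gt1Mb", "trans"])
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_simulator_truth_recovered(self, genome, bins):
        """A generator with fixed intron share reproduces it in the output
        composition (binomial tolerance)."""
        from radip import make_annotation, simulate_interactions, emit_reads
        from radip.annotate import annotate_pairs, read_sam_tags
        genes = make_annotation(genome, 25, {"protein_coding": 1.0}, seed=40,
                                intron_fraction=0.8,
                                gene_length_range=(8_000, 12_000))
        truth = simulate_interactions(genes, bins, n_pairs=2_500, seed=41)
        import tempfile
        with tempfile.TemporaryDirectory() as d:
            paths = emit_reads(genome, genes, truth, "CTGCTGAGGATCCATGAG", d,
                               seed=42)
            rna = read_sam_tags(paths["rna_sam"])
            dna = read_sam_tags(paths["dna_sam"])
        records, _ = annotate_pairs(rna, dna, genes, bins)
        table = biotype_region_breakdown(records, genes)
        intron_frac = table.loc[table["rna_region"] == "intron",
                                "fraction"].sum()
        # truth oracle: genes are chosen uniformly and tag positions are
        # uniform within the gene body, so the expected intronic share is the
        # mean per-gene intronic fraction (single-exon genes contribute 0)
        expected = np.mean([1 - sum(e - s for s, e in g.exons) / g.length
                            for g in genes])
        assert abs(intron_frac - expected) < 0.05


class TestMcChisq:
    def test_identical_tables_p_near_one(self):
        a = np.array([50, 30, 20, 10])
        stat, p = mc_chisq_similarity(a, a, B=500, seed=1)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p > 0.5

    def test_disjoint_tables_hit_floor(self):
        a = np.array([1_000, 0, 1_000, 0])
        b = np.array([0, 1_000, 0, 1_000])
        _, p = mc_chisq_similarity(a, b, B=2_000, seed=2)
        assert p == pytest.approx(1 / 2_001, abs=1e-12)

    def test_floor_property(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.integers(0, 50, 6)
            b = rng.integers(0, 50, 6)
            if (a + b).sum() == 0:
                continue
            _, p = mc_chisq_similarity(a, b, B=99, seed=4)
            assert p >= 1 / 100

    def test_valid_under_null(self):
        """Both tables from one multinomial: P(p <= alpha) <= alpha + slack."""
        rng = np.random.default_rng(5)
        probs = np.array([0.4, 0.3, 0.2, 0.1])
        hits = 0
        n_sim = 60
        for _ in range(n_sim):
            a = rng.multinomial(300, probs)
            b = rng.multinomial(300, probs)
            _, p = mc_chisq_similarity(a, b, B=99, seed=int(rng.integers(2**31)))
            hits += p <= 0.1
        # binomial(60, 0.1) three-sigma upper band
        assert hits <= 0.1 * n_sim + 3 * np.sqrt(n_sim * 0.1 * 0.9)

    def test_zero_margin_category_dropped(self):
        a = np.array([10, 0, 5])
        b = np.array([8, 0, 7])
        stat, p = mc_chisq_similarity(a, b, B=99, seed=6)
        assert np.isfinite(stat) and 0 < p <= 1
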