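import numpy as np
import pandas as pd
import pytest

from radip import (GenomeBins, make_annotation, make_genome, make_peaks,
                   simulate_interactions)

ADAPTOR = "CTGCTGAGGATCCATGAG"


@pytest.fixture(scope="session")
def genome():
    return make_genome(2, [400_000, 250_000], seed=11)


@pytest.fixture(scope="session")
def genes(genome):
    return make_annotation(genome, 40, seed=12)


@pytest.fixture(scope="session")
def bins(genome):
    return GenomeBins(genome.sizes, 25_000)


@pytest.fixture(scope="session")
def peaks(bins):
    return make_peaks(bins, 5, seed=13)


@pytest.fixture(scope="session")
def truth(genes, bins):
    return simulate_interactions(genes, bins, n_pairs=3_000, seed=14)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_records(n_cis=3, n_trans=1):
    """Small hand-built annotated record table for analytics tests."""
    rows = []
    for i in range(n_cis):
        rows.append((f"r{i}", "chr1", 10_000 + i, "+", "gA", "exon",
                     "chr1", 40_000, 40_027, 40_013, "chr1:1", 30_013 + i,
                     "cis_lt100kb"))
    for i in range(n_trans):
        rows.append((f"t{i}", "chr1", 10_000, "+", "gA", "intron",
                     "chr2", 1_000, 1_027, 1_013, "chr2:0", np.nan, "trans"))
    return pd.DataFrame(rows, columns=[
        "read_id", "rna_chrom", "rna_center", "rna_strand", "gene_id",
        "rna_region", "dna_chrom", "dna_start", "dna_end", "dna_center",
        "bin_id", "distance", "distance_class"])
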