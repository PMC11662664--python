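"""Summary analytics over annotated interaction tables.

Distance-class composition, genome-wide bin-bin contact matrices,
peak-centered meta-profiles of DNA tag density, peak overlap fractions,
sequencing-depth saturation curves, biotype x region breakdowns and a
Monte-Carlo chi-square test of sample similarity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse, stats
from intervaltree import IntervalTree

from .annotate import DISTANCE_CLASSES, classify_distance  # noqa: F401 (re-export)
from .genes import GeneModel, GenomeBins

logger = logging.getLogger(__name__)


def cis_trans_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of interactions per distance class."""
    counts = records["distance_class"].value_counts()
    rows = []
    total = int(counts.sum())
    for cls in DISTANCE_CLASSES:
        n = int(counts.get(cls, 0))
        rows.append((cls, n, n / total if total else np.nan))
    if total == 0:
        logger.warning("cis_trans_summary on empty input; fractions undefined")
    return pd.DataFrame(rows, columns=["distance_class", "count", "fraction"])


def _global_bin_offsets(bins: GenomeBins) -> dict[str, int]:
    offsets = {}
    cum = 0
    for chrom, n in bins.n_bins.items():
        offsets[chrom] = cum
        cum += n
    return offsets


def bin_bin_matrix(records: pd.DataFrame, bins: GenomeBins,
                   width: int | None = None) -> sparse.coo_matrix:
    """Sparse (RNA bin x DNA bin) contact matrix over a global bin index.

    Chromosomes are concatenated in the order of the bins object. ``width``
    optionally re-bins at a different (coarser or finer) resolution. The
    matrix total always equals the number of records.
    """
    if width is not None and width != bins.width:
        bins = GenomeBins(bins.chrom_sizes, width)
    offsets = _global_bin_offsets(bins)
    n = bins.total_bins
    rows = records["rna_chrom"].map(offsets).to_numpy() + \
        records["rna_center"].to_numpy() // bins.width
    cols = records["dna_chrom"].map(offsets).to_numpy() + \
        records["dna_center"].to_numpy() // bins.width
    data = np.ones(len(records), dtype=np.int64)
    return sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocoo()


def metaprofile(dna_centers: pd.DataFrame, peaks: pd.DataFrame,
                flank: int = 3_000, step: int = 50) -> pd.DataFrame:
    """Average DNA-tag density around peak centers.

    For each peak, tag centers are histogrammed by signed offset in
    ``[-flank, +flank)`` at ``step``-bp resolution, then averaged over peaks
    (normalization by peak count; windows clipped at chromosome edges use
    their covered width). Returns offsets (sub-bin left edges) and densities.
    """
    if len(peaks) == 0:
        raise ValueError("no peaks supplied")
    n_sub = 2 * flank // step
    edges = np.arange(-flank, flank + step, step)
    acc = np.zeros(n_sub)
    coverage = np.zeros(n_sub)
    by_chrom = {c: g["dna_center"].to_numpy()
                for c, g in dna_centers.groupby("dna_chrom")}
    for chrom, start, end in peaks[["chrom", "start", "end"]].itertuples(index=False):
        center = (start + end) // 2
        centers = by_chrom.get(chrom)
        if centers is not None:
            offs = centers - center
            sel = (offs >= -flank) & (offs < flank)
            hist, _ = np.histogram(offs[sel], bins=edges)
            acc += hist
        # edge clipping: sub-bins fully below 0 contribute no coverable width
        sub_left = center + edges[:-1]
        sub_right = center + edges[1:]
        covered = np.clip(sub_right, 0, None) - np.clip(sub_left, 0, None)
        coverage += np.clip(covered, 0, step) / step
    dens = np.divide(acc, coverage, out=np.zeros(n_sub), where=coverage > 0)
    return pd.DataFrame({"offset": edges[:-1], "density": dens,
                         "n_peaks": len(peaks)})


def peak_overlap_fraction(dna_tags: pd.DataFrame,
                          peaks: pd.DataFrame) -> dict[str, float]:
    """Fraction of DNA tags overlapping peaks and the peak-centric converse.

    Overlap requires >= 1 shared bp under half-open semantics (adjacent
    intervals do not overlap).
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in peaks[["chrom", "start", "end"]].itertuples(index=False):
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    if len(dna_tags):
        hits = sum(bool(trees.get(c) and trees[c].overlap(s, e))
                   for c, s, e in dna_tags[["dna_chrom", "dna_start", "dna_end"]]
                   .itertuples(index=False))
        tag_frac = hits / len(dna_tags)
    else:
        tag_frac = float("nan")
    tag_trees: dict[str, IntervalTree] = {}
    for c, s, e in dna_tags[["dna_chrom", "dna_start", "dna_end"]].itertuples(index=False):
        if e > s:
            tag_trees.setdefault(c, IntervalTree()).addi(s, e)
    if len(peaks):
        phits = sum(bool(tag_trees.get(c) and tag_trees[c].overlap(s, e))
                    for c, s, e in peaks[["chrom", "start", "end"]].itertuples(index=False))
        peak_frac = phits / len(peaks)
    else:
        peak_frac = float("nan")
    return {"tags_in_peaks": tag_frac, "peaks_in_tags": peak_frac}


def saturation_curves(records: pd.DataFrame, depths, n_seeds: int = 5,
                      seed: int = 0) -> pd.DataFrame:
    """Distinct DNA bins and RNA species recovered at subsampled depths.

    For each depth and seed, records are subsampled without replacement and
    the numbers of distinct DNA bins and distinct RNA gene ids are counted;
    the mean and SD across seeds are reported. Depth values <= 1 are read as
    fractions of the table (1.0 = full depth); larger values as absolute
    counts, capped at the table size with a warning.
    """
    n = len(records)
    depths = [int(round(d * n)) if d <= 1 else int(d) for d in depths]
    capped = [min(d, n) for d in depths]
    if capped != depths:
        logger.warning("saturation depths capped at table size %d", n)
    bins_arr = records["bin_id"].to_numpy()
    genes_arr = records["gene_id"].to_numpy()
    rows = []
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_seeds)
    for depth in capped:
        nb, ng = [], []
        for s in seeds:
            rng = np.random.default_rng(s)
            idx = rng.choice(n, size=depth, replace=False) if depth < n \
                else np.arange(n)
            nb.append(len(pd.unique(bins_arr[idx])))
            sel = genes_arr[idx]
            ng.append(len(pd.unique(sel[pd.notna(sel)])))
        rows.append((depth, float(np.mean(nb)), float(np.std(nb)),
                     float(np.mean(ng)), float(np.std(ng))))
    return pd.DataFrame(rows, columns=["depth", "bins_mean", "bins_sd",
                                       "species_mean", "species_sd"])


def biotype_region_breakdown(records: pd.DataFrame,
                             genes: list[GeneModel]) -> pd.DataFrame:
    """Composition of gene-assigned records by biotype x RNA region.

    Also reports the distance-class composition within each stratum. Overall
    fractions sum to 1 over strata; distance fractions sum to 1 per stratum.
    """
    bmap = {g.gene_id: g.biotype for g in genes}
    assigned = records.dropna(subset=["gene_id"]).copy()
    assigned["biotype"] = assigned["gene_id"].map(bmap)
    total = len(assigned)
    rows = []
    for (bt, region), grp in assigned.groupby(["biotype", "rna_region"]):
        row = {"biotype": bt, "rna_region": region, "count": len(grp),
               "fraction": len(grp) / total}
        cls_counts = grp["distance_class"].value_counts()
        for cls in DISTANCE_CLASSES:
            row[f"frac_{cls}"] = float(cls_counts.get(cls, 0)) / len(grp)
        rows.append(row)
    return pd.DataFrame(rows)


def mc_chisq_similarity(table_a, table_b, B: int = 2_000,
                        seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo chi-square test that two count profiles differ.

    ``table_a`` and ``table_b`` are per-category interaction counts over the
    same category universe (e.g. per-gene or per-bin totals of two samples).
    The chi-square statistic of the 2 x K contingency table is compared with
    ``B`` random tables drawn under fixed margins; the p-value is
    ``(1 + #{sim >= obs}) / (B + 1)`` and can never drop below 1/(B+1).
    Zero-margin categories are dropped with a warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    a = np.asarray(table_a, dtype=np.int64)
    b = np.asarray(table_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("category universes differ")
    nonzero = (a + b) > 0
    if not nonzero.all():
        logger.warning("dropping %d zero-margin categories", int((~nonzero).sum()))
        a, b = a[nonzero], b[nonzero]
    obs = np.vstack([a, b])

    def chisq(t: np.ndarray) -> float:
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = (t - expected) ** 2 / expected
        return float(np.nansum(terms))

    stat = chisq(obs)
    rng = np.random.default_rng(seed)
    dist = stats.random_table(obs.sum(axis=1), obs.sum(axis=0))
    sims = dist.rvs(B, random_state=rng)
    sim_stats = np.array([chisq(s) for s in sims])
    p = (1 + int((sim_stats >= stat - 1e-12).sum())) / (B + 1)
    return stat, p
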