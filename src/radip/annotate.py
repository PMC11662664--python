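"""Turn aligned RNA/DNA tag pairs into annotated interaction records.

Stages, in order: unique-mapping filter (both tags of a read must survive),
reduction of each tag to its single-nucleotide center, strand-aware gene
assignment for RNA tags, fixed-width bin assignment for DNA tags, blacklist
removal on DNA tag intervals, and aggregation into a gene x bin count table.

The center-point rule exists to keep each fragment from touching multiple
genes or bins, so gene containment is tested at the center only, while
blacklist removal uses the full DNA tag interval (an overlap criterion).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .genes import GeneIndex, GeneModel, GenomeBins

logger = logging.getLogger(__name__)

UNIQUE_MAPQ = 37  # aligner convention: uniquely mapped

DISTANCE_CLASSES = ["cis_lt100kb", "cis_100kb_1Mb", "cis_gt1Mb", "trans"]


@dataclass
class AlignedTag:
    """A single aligned tag with 0-based half-open coordinates."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval for {self.read_id}")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")

    @property
    def center(self) -> int:
        return center_coord(self.start, self.end)


def center_coord(start: int, end: int) -> int:
    """Single-nucleotide center of a half-open interval (floor midpoint)."""
    if start >= end:
        raise ValueError(f"invalid interval [{start},{end})")
    return (start + end) // 2


def read_sam_tags(path: str | os.PathLike) -> list[AlignedTag]:
    """Load primary alignments from a SAM/BAM file as AlignedTag records."""
    tags = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            tags.append(AlignedTag(aln.query_name, aln.reference_name,
                                   aln.reference_start, aln.reference_end,
                                   "-" if aln.is_reverse else "+",
                                   aln.mapping_quality))
    return tags


def filter_unique(rna_tags: list[AlignedTag], dna_tags: list[AlignedTag],
                  required_mapq: int = UNIQUE_MAPQ,
                  mapq_mode: str = "exact") -> tuple[list[AlignedTag], list[AlignedTag]]:
    """Keep reads whose RNA *and* DNA tags are uniquely mapped.

    ``mapq_mode`` selects equality against the aligner's unique-mapping value
    (default) or a minimum threshold for aligners with a different convention.
    """
    if mapq_mode not in ("exact", "min"):
        raise ValueError("mapq_mode must be 'exact' or 'min'")

    def ok(t: AlignedTag) -> bool:
        return t.mapq == required_mapq if mapq_mode == "exact" else t.mapq >= required_mapq

    rna_ok = {t.read_id for t in rna_tags if ok(t)}
    dna_ok = {t.read_id for t in dna_tags if ok(t)}
    both = rna_ok & dna_ok
    kept_rna = [t for t in rna_tags if t.read_id in both]
    kept_dna = [t for t in dna_tags if t.read_id in both]
    logger.info("unique-mapping filter: %d/%d reads kept",
                len(both), len({t.read_id for t in rna_tags} | {t.read_id for t in dna_tags}))
    return kept_rna, kept_dna


def assign_dna_to_bin(center: int, chrom: str, bins: GenomeBins) -> str:
    return bins.bin_id(chrom, center)


def assign_rna_to_gene(center: int, chrom: str, strand: str,
                       index: GeneIndex) -> tuple[str | None, str | None, str]:
    """Assign an RNA tag center to a gene, honoring strand and unambiguity.

    Returns ``(gene_id, region, status)`` where status is one of
    ``assigned``, ``unassigned`` (no candidate) or ``ambiguous`` (several
    same-strand genes contain the center). Region is ``exon`` if the center
    falls inside any exon of the assigned gene, else ``intron``.
    """
    candidates = index.query(chrom, center, strand)
    if not candidates:
        return None, None, "unassigned"
    if len(candidates) > 1:
        return None, None, "ambiguous"
    gene = candidates[0]
    region = "exon" if gene.contains_exonic(center) else "intron"
    return gene.gene_id, region, "assigned"


def classify_distance(rna_chrom: str, rna_center: int,
                      dna_chrom: str, dna_center: int) -> tuple[int | None, str]:
    """Distance class of one interaction (trans, or cis by separation)."""
    if rna_chrom != dna_chrom:
        return None, "trans"
    d = abs(rna_center - dna_center)
    if d <= 100_000:
        return d, "cis_lt100kb"
    if d <= 1_000_000:
        return d, "cis_100kb_1Mb"
    return d, "cis_gt1Mb"


def build_blacklist_index(blacklist: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in blacklist[["chrom", "start", "end"]].itertuples(index=False):
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def blacklist_filter(records: pd.DataFrame,
                     blacklist: pd.DataFrame | None) -> pd.DataFrame:
    """Drop records whose DNA tag interval overlaps a blacklisted region.

    Overlap means >= 1 bp of shared sequence under half-open semantics, based
    on the genomic coordinates of the DNA tags.
    """
    if blacklist is None or len(blacklist) == 0 or len(records) == 0:
        return records
    trees = build_blacklist_index(blacklist)
    keep = []
    for chrom, start, end in records[["dna_chrom", "dna_start", "dna_end"]].itertuples(index=False):
        tree = trees.get(chrom)
        keep.append(tree is None or not tree.overlap(start, end))
    dropped = len(keep) - sum(keep)
    if dropped:
        logger.info("blacklist filter removed %d records", dropped)
    return records.loc[keep].reset_index(drop=True)


def annotate_pairs(rna_tags: list[AlignedTag], dna_tags: list[AlignedTag],
                   genes: list[GeneModel], bins: GenomeBins,
                   blacklist: pd.DataFrame | None = None,
                   required_mapq: int = UNIQUE_MAPQ,
                   mapq_mode: str = "exact") -> tuple[pd.DataFrame, dict]:
    """Full annotation chain from aligned tags to an interaction table.

    Returns the annotated pairs table (one row per surviving read, including
    gene-unassigned records) and a per-stage accounting dict such that every
    input read is either kept or attributed to exactly one drop reason.
    """
    stats = {"input_reads": len({t.read_id for t in rna_tags} |
                                {t.read_id for t in dna_tags})}
    kept_rna, kept_dna = filter_unique(rna_tags, dna_tags, required_mapq, mapq_mode)
    stats["dropped_mapq"] = stats["input_reads"] - len(kept_rna)

    index = GeneIndex(genes)
    dna_by_id = {t.read_id: t for t in kept_dna}
    rows = []
    n_ambiguous = 0
    for rt in kept_rna:
        dt = dna_by_id[rt.read_id]
        rna_center = rt.center
        dna_center = dt.center
        gene_id, region, status = assign_rna_to_gene(rna_center, rt.chrom,
                                                     rt.strand, index)
        if status == "ambiguous":
            n_ambiguous += 1
            continue
        bin_id = bins.bin_id(dt.chrom, dna_center)
        distance, dclass = classify_distance(rt.chrom, rna_center, dt.chrom,
                                             dna_center)
        rows.append((rt.read_id, rt.chrom, rna_center, rt.strand,
                     gene_id, region, dt.chrom, dt.start, dt.end, dna_center,
                     bin_id, distance, dclass))
    records = pd.DataFrame(rows, columns=[
        "read_id", "rna_chrom", "rna_center", "rna_strand", "gene_id",
        "rna_region", "dna_chrom", "dna_start", "dna_end", "dna_center",
        "bin_id", "distance", "distance_class"])
    stats["dropped_ambiguous_gene"] = n_ambiguous
    n_before = len(records)
    records = blacklist_filter(records, blacklist)
    stats["dropped_blacklist"] = n_before - len(records)
    stats["kept"] = len(records)
    assert stats["kept"] + stats["dropped_mapq"] + stats["dropped_ambiguous_gene"] \
        + stats["dropped_blacklist"] == stats["input_reads"]
    return records, stats


def attach_biotypes(records: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    bmap = {g.gene_id: g.biotype for g in genes}
    out = records.copy()
    out["gene_biotype"] = out["gene_id"].map(bmap)
    return out


def build_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate annotated records into a long-format gene x bin count table.

    Records with no assigned gene stay in the coordinate-level pairs table
    (they are needed for genome-wide bin-bin views) but are excluded here, so
    the matrix total equals the number of gene-assigned records.
    """
    assigned = records.dropna(subset=["gene_id"])
    counts = (assigned.groupby(["gene_id", "bin_id"], as_index=False)
              .size().rename(columns={"size": "count"}))
    return counts
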