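"""Gene models, fixed-width genome bins and GTF input/output.

Internal coordinates are 0-based half-open throughout the package. GTF is
1-based inclusive and is converted on read and write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from intervaltree import IntervalTree


@dataclass
class GeneModel:
    """One annotated gene: interval, strand, biotype and merged exons."""

    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    biotype: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval for {self.gene_id}")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon outside gene body for {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_exonic(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)


class GeneIndex:
    """Strand-aware interval lookup of gene bodies by a single position."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault((g.chrom, g.strand), IntervalTree())
            tree.addi(g.start, g.end, g.gene_id)

    def query(self, chrom: str, pos: int, strand: str) -> list[GeneModel]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in tree.at(pos)]


class GenomeBins:
    """Fixed-width tiling of each chromosome from position 0.

    The final bin of a chromosome may be short; bins are non-overlapping and
    exhaustive. A bin id is the string ``"<chrom>:<index>"``.
    """

    def __init__(self, chrom_sizes: dict[str, int], width: int = 25_000):
        if width <= 0:
            raise ValueError("bin width must be positive")
        self.width = width
        self.chrom_sizes = dict(chrom_sizes)
        self.n_bins = {c: -(-length // width) for c, length in chrom_sizes.items()}

    def bin_index(self, chrom: str, pos: int) -> int:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.chrom_sizes[chrom]):
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.width

    def bin_id(self, chrom: str, pos: int) -> str:
        return f"{chrom}:{self.bin_index(chrom, pos)}"

    def bin_interval(self, chrom: str, index: int) -> tuple[int, int]:
        start = index * self.width
        return start, min(start + self.width, self.chrom_sizes[chrom])

    def bin_center(self, chrom: str, index: int) -> int:
        s, e = self.bin_interval(chrom, index)
        return (s + e) // 2

    def iter_bins(self):
        for chrom, n in self.n_bins.items():
            for i in range(n):
                yield chrom, i

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins.values())


def write_gtf(genes: list[GeneModel], path: str | os.PathLike,
              source: str = "radip") -> None:
    """Serialize gene and exon features with gene_id/gene_type attributes."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            fh.write(f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene/exon features from a GTF file into GeneModel records.

    Coordinates are converted from GTF 1-based inclusive to 0-based half-open.
    Exons are attached to their gene via the ``gene_id`` attribute; genes
    lacking an explicit ``gene`` feature are inferred from their exon span.
    """
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[str, str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            attrs = _parse_attributes(attr)
            gid = attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            s, e = int(start) - 1, int(end)
            if feature == "gene":
                genes[gid] = GeneModel(gid, chrom, s, e, strand,
                                       attrs.get("gene_type", "other"))
            elif feature == "exon":
                exons.setdefault(gid, []).append((chrom, strand, s, e))
    for gid, ex in exons.items():
        merged = _merge_intervals([(s, e) for _, _, s, e in ex])
        if gid in genes:
            genes[gid].exons = merged
        else:
            chrom, strand = ex[0][0], ex[0][1]
            genes[gid] = GeneModel(gid, chrom, merged[0][0], merged[-1][1],
                                   strand, "other", merged)
    return list(genes.values())


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]
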