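"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything on disk is tab-separated text, FASTA/FASTQ, SAM or GTF/BED so that
intermediate results stay inspectable with standard command-line tools.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

#: Column order of the annotated pairs table produced by :mod:`radip.annotate`.
PAIRS_COLUMNS = [
    "read_id",
    "rna_chrom",
    "rna_center",
    "rna_strand",
    "gene_id",
    "gene_biotype",
    "rna_region",
    "dna_chrom",
    "dna_start",
    "dna_end",
    "dna_center",
    "bin_id",
    "distance",
    "distance_class",
]


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` table into an ordered dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": int})
    if (df["length"] <= 0).any():
        raise ValueError(f"non-positive chromosome length in {path}")
    return dict(zip(df["chrom"], df["length"]))


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read the first three BED columns (0-based half-open intervals).

    Raises ``ValueError`` naming the offending line number on malformed input.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid BED interval [{start},{end})")
            rows.append((fields[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_pairs(path: str | os.PathLike) -> pd.DataFrame:
    """Read an annotated pairs table written by :func:`write_pairs`."""
    return pd.read_csv(path, sep="\t", dtype={"rna_chrom": str, "dna_chrom": str,
                                              "bin_id": str, "gene_id": str})


def write_pairs(pairs: pd.DataFrame, path: str | os.PathLike) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
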