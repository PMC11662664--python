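"""Synthetic genomes, annotations and chimeric RNA-adaptor-DNA libraries.

This module builds small but statistically faithful stand-ins for a real
RNA-chromatin interaction experiment: a random genome, a non-overlapping gene
annotation, a ground-truth table of (RNA gene, DNA bin) interaction pairs with
distance-decayed cis frequencies, a trans fraction and optional fold
enrichment at designated peak bins, and finally the chimeric single-end reads
(RNA tag + internal bridge adaptor + DNA tag) together with truth alignments.

Every generator is a pure function of its inputs and seed, so downstream
stages can be tested end-to-end against exact ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genes import GeneModel, GenomeBins
from .readwrite import write_chrom_sizes

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Default mean suppression applied to trans interaction intensities: trans
#: contacts are individually rare compared with proximal cis contacts.
DEFAULT_EPS_TRANS = 0.05


class GenerationError(RuntimeError):
    """Raised when a simulation request cannot be satisfied."""


class ConfigError(RuntimeError):
    """Raised for inconsistent simulation configuration."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimGenome:
    """A toy genome: named chromosomes with explicit A/C/G/T sequences."""

    chroms: dict[str, str]
    seed: int

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chroms.items()}

    def write_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_chrom_sizes(self, path: str | os.PathLike) -> None:
        write_chrom_sizes(self.sizes, path)


@dataclass
class SimTruth:
    """Ground-truth interaction table plus the parameters that generated it.

    ``pairs`` has one row per (gene, bin) support pair with its count weight
    (number of read events); ``planted_enriched`` flags pairs whose DNA bin
    overlaps a designated peak and whose intensity was scaled by
    ``enrichment_fold`` (IP condition only).
    """

    pairs: pd.DataFrame
    planted_enriched: set[tuple[str, str]]
    trans_fraction: float
    decay_scale: float
    mu0: float
    r0: float
    condition: str
    params: dict = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return int(self.pairs["count"].sum())


def make_genome(n_chroms: int, lengths: list[int], seed: int,
                prefix: str = "chrS") -> SimGenome:
    """Generate a uniform-composition random genome.

    Chromosomes are named ``<prefix>1..<prefix>n``. Identical seeds produce
    byte-identical sequences.
    """
    if n_chroms != len(lengths):
        raise ValueError(f"n_chroms={n_chroms} but {len(lengths)} lengths given")
    if any(L <= 0 for L in lengths):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    chroms = {}
    for i, L in enumerate(lengths, start=1):
        seq = rng.choice(alphabet, size=L)
        chroms[f"{prefix}{i}"] = seq.tobytes().decode()
    return SimGenome(chroms, seed)


def make_annotation(genome: SimGenome, n_genes: int,
                    biotype_fractions: dict[str, float] | None = None,
                    seed: int = 0,
                    gene_length_range: tuple[int, int] = (2_000, 10_000),
                    max_exons: int = 4,
                    intron_fraction: float | None = None) -> list[GeneModel]:
    """Place non-overlapping genes with strands, biotypes and exon structure.

    ``biotype_fractions`` maps biotype names (protein_coding, lncRNA, other)
    to sampling proportions summing to 1. Multi-exon genes carry intronic gaps;
    ``intron_fraction``, if given, fixes the intronic share of each multi-exon
    gene body (otherwise exon boundaries are random).
    """
    if biotype_fractions is None:
        biotype_fractions = {"protein_coding": 0.8, "lncRNA": 0.15, "other": 0.05}
    total = sum(biotype_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"biotype fractions sum to {total}, expected 1")
    rng = np.random.default_rng(seed)
    sizes = genome.sizes
    chrom_names = list(sizes)
    chrom_weights = np.array([sizes[c] for c in chrom_names], dtype=float)
    chrom_weights /= chrom_weights.sum()
    biotypes = list(biotype_fractions)
    bt_probs = np.array([biotype_fractions[b] for b in biotypes])

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    genes: list[GeneModel] = []
    attempts = 0
    max_attempts = 200 * n_genes
    while len(genes) < n_genes:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {n_genes} non-overlapping genes "
                f"(placed {len(genes)}); genome too small")
        chrom = rng.choice(chrom_names, p=chrom_weights)
        length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        if length >= sizes[chrom]:
            continue
        start = int(rng.integers(0, sizes[chrom] - length))
        end = start + length
        if any(start < e and s < end for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = biotypes[rng.choice(len(biotypes), p=bt_probs)]
        n_exons = int(rng.integers(1, max_exons + 1))
        exons = _make_exons(start, end, n_exons, rng, intron_fraction)
        genes.append(GeneModel(f"gene{len(genes) + 1:04d}", chrom, start, end,
                               strand, biotype, exons))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _make_exons(start: int, end: int, n_exons: int, rng: np.random.Generator,
                intron_fraction: float | None) -> list[tuple[int, int]]:
    # single-exon genes have zero intronic bases; multi-exon genes split the
    # body into alternating exon/intron blocks anchored at both gene ends
    if n_exons == 1:
        return [(start, end)]
    length = end - start
    if intron_fraction is None:
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2,
                                  replace=False))
    else:
        exonic = max(n_exons, int(round(length * (1 - intron_fraction))))
        exon_lens = np.full(n_exons, exonic // n_exons)
        exon_lens[:exonic % n_exons] += 1
        intronic = length - exon_lens.sum()
        intron_lens = np.full(n_exons - 1, intronic // (n_exons - 1))
        intron_lens[:intronic % (n_exons - 1)] += 1
        bounds = []
        pos = 0
        for i in range(n_exons - 1):
            pos += exon_lens[i]
            bounds.append(pos)
            pos += intron_lens[i]
            bounds.append(pos)
        cuts = np.array(bounds)
    edges = np.concatenate([[0], cuts, [length]])
    return [(start + int(edges[2 * i]), start + int(edges[2 * i + 1]))
            for i in range(n_exons)]


def _peak_bins(bins: GenomeBins, peaks: pd.DataFrame | None) -> set[tuple[str, int]]:
    if peaks is None or len(peaks) == 0:
        return set()
    hits: set[tuple[str, int]] = set()
    for chrom, start, end in peaks[["chrom", "start", "end"]].itertuples(index=False):
        if chrom not in bins.chrom_sizes:
            continue
        end = min(end, bins.chrom_sizes[chrom])
        first = start // bins.width
        last = (end - 1) // bins.width
        for i in range(first, last + 1):
            hits.add((chrom, i))
    return hits


def _sample_ztnb(mu: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated NB draws with mean parameter mu (pre-truncation)."""
    p = r / (r + np.asarray(mu, dtype=float))
    out = rng.negative_binomial(r, p)
    out = np.atleast_1d(out)
    zero = out == 0
    while zero.any():
        out[zero] = rng.negative_binomial(r, p[zero])
        zero = out == 0
    return out


def simulate_interactions(genes: list[GeneModel], bins: GenomeBins,
                          mu0: float = 2.0, r0: float = 1.0,
                          decay_scale: float = 100_000.0,
                          trans_fraction: float = 0.7,
                          peaks: pd.DataFrame | None = None,
                          enrichment_fold: float = 1.0,
                          n_pairs: int = 10_000,
                          condition: str = "input",
                          eps_trans: float = DEFAULT_EPS_TRANS,
                          seed: int = 0) -> SimTruth:
    """Draw a ground-truth interaction table with exactly ``n_pairs`` reads.

    Support pairs are sampled sequentially: the source gene uniformly, a
    cis/trans Bernoulli at ``trans_fraction``, the target bin from the
    exponential distance kernel ``exp(-d / decay_scale)`` on the gene's
    chromosome (cis) or uniformly over other chromosomes (trans). Each support
    pair receives a zero-truncated NB(mu, r0) count weight with
    ``mu = mu0 * exp(-d / decay_scale)`` in cis and ``mu0 * eps_trans`` in
    trans; bins overlapping ``peaks`` have mu multiplied by
    ``enrichment_fold`` when ``condition == "ip"``. Sampling stops when the
    accumulated count weights reach ``n_pairs`` read events (the final pair is
    trimmed), so the emitted library size is exact.
    """
    if not genes:
        raise ValueError("empty gene set")
    if not (0.0 <= trans_fraction <= 1.0):
        raise ValueError("trans_fraction must be in [0, 1]")
    if enrichment_fold < 1.0:
        raise ValueError("enrichment_fold must be >= 1")
    if condition not in ("input", "ip"):
        raise ValueError("condition must be 'input' or 'ip'")
    rng = np.random.default_rng(seed)
    peak_set = _peak_bins(bins, peaks)
    apply_fold = (condition == "ip") and enrichment_fold > 1.0

    chrom_names = list(bins.chrom_sizes)
    # per-gene cis kernel over the bins of its own chromosome
    kernels = []
    for g in genes:
        centers = np.array([bins.bin_center(g.chrom, i)
                            for i in range(bins.n_bins[g.chrom])])
        gcenter = (g.start + g.end) // 2
        d = np.abs(centers - gcenter)
        w = np.exp(-d / decay_scale) if np.isfinite(decay_scale) else np.ones_like(d, float)
        kernels.append((d, w / w.sum()))
    trans_bins = {c: [(c2, i) for c2 in chrom_names if c2 != c
                      for i in range(bins.n_bins[c2])]
                  for c in chrom_names}

    rows = []
    total = 0
    batch = max(256, n_pairs // 8)
    while total < n_pairs:
        gidx = rng.integers(0, len(genes), size=batch)
        is_trans = rng.random(batch) < trans_fraction
        for k in range(batch):
            g = genes[gidx[k]]
            if is_trans[k]:
                cands = trans_bins[g.chrom]
                if not cands:  # single-chromosome genome: fall back to cis
                    is_trans[k] = False
                else:
                    chrom, bi = cands[rng.integers(0, len(cands))]
                    mu = mu0 * eps_trans
            if not is_trans[k]:
                d, w = kernels[gidx[k]]
                bi = int(rng.choice(len(w), p=w))
                chrom = g.chrom
                mu = mu0 * float(np.exp(-d[bi] / decay_scale)) \
                    if np.isfinite(decay_scale) else mu0
            at_peak = (chrom, bi) in peak_set
            if at_peak and apply_fold:
                mu *= enrichment_fold
            count = int(_sample_ztnb(np.array([mu]), r0, rng)[0])
            rows.append((g.gene_id, g.chrom, chrom, bi, bool(is_trans[k]),
                         at_peak, mu, count))
            total += count
            if total >= n_pairs:
                break
    # trim the final pair so emitted reads equal the requested total
    overshoot = total - n_pairs
    if overshoot:
        last = rows[-1]
        rows[-1] = last[:-1] + (last[-1] - overshoot,)
        if rows[-1][-1] == 0:
            rows.pop()

    pairs = pd.DataFrame(rows, columns=["gene_id", "rna_chrom", "dna_chrom",
                                        "bin_index", "is_trans", "at_peak",
                                        "mu", "count"])
    pairs = (pairs.groupby(["gene_id", "rna_chrom", "dna_chrom", "bin_index",
                            "is_trans", "at_peak"], as_index=False)
             .agg(mu=("mu", "first"), count=("count", "sum"),
                  n_draws=("count", "size")))
    pairs["bin_id"] = pairs["dna_chrom"] + ":" + pairs["bin_index"].astype(str)
    planted = {(r.gene_id, r.bin_id) for r in pairs.itertuples()
               if r.at_peak and apply_fold}
    return SimTruth(pairs=pairs, planted_enriched=planted,
                    trans_fraction=trans_fraction, decay_scale=decay_scale,
                    mu0=mu0, r0=r0, condition=condition,
                    params={"eps_trans": eps_trans,
                            "enrichment_fold": enrichment_fold,
                            "n_pairs": n_pairs, "seed": seed,
                            "bin_width": bins.width,
                            "peaks": peaks})


def emit_reads(genome: SimGenome, genes: list[GeneModel], truth: SimTruth,
               adaptor: str, outdir: str | os.PathLike,
               tag_len_range: tuple[int, int] = (25, 27),
               error_rate: float = 0.0, seed: int = 0,
               prefix: str = "sim") -> dict[str, str]:
    """Write the chimeric FASTQ plus truth SAM/pairs files for a SimTruth.

    Each read is ``RNA tag + adaptor + DNA tag`` (RNA side 5' of the adaptor).
    RNA tags are drawn uniformly inside their source gene and reported on the
    gene strand (reverse-complemented in the read for minus-strand genes);
    DNA tags are drawn uniformly inside their target bin on the forward
    strand. For IP libraries with fold enrichment, the excess reads of
    peak-overlapping pairs — a fraction (fold-1)/fold of each such pair's
    reads — have their DNA tag placed so it overlaps the peak interval,
    mirroring immunoprecipitation pulling down fragments at the mark.
    Substitution errors at ``error_rate`` apply to the whole read.
    Truth SAM files carry the exact tag coordinates at MAPQ 37.
    """
    lo, hi = tag_len_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid tag length range")
    if not set(adaptor) <= set("ACGT") or not adaptor:
        raise ConfigError("adaptor must be a non-empty A/C/G/T string")
    gene_map = {g.gene_id: g for g in genes}
    rng = np.random.default_rng(seed)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fastq": os.path.join(outdir, f"{prefix}.reads.fastq"),
        "rna_sam": os.path.join(outdir, f"{prefix}.rna.sam"),
        "dna_sam": os.path.join(outdir, f"{prefix}.dna.sam"),
        "pairs": os.path.join(outdir, f"{prefix}.truth_pairs.tsv"),
    }
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": c, "LN": L} for c, L in genome.sizes.items()]}
    fold = truth.params.get("enrichment_fold", 1.0)
    peak_pull = (truth.condition == "ip") and fold > 1.0
    p_peak = (fold - 1.0) / fold if peak_pull else 0.0
    peaks = truth.params.get("peaks")
    peak_by_bin: dict[tuple[str, int], list[tuple[int, int]]] = {}
    if peak_pull and peaks is not None:
        w = truth.params["bin_width"]
        for chrom, ps, pe in peaks[["chrom", "start", "end"]].itertuples(index=False):
            for bi in range(ps // w, (max(pe - 1, ps)) // w + 1):
                peak_by_bin.setdefault((chrom, bi), []).append((ps, pe))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    bases = "ACGT"

    with open(paths["fastq"], "w") as fq, \
            pysam.AlignmentFile(paths["rna_sam"], "wh", header=header) as rsam, \
            pysam.AlignmentFile(paths["dna_sam"], "wh", header=header) as dsam, \
            open(paths["pairs"], "w") as tp:
        tp.write("read_id\tgene_id\tbin_id\trna_chrom\trna_start\trna_end\t"
                 "rna_strand\tdna_chrom\tdna_start\tdna_end\n")
        read_no = 0
        for row in truth.pairs.itertuples():
            g = gene_map[row.gene_id]
            for _ in range(int(row.count)):
                read_no += 1
                rid = f"{prefix}_read{read_no:07d}"
                rlen = int(rng.integers(lo, hi + 1))
                dlen = int(rng.integers(lo, hi + 1))
                if g.length < rlen:
                    raise GenerationError(f"gene {g.gene_id} shorter than tag")
                rstart = int(rng.integers(g.start, g.end - rlen + 1))
                bs, be = _bin_interval(genome, row.dna_chrom, row.bin_index,
                                       truth)
                hit_peaks = peak_by_bin.get((row.dna_chrom, row.bin_index))
                if (row.at_peak and hit_peaks and rng.random() < p_peak):
                    # enriched read: DNA tag overlaps the peak interval
                    ps, pe = hit_peaks[int(rng.integers(0, len(hit_peaks)))]
                    s_lo = max(0, ps - dlen + 1)
                    s_hi = min(pe - 1, len(genome.chroms[row.dna_chrom]) - dlen)
                    dstart = int(rng.integers(s_lo, s_hi + 1)) if s_hi >= s_lo \
                        else max(0, pe - dlen)
                elif be - bs >= dlen:
                    dstart = int(rng.integers(bs, be - dlen + 1))
                else:
                    dstart = max(0, be - dlen)
                rna_genomic = genome.chroms[g.chrom][rstart:rstart + rlen]
                rna_read = revcomp(rna_genomic) if g.strand == "-" else rna_genomic
                dna_seq = genome.chroms[row.dna_chrom][dstart:dstart + dlen]
                read = rna_read + adaptor + dna_seq
                if error_rate > 0:
                    arr = list(read)
                    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
                    for h in hits:
                        shift = int(rng.integers(1, 4))
                        arr[h] = bases[(base_idx[arr[h]] + shift) % 4]
                    read = "".join(arr)
                fq.write(f"@{rid}\n{read}\n+\n{'I' * len(read)}\n")
                _write_aln(rsam, rid, g.chrom, rstart, rna_genomic,
                           reverse=(g.strand == "-"))
                _write_aln(dsam, rid, row.dna_chrom, dstart, dna_seq,
                           reverse=False)
                tp.write(f"{rid}\t{g.gene_id}\t{row.bin_id}\t{g.chrom}\t"
                         f"{rstart}\t{rstart + rlen}\t{g.strand}\t"
                         f"{row.dna_chrom}\t{dstart}\t{dstart + dlen}\n")
    return paths


def _bin_interval(genome: SimGenome, chrom: str, index: int,
                  truth: SimTruth) -> tuple[int, int]:
    w = truth.params.get("bin_width", 25_000)
    start = index * w
    return start, min(start + w, len(genome.chroms[chrom]))


def _write_aln(sam: pysam.AlignmentFile, rid: str, chrom: str, start: int,
               seq: str, reverse: bool) -> None:
    a = pysam.AlignedSegment(sam.header)
    a.query_name = rid
    a.query_sequence = seq
    a.flag = 16 if reverse else 0
    a.reference_id = sam.header.get_tid(chrom)
    a.reference_start = start
    a.mapping_quality = 37
    a.cigarstring = f"{len(seq)}M"
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    sam.write(a)


def make_peaks(bins: GenomeBins, n_peaks: int, peak_width: int = 2_000,
               seed: int = 0) -> pd.DataFrame:
    """Place peak intervals at the centers of randomly chosen distinct bins."""
    rng = np.random.default_rng(seed)
    all_bins = list(bins.iter_bins())
    if n_peaks > len(all_bins):
        raise ValueError("more peaks requested than bins available")
    chosen = rng.choice(len(all_bins), size=n_peaks, replace=False)
    rows = []
    for idx in sorted(chosen):
        chrom, i = all_bins[idx]
        c = bins.bin_center(chrom, i)
        half = peak_width // 2
        start = max(0, c - half)
        end = min(bins.chrom_sizes[chrom], c + half)
        rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
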