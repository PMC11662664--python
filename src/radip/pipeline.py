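"""End-to-end orchestration: simulate -> deconvolve -> annotate -> call ->
differential -> summarize, with structured config, per-stage seeds, and a
manifest of produced files.

All randomness flows from one root seed, split deterministically per stage
and replicate, so a re-run with the same config and seed reproduces identical
non-timestamp outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analytics import (biotype_region_breakdown, cis_trans_summary,
                        mc_chisq_similarity, metaprofile, peak_overlap_fraction,
                        saturation_curves)
from .annotate import annotate_pairs, build_pairs, read_sam_tags
from .deconvolve import BridgeAdaptorSpec, DEFAULT_ADAPTOR, deconvolve_fastq, qc_report
from .enrichment import build_special_sets, differential_test
from .genes import GenomeBins, read_gtf
from .readwrite import read_bed, read_pairs, write_bed, write_pairs, write_table
from .significance import call_significant
from .synthetic_data import (make_annotation, make_genome, make_peaks,
                             simulate_interactions, emit_reads)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "deconvolve", "annotate", "call", "differential",
          "summarize"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; YAML round-trippable."""

    outdir: str = "radip_run"
    seed: int = 0
    # genome / annotation
    chrom_lengths: list[int] = field(default_factory=lambda: [600_000, 400_000])
    n_genes: int = 60
    biotype_fractions: dict[str, float] = field(
        default_factory=lambda: {"protein_coding": 0.8, "lncRNA": 0.15, "other": 0.05})
    # interaction simulation
    bin_size: int = 25_000
    n_pairs: int = 4_000
    n_replicates: int = 4
    mu0: float = 2.0
    r0: float = 1.0
    decay_scale: float = 100_000.0
    trans_fraction: float = 0.7
    n_peaks: int = 8
    enrichment_fold: float = 4.0
    error_rate: float = 0.0
    # deconvolution
    adaptor: str = DEFAULT_ADAPTOR
    max_mismatches: int = 1
    min_tag_len: int = 25
    max_tag_len: int = 27
    # annotation / significance / differential
    mapq: int = 37
    q_max: float = 0.1
    min_bins: int = 10
    adjp_max: float = 0.1
    lfc_min: float = 0.5
    # per-RNA counting basis for the differential stage: "raw" uses all
    # annotated pairs (enrichment is best judged before background removal),
    # "filtered" restricts to background-passing pairs
    differential_counts: str = "raw"
    # analytics
    flank: int = 3_000
    step: int = 50
    depth_fractions: list[float] = field(
        default_factory=lambda: [0.1, 0.25, 0.5, 0.75, 1.0])

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        # outdir is a location, not a semantic parameter
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        canon = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_seed(root_seed: int, stage: str, replicate: int = 0) -> int:
    """Deterministic per-stage, per-replicate seed below 2**31."""
    ss = np.random.SeedSequence(entropy=root_seed,
                                spawn_key=(STAGES.index(stage), replicate))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


class PipelineError(RuntimeError):
    pass


def _conditions(cfg: RunConfig):
    for cond in ("input", "ip"):
        for rep in range(1, cfg.n_replicates + 1):
            yield cond, rep


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in order and return the manifest.

    Later stages read earlier stages' on-disk outputs, so the pipeline can be
    restarted per stage. Raises PipelineError naming the stage and missing
    file when an input is absent.
    """
    stages = stages or STAGES
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    stages = sorted(stages, key=STAGES.index)
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {"version": __version__, "config_hash": cfg.config_hash(),
                      "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "files": {}}
    cfg.to_yaml(os.path.join(cfg.outdir, "config.yaml"))
    for stage in stages:
        logger.info("stage %s", stage)
        getattr(_Stages, stage)(cfg, manifest)
    manifest_path = os.path.join(cfg.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _record(manifest: dict, path: str, rows: int | None = None) -> None:
    if rows is None:
        try:
            with open(path) as fh:
                rows = sum(1 for _ in fh)
        except UnicodeDecodeError:
            rows = -1
    manifest["files"][os.path.basename(path)] = rows


def _need(path: str, stage: str) -> str:
    if not os.path.exists(path):
        raise PipelineError(f"stage '{stage}' requires missing input: {path}")
    return path


class _Stages:
    @staticmethod
    def simulate(cfg: RunConfig, manifest: dict) -> None:
        out = cfg.outdir
        seed = stage_seed(cfg.seed, "simulate")
        genome = make_genome(len(cfg.chrom_lengths), cfg.chrom_lengths, seed)
        genes = make_annotation(genome, cfg.n_genes, cfg.biotype_fractions,
                                seed=seed + 1)
        bins = GenomeBins(genome.sizes, cfg.bin_size)
        peaks = make_peaks(bins, cfg.n_peaks, seed=seed + 2)
        genome.write_fasta(os.path.join(out, "genome.fa"))
        genome.write_chrom_sizes(os.path.join(out, "chrom.sizes"))
        from .genes import write_gtf
        write_gtf(genes, os.path.join(out, "genes.gtf"))
        write_bed(peaks.itertuples(index=False), os.path.join(out, "peaks.bed"))
        for path in ("genome.fa", "chrom.sizes", "genes.gtf", "peaks.bed"):
            _record(manifest, os.path.join(out, path))
        for cond, rep in _conditions(cfg):
            rep_seed = stage_seed(cfg.seed, "simulate",
                                  replicate=rep + (100 if cond == "ip" else 0))
            truth = simulate_interactions(
                genes, bins, mu0=cfg.mu0, r0=cfg.r0,
                decay_scale=cfg.decay_scale, trans_fraction=cfg.trans_fraction,
                peaks=peaks, enrichment_fold=cfg.enrichment_fold,
                n_pairs=cfg.n_pairs, condition=cond, seed=rep_seed)
            paths = emit_reads(genome, genes, truth, cfg.adaptor, out,
                               tag_len_range=(cfg.min_tag_len, cfg.max_tag_len),
                               error_rate=cfg.error_rate, seed=rep_seed + 7,
                               prefix=f"{cond}_rep{rep}")
            for p in paths.values():
                _record(manifest, p)

    @staticmethod
    def deconvolve(cfg: RunConfig, manifest: dict) -> None:
        spec = BridgeAdaptorSpec(cfg.adaptor, cfg.max_mismatches,
                                 min_tag_len=cfg.min_tag_len,
                                 max_tag_len=cfg.max_tag_len)
        for cond, rep in _conditions(cfg):
            prefix = os.path.join(cfg.outdir, f"{cond}_rep{rep}")
            fq = _need(f"{prefix}.reads.fastq", "deconvolve")
            pairs = deconvolve_fastq(fq, spec, f"{prefix}.rna_tags.fastq",
                                     f"{prefix}.dna_tags.fastq")
            with open(f"{prefix}.qc.json", "w") as fh:
                json.dump(qc_report(pairs), fh)
            for suffix in (".rna_tags.fastq", ".dna_tags.fastq", ".qc.json"):
                _record(manifest, prefix + suffix)

    @staticmethod
    def annotate(cfg: RunConfig, manifest: dict) -> None:
        out = cfg.outdir
        genes = read_gtf(_need(os.path.join(out, "genes.gtf"), "annotate"))
        from .readwrite import read_chrom_sizes
        sizes = read_chrom_sizes(_need(os.path.join(out, "chrom.sizes"), "annotate"))
        bins = GenomeBins(sizes, cfg.bin_size)
        for cond, rep in _conditions(cfg):
            prefix = os.path.join(out, f"{cond}_rep{rep}")
            # alignment is external in production; the orchestrated run uses
            # the simulator's truth alignments restricted to deconvolved reads
            rna = read_sam_tags(_need(f"{prefix}.rna.sam", "annotate"))
            dna = read_sam_tags(_need(f"{prefix}.dna.sam", "annotate"))
            kept_ids = set()
            with open(_need(f"{prefix}.rna_tags.fastq", "annotate")) as fh:
                for i, line in enumerate(fh):
                    if i % 4 == 0:
                        kept_ids.add(line[1:].strip())
            rna = [t for t in rna if t.read_id in kept_ids]
            dna = [t for t in dna if t.read_id in kept_ids]
            records, stats = annotate_pairs(rna, dna, genes, bins,
                                            required_mapq=cfg.mapq)
            write_pairs(records, f"{prefix}.pairs.tsv")
            with open(f"{prefix}.annotate_stats.json", "w") as fh:
                json.dump(stats, fh)
            _record(manifest, f"{prefix}.pairs.tsv", len(records))
            _record(manifest, f"{prefix}.annotate_stats.json", 1)

    @staticmethod
    def call(cfg: RunConfig, manifest: dict) -> None:
        out = cfg.outdir
        for cond in ("input", "ip"):
            frames = []
            for rep in range(1, cfg.n_replicates + 1):
                path = _need(os.path.join(out, f"{cond}_rep{rep}.pairs.tsv"), "call")
                frames.append(read_pairs(path))
            merged = pd.concat(frames, ignore_index=True)
            counts = build_pairs(merged)
            results = call_significant(counts, q_max=cfg.q_max,
                                       min_bins=cfg.min_bins)
            write_table(results, os.path.join(out, f"{cond}.significance.tsv"))
            sig_pairs = results.loc[results["significant"],
                                    ["gene_id", "bin_id"]]
            filtered = merged.merge(sig_pairs, on=["gene_id", "bin_id"])
            write_pairs(filtered, os.path.join(out, f"{cond}.filtered_pairs.tsv"))
            _record(manifest, os.path.join(out, f"{cond}.significance.tsv"),
                    len(results))
            _record(manifest, os.path.join(out, f"{cond}.filtered_pairs.tsv"),
                    len(filtered))

    @staticmethod
    def differential(cfg: RunConfig, manifest: dict) -> None:
        out = cfg.outdir
        # per-replicate per-RNA counts, restricted to background-passing pairs
        if cfg.differential_counts == "filtered":
            sig = {cond: pd.read_csv(_need(os.path.join(out, f"{cond}.significance.tsv"),
                                           "differential"), sep="\t")
                   for cond in ("input", "ip")}
            keep = {cond: set(map(tuple, s.loc[s["significant"],
                                               ["gene_id", "bin_id"]].to_numpy()))
                    for cond, s in sig.items()}
        else:
            keep = None
        cols: dict[str, pd.Series] = {}
        species: dict[str, set] = {}
        for cond, rep in _conditions(cfg):
            path = _need(os.path.join(out, f"{cond}_rep{rep}.pairs.tsv"),
                         "differential")
            pairs = read_pairs(path).dropna(subset=["gene_id"])
            if keep is not None:
                mask = [(g, b) in keep[cond] for g, b in
                        zip(pairs["gene_id"], pairs["bin_id"])]
                pairs = pairs.loc[mask]
            cols[f"{cond}_rep{rep}"] = pairs.groupby("gene_id").size()
            species.setdefault(cond, set()).update(pairs["gene_id"].unique())
        table = pd.DataFrame(cols).fillna(0).astype(int)
        common = sorted(species["input"] & species["ip"])
        input_cols = [f"input_rep{r}" for r in range(1, cfg.n_replicates + 1)]
        ip_cols = [f"ip_rep{r}" for r in range(1, cfg.n_replicates + 1)]
        diff = differential_test(table.loc[common], input_cols, ip_cols,
                                 adjp_max=cfg.adjp_max, lfc_min=cfg.lfc_min)
        write_table(diff, os.path.join(out, "differential.tsv"))
        sets = build_special_sets(species["input"], species["ip"], diff)
        rows = [(cond, gene,
                 gene in sets.unique[cond], gene in sets.enriched[cond])
                for cond in ("input", "ip") for gene in sorted(sets.special[cond])]
        special = pd.DataFrame(rows, columns=["condition", "gene_id",
                                              "unique", "enriched"])
        write_table(special, os.path.join(out, "special_sets.tsv"))
        _record(manifest, os.path.join(out, "differential.tsv"), len(diff))
        _record(manifest, os.path.join(out, "special_sets.tsv"), len(special))

    @staticmethod
    def summarize(cfg: RunConfig, manifest: dict) -> None:
        out = cfg.outdir
        from .readwrite import read_chrom_sizes
        genes = read_gtf(_need(os.path.join(out, "genes.gtf"), "summarize"))
        peaks = read_bed(_need(os.path.join(out, "peaks.bed"), "summarize"))
        seed = stage_seed(cfg.seed, "summarize")
        per_gene_tables = {}
        for cond in ("input", "ip"):
            pairs = read_pairs(_need(os.path.join(out, f"{cond}_rep1.pairs.tsv"),
                                     "summarize"))
            merged = pd.concat(
                [read_pairs(os.path.join(out, f"{cond}_rep{r}.pairs.tsv"))
                 for r in range(1, cfg.n_replicates + 1)], ignore_index=True)
            write_table(cis_trans_summary(merged),
                        os.path.join(out, f"{cond}.distance_summary.tsv"))
            depths = [f for f in cfg.depth_fractions]
            write_table(saturation_curves(merged, depths, seed=seed),
                        os.path.join(out, f"{cond}.saturation.tsv"))
            write_table(metaprofile(merged, peaks, cfg.flank, cfg.step),
                        os.path.join(out, f"{cond}.metaprofile.tsv"))
            write_table(biotype_region_breakdown(merged, genes),
                        os.path.join(out, f"{cond}.breakdown.tsv"))
            overlap = peak_overlap_fraction(merged, peaks)
            with open(os.path.join(out, f"{cond}.peak_overlap.json"), "w") as fh:
                json.dump(overlap, fh)
            per_gene_tables[cond] = merged.dropna(subset=["gene_id"]) \
                .groupby("gene_id").size()
            for suffix in ("distance_summary", "saturation", "metaprofile",
                           "breakdown"):
                _record(manifest, os.path.join(out, f"{cond}.{suffix}.tsv"))
            _record(manifest, os.path.join(out, f"{cond}.peak_overlap.json"), 1)
        universe = sorted(set(per_gene_tables["input"].index) |
                          set(per_gene_tables["ip"].index))
        a = per_gene_tables["input"].reindex(universe).fillna(0).to_numpy()
        b = per_gene_tables["ip"].reindex(universe).fillna(0).to_numpy()
        stat, p = mc_chisq_similarity(a, b, seed=seed)
        with open(os.path.join(out, "similarity.json"), "w") as fh:
            json.dump({"chisq": stat, "p": p, "n_categories": len(universe)}, fh)
        _record(manifest, os.path.join(out, "similarity.json"), 1)
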