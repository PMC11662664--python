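"""Split chimeric reads into RNA and DNA tags at the internal bridge adaptor.

The library design places the RNA-derived tag on the 5' side of a fully
sequenced bridge adaptor and the DNA-derived tag on the 3' side (orientation
configurable). Adaptor matching is Hamming-only: tags are short and the
protocol requires the entire adaptor to be present in the read, so indel
tolerance buys little and costs determinism.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Placeholder bridge adaptor used by the simulator and as a CLI default.
#: The exact production chemistry is configurable via BridgeAdaptorSpec.
DEFAULT_ADAPTOR = "CTGCTGAGGATCCATGAG"


@dataclass(frozen=True)
class BridgeAdaptorSpec:
    """How to find the internal adaptor and size-select the flanking tags."""

    sequence: str = DEFAULT_ADAPTOR
    max_mismatches: int = 0
    rna_side: str = "five_prime"
    min_tag_len: int = 25
    max_tag_len: int = 27

    def __post_init__(self) -> None:
        if not self.sequence or not set(self.sequence) <= set("ACGT"):
            raise ValueError("adaptor sequence must be non-empty over A/C/G/T")
        if self.rna_side not in ("five_prime", "three_prime"):
            raise ValueError("rna_side must be five_prime or three_prime")
        if not (1 <= self.min_tag_len <= self.max_tag_len):
            raise ValueError("require 1 <= min_tag_len <= max_tag_len")


@dataclass
class TagPair:
    """One read's RNA tag and DNA tag after adaptor-based splitting."""

    read_id: str
    rna_seq: str = ""
    rna_quals: str = ""
    dna_seq: str = ""
    dna_quals: str = ""
    adaptor_offset: int | None = None
    adaptor_found: bool = False
    multi_hit: bool = False
    length_pass: bool = False
    qual_pass: bool = True
    trim_flag: bool = False


def locate_adaptor(read_seq: str, spec: BridgeAdaptorSpec) -> tuple[int | None, bool]:
    """Find the leftmost adaptor occurrence within the mismatch budget.

    Returns ``(offset, multi_hit)``; offset is None when no window of the
    read matches the adaptor at Hamming distance <= max_mismatches. When
    several windows qualify the leftmost is chosen and multi_hit is set.
    """
    adaptor = spec.sequence
    n, m = len(read_seq), len(adaptor)
    if n < m:
        return None, False
    if spec.max_mismatches == 0:
        first = read_seq.find(adaptor)
        if first < 0:
            return None, False
        second = read_seq.find(adaptor, first + 1)
        return first, second >= 0
    read = np.frombuffer(read_seq.encode(), dtype=np.uint8)
    ad = np.frombuffer(adaptor.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(read, m)
    dists = (windows != ad).sum(axis=1)
    hits = np.nonzero(dists <= spec.max_mismatches)[0]
    if hits.size == 0:
        return None, False
    return int(hits[0]), hits.size > 1


def split_chimera(read_id: str, read_seq: str, read_quals: str,
                  offset: int | None, spec: BridgeAdaptorSpec,
                  multi_hit: bool = False) -> TagPair:
    """Cut a read at the located adaptor into an RNA tag and a DNA tag.

    Both tags are truncated to ``max_tag_len`` measured from the
    adaptor-proximal end; ``length_pass`` requires both tags to fall within
    [min_tag_len, max_tag_len]. An empty side fails the length filter rather
    than raising.
    """
    pair = TagPair(read_id=read_id)
    if offset is None:
        return pair
    m = len(spec.sequence)
    if offset < 0 or offset + m > len(read_seq):
        raise ValueError(f"adaptor offset {offset} invalid for read of length "
                         f"{len(read_seq)}")
    left_seq, left_q = read_seq[:offset], read_quals[:offset]
    right_seq, right_q = read_seq[offset + m:], read_quals[offset + m:]
    # adaptor-proximal trimming: keep the 3' end of the left side and the
    # 5' end of the right side
    if len(left_seq) > spec.max_tag_len:
        left_seq, left_q = (left_seq[-spec.max_tag_len:], left_q[-spec.max_tag_len:])
    if len(right_seq) > spec.max_tag_len:
        right_seq, right_q = (right_seq[:spec.max_tag_len], right_q[:spec.max_tag_len])
    if spec.rna_side == "five_prime":
        rna, rna_q, dna, dna_q = left_seq, left_q, right_seq, right_q
    else:
        rna, rna_q, dna, dna_q = right_seq, right_q, left_seq, left_q
    length_pass = (spec.min_tag_len <= len(rna) <= spec.max_tag_len and
                   spec.min_tag_len <= len(dna) <= spec.max_tag_len)
    return TagPair(read_id=read_id, rna_seq=rna, rna_quals=rna_q,
                   dna_seq=dna, dna_quals=dna_q, adaptor_offset=offset,
                   adaptor_found=True, multi_hit=multi_hit,
                   length_pass=length_pass)


def deconvolve_read(read_id: str, read_seq: str, read_quals: str,
                    spec: BridgeAdaptorSpec) -> TagPair:
    offset, multi = locate_adaptor(read_seq, spec)
    return split_chimera(read_id, read_seq, read_quals, offset, spec, multi)


def deconvolve_fastq(fastq_path: str | os.PathLike, spec: BridgeAdaptorSpec,
                     rna_out: str | os.PathLike | None = None,
                     dna_out: str | os.PathLike | None = None,
                     min_mean_phred: float | None = None,
                     rrna_blocklist: set[str] | None = None) -> list[TagPair]:
    """Deconvolve every read of a FASTQ file; optionally write tag FASTQs.

    Quality is reported, not enforced, unless ``min_mean_phred`` is given;
    ``rrna_blocklist`` drops pairs whose RNA tag sequence is in the set
    (sequence-level contaminant filter).
    """
    pairs: list[TagPair] = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        pair = deconvolve_read(rec.id, str(rec.seq), quals, spec)
        if min_mean_phred is not None and pair.adaptor_found:
            phreds = [ord(c) - 33 for c in pair.rna_quals + pair.dna_quals]
            pair.qual_pass = bool(phreds) and float(np.mean(phreds)) >= min_mean_phred
        if rrna_blocklist and pair.rna_seq in rrna_blocklist:
            pair.qual_pass = False
        pairs.append(pair)
    if rna_out and dna_out:
        kept = [p for p in pairs if p.adaptor_found and p.length_pass and p.qual_pass]
        _write_tag_fastq(kept, rna_out, "rna")
        _write_tag_fastq(kept, dna_out, "dna")
    return pairs


def _write_tag_fastq(pairs: list[TagPair], path: str | os.PathLike, side: str) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            seq = p.rna_seq if side == "rna" else p.dna_seq
            quals = p.rna_quals if side == "rna" else p.dna_quals
            fh.write(f"@{p.read_id}\n{seq}\n+\n{quals}\n")


def trim_tags(pairs: list[TagPair], target_len: int) -> list[TagPair]:
    """Truncate both tags to ``target_len`` from the adaptor-proximal end.

    Tags already shorter than the target are left unchanged and flagged.
    Used to reproduce the effect of shorter tag chemistries on unique-mapping
    rates (e.g. the 27 -> 20 nt comparison).
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    out = []
    for p in pairs:
        if len(p.rna_seq) < target_len or len(p.dna_seq) < target_len:
            out.append(replace(p, trim_flag=True))
            continue
        # RNA tag is 5' of the adaptor: its adaptor-proximal end is its 3' end;
        # the DNA tag's adaptor-proximal end is its 5' end
        out.append(replace(
            p,
            rna_seq=p.rna_seq[-target_len:], rna_quals=p.rna_quals[-target_len:],
            dna_seq=p.dna_seq[:target_len], dna_quals=p.dna_quals[:target_len]))
    return out


def qc_report(pairs: list[TagPair]) -> dict:
    """Summarize tag qualities, lengths and base composition.

    Returns per-position mean Phred score, the overall fraction of bases at
    Phred >= 25, tag-length histograms and per-position base fractions for
    each side. Inputs are not mutated.
    """
    if not pairs:
        logger.warning("qc_report called with no tag pairs")
        return {"n_reads": 0}
    report: dict = {"n_reads": len(pairs),
                    "adaptor_found_rate": float(np.mean([p.adaptor_found for p in pairs])),
                    "length_pass_rate": float(np.mean([p.length_pass for p in pairs])),
                    "multi_hit_rate": float(np.mean([p.multi_hit for p in pairs]))}
    for side in ("rna", "dna"):
        seqs = [getattr(p, f"{side}_seq") for p in pairs if getattr(p, f"{side}_seq")]
        quals = [getattr(p, f"{side}_quals") for p in pairs if getattr(p, f"{side}_seq")]
        if not seqs:
            continue
        maxlen = max(len(s) for s in seqs)
        phred_sum = np.zeros(maxlen)
        phred_n = np.zeros(maxlen)
        base_counts = np.zeros((maxlen, 4))
        ge25 = total = 0
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for s, q in zip(seqs, quals):
            for i, (b, qc) in enumerate(zip(s, q)):
                ph = ord(qc) - 33
                phred_sum[i] += ph
                phred_n[i] += 1
                ge25 += ph >= 25
                total += 1
                if b in base_idx:
                    base_counts[i, base_idx[b]] += 1
        with np.errstate(invalid="ignore"):
            comp = base_counts / base_counts.sum(axis=1, keepdims=True)
        report[side] = {
            "mean_phred_by_pos": (phred_sum / np.maximum(phred_n, 1)).tolist(),
            "frac_phred_ge25": ge25 / total,
            "length_hist": dict(sorted(Counter(len(s) for s in seqs).items())),
            "base_composition_by_pos": comp.tolist(),
        }
    return report
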