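"""Truth-aware long-read simulator.

Generates a random reference, implants deletions on an alternate haplotype,
simulates noisy continuous long reads (CLR-like: ~20 kb mean length, ~15%
base error split between substitutions and 1-bp indels) and emits the
alignments directly as SAM: each read's CIGAR is constructed from the known
truth coordinates, so a read spanning an implanted deletion carries a D op of
the true length and no external aligner is needed.  Homozygous runs draw all
reads from the alternate haplotype; heterozygous runs draw each read from the
alternate or reference haplotype with probability 1/2.  Everything is
reproducible from the config seed.

This hermetic alignment emulation is a deliberate fidelity trade: it removes
mapping artefacts (no chimeric splits, no mismapped reads), which makes every
downstream stage testable against exact truth, at the cost of being cleaner
than aligner output.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np
import pysam

from .alignment_io import AlignmentRecord, write_alignments

MIN_DELETION_SEPARATION = 10_000   # one read rarely spans two events
EDGE_MARGIN = 5_000
MIN_READ_LEN = 1_000

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    ref_length: int = 500_000
    n_deletions: int = 30
    size_ranges: List[Tuple[int, int]] = field(
        default_factory=lambda: [(50, 1000), (1000, 5000)])
    zygosity: str = "homozygous"          # or "heterozygous"
    depth: float = 45.0
    read_len_mean: int = 20_000
    read_len_sd: int = 2_000
    error_rate: float = 0.15
    error_mix: Tuple[float, float, float] = (0.4, 0.3, 0.3)  # sub, ins, del
    clip_fraction: float = 0.02
    max_clip: int = 200
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.zygosity not in ("homozygous", "heterozygous"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if any(lo <= 0 or hi < lo for lo, hi in self.size_ranges):
            raise ValueError("size ranges must be positive and ordered")
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ValueError("error_mix must sum to 1")


@dataclass(frozen=True)
class TruthDeletion:
    chrom: str
    start: int     # 0-based inclusive
    end: int       # 0-based exclusive
    zygosity: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimResult:
    records: List[AlignmentRecord]
    truth: List[TruthDeletion]
    reference: str
    config: SimConfig
    manifest: dict


# ------------------------------------------------------------- construction

def _place_deletions(rng: np.random.Generator, cfg: SimConfig
                     ) -> List[Tuple[int, int]]:
    """Non-overlapping deletion intervals with the separation constraint.

    Sizes are drawn uniformly within a uniformly chosen size range; positions
    are a uniform composition of the leftover slack, which always succeeds
    when the slack is non-negative and errors out otherwise.
    """
    n = cfg.n_deletions
    if n == 0:
        return []
    ranges = cfg.size_ranges
    sizes = np.empty(n, dtype=np.int64)
    for i in range(n):
        lo, hi = ranges[int(rng.integers(len(ranges)))]
        sizes[i] = int(rng.integers(lo, hi + 1))
    slack = (cfg.ref_length - 2 * EDGE_MARGIN - int(sizes.sum())
             - (n - 1) * MIN_DELETION_SEPARATION)
    if slack < 0:
        raise ValueError(
            f"cannot place {n} deletions (total {int(sizes.sum())} bp) on a "
            f"{cfg.ref_length} bp reference with {MIN_DELETION_SEPARATION} bp "
            "separation")
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    out = []
    pos = EDGE_MARGIN + int(cuts[0])
    for i in range(n):
        if i > 0:
            pos += MIN_DELETION_SEPARATION + int(cuts[i] - cuts[i - 1])
        out.append((pos, pos + int(sizes[i])))
        pos += int(sizes[i])
    return out


def _rle(ops: np.ndarray) -> List[Tuple[int, int]]:
    """Run-length encode an int op-code array into (code, length) runs."""
    if ops.size == 0:
        return []
    change = np.nonzero(np.diff(ops))[0] + 1
    bounds = np.concatenate([[0], change, [ops.size]])
    return [(int(ops[bounds[i]]), int(bounds[i + 1] - bounds[i]))
            for i in range(len(bounds) - 1)]


_OP_CHARS = {0: "M", 1: "D", 2: "I"}


def _simulate_read(rng, hap_codes, start, end, junctions, junction_ref,
                   cfg) -> Tuple[int, List[Tuple[str, int]], np.ndarray]:
    """One read from haplotype coordinates [start, end).

    ``junctions`` are the haplotype coordinates of implanted-deletion
    junctions falling strictly inside the read, paired with the deletion
    lengths in ``junction_ref``.  Returns (ref_start, cigar, query_codes).
    """
    bases = hap_codes[start:end].copy()
    L = bases.size
    e_sub = cfg.error_rate * cfg.error_mix[0]
    e_ins = cfg.error_rate * cfg.error_mix[1]
    e_del = cfg.error_rate * cfg.error_mix[2]
    u = rng.random(L)
    sub_mask = u < e_sub
    del_mask = (u >= e_sub) & (u < e_sub + e_del)
    ins_mask = (u >= e_sub + e_del) & (u < e_sub + e_del + e_ins)
    bases[sub_mask] = (bases[sub_mask]
                       + rng.integers(1, 4, size=int(sub_mask.sum()))) % 4

    # column layout: each read base is one column; an insertion error adds a
    # column right after its base
    ins_before = np.concatenate([[0], np.cumsum(ins_mask)[:-1]])
    base_pos = np.arange(L) + ins_before
    total = L + int(ins_mask.sum())
    col_op = np.zeros(total, dtype=np.int8)
    col_op[base_pos[del_mask]] = 1
    ins_cols = base_pos[ins_mask] + 1
    col_op[ins_cols] = 2
    col_base = np.zeros(total, dtype=np.uint8)
    col_base[base_pos] = bases
    col_base[ins_cols] = rng.integers(0, 4, size=ins_cols.size)

    # assemble ops per implanted-deletion segment, weaving in true D ops
    cigar_codes: List[Tuple[int, int]] = []
    seg_starts = [0] + [int(j - start) for j in junctions]
    seg_ends = [int(j - start) for j in junctions] + [L]
    for si, (qa, qb) in enumerate(zip(seg_starts, seg_ends)):
        if si > 0:
            cigar_codes.append((1, int(junction_ref[si - 1])))  # true deletion
        if qa >= qb:
            continue
        ca = int(base_pos[qa])
        cb = int(base_pos[qb - 1]) + 1 + int(ins_mask[qb - 1])
        cigar_codes.extend(_rle(col_op[ca:cb]))

    # merge adjacent same-type runs created at segment boundaries
    merged: List[Tuple[int, int]] = []
    for code, ln in cigar_codes:
        if merged and merged[-1][0] == code:
            merged[-1] = (code, merged[-1][1] + ln)
        else:
            merged.append((code, ln))
    # aligners do not report deletions at read ends: trim and shift POS
    lead_del = 0
    while merged and merged[0][0] == 1:
        lead_del += merged.pop(0)[1]
    while merged and merged[-1][0] == 1:
        merged.pop()

    query = col_base[col_op != 1]
    cigar = [(_OP_CHARS[code], ln) for code, ln in merged]
    return lead_del, cigar, query


def simulate(config: SimConfig, out_dir: Optional[str] = None) -> SimResult:
    """Run the simulator; optionally write SAM/FASTA/BED/manifest files."""
    rng = np.random.default_rng(config.seed)
    ref_codes = rng.integers(0, 4, size=config.ref_length).astype(np.uint8)
    dels = _place_deletions(rng, config)
    truth = [TruthDeletion(config.chrom, a, b, config.zygosity)
             for a, b in dels]

    keep = np.ones(config.ref_length, dtype=bool)
    for a, b in dels:
        keep[a:b] = False
    alt_codes = ref_codes[keep]
    # haplotype coordinate of each junction and cumulative removed length
    del_lens = np.asarray([b - a for a, b in dels], dtype=np.int64)
    cum_before = np.concatenate([[0], np.cumsum(del_lens)[:-1]])
    alt_junctions = (np.asarray([a for a, _ in dels], dtype=np.int64)
                     - cum_before)

    # reads overhanging the contig end are truncated, which loses about
    # mean^2 / (2 * span) bases per read; inflate the read count so the
    # realised coverage stays on target
    effective_len = config.read_len_mean * max(
        0.5, 1.0 - config.read_len_mean / (2.0 * config.ref_length))
    n_reads = max(1, int(round(config.depth * config.ref_length
                               / effective_len)))
    records: List[AlignmentRecord] = []
    for i in range(n_reads):
        from_alt = (config.zygosity == "homozygous"
                    or bool(rng.random() < 0.5))
        hap = alt_codes if from_alt else ref_codes
        hap_len = hap.size
        start = int(rng.integers(0, max(1, hap_len - MIN_READ_LEN)))
        length = int(np.clip(rng.normal(config.read_len_mean,
                                        config.read_len_sd),
                             MIN_READ_LEN, 2 * config.read_len_mean))
        end = min(start + length, hap_len)

        if from_alt and len(dels):
            inside = (alt_junctions > start) & (alt_junctions < end)
            junctions = alt_junctions[inside]
            junction_lens = del_lens[inside]
        else:
            junctions = np.empty(0, dtype=np.int64)
            junction_lens = np.empty(0, dtype=np.int64)

        lead_del, cigar, query = _simulate_read(
            rng, hap, start, end, junctions, junction_lens, config)
        if not cigar:
            continue
        if from_alt:
            n_before = int(np.searchsorted(alt_junctions, start, side="right"))
            ref_start = start + int(cum_before[n_before - 1] + del_lens[n_before - 1]) \
                if n_before else start
            ref_start += lead_del
        else:
            ref_start = start + lead_del

        # optional read-end soft clips exercise the blue image channel
        if config.clip_fraction > 0 and rng.random() < config.clip_fraction:
            clip_len = int(rng.integers(20, config.max_clip + 1))
            clip = rng.integers(0, 4, size=clip_len).astype(np.uint8)
            if rng.random() < 0.5:
                cigar = [("S", clip_len)] + cigar
                query = np.concatenate([clip, query])
            else:
                cigar = cigar + [("S", clip_len)]
                query = np.concatenate([query, clip])

        records.append(AlignmentRecord(
            query_name=f"read_{i:06d}",
            flag=0,
            ref_name=config.chrom,
            pos=ref_start + 1,
            mapq=60,
            cigar=tuple(cigar),
            seq=bytes(_BASES[query]).decode(),
        ))

    records.sort(key=lambda r: (r.ref_name, r.pos, r.query_name))
    reference = bytes(_BASES[ref_codes]).decode()
    manifest = {
        "config": _jsonable(asdict(config)),
        "n_reads": len(records),
        "n_deletions": len(truth),
        "total_deleted_bp": int(del_lens.sum()) if len(dels) else 0,
    }
    result = SimResult(records, truth, reference, config, manifest)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_outputs(result: SimResult, out_dir) -> dict:
    """Write SAM, reference FASTA (+ .fai), truth BED and a JSON manifest."""
    os.makedirs(out_dir, exist_ok=True)
    cfg = result.config
    paths = {
        "sam": os.path.join(out_dir, "reads.sam"),
        "reference_fasta": os.path.join(out_dir, "reference.fa"),
        "truth_bed": os.path.join(out_dir, "truth.bed"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    write_alignments(result.records, [(cfg.chrom, cfg.ref_length)],
                     paths["sam"])
    with open(paths["reference_fasta"], "w") as fh:
        fh.write(f">{cfg.chrom}\n")
        seq = result.reference
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    pysam.faidx(paths["reference_fasta"])
    with open(paths["truth_bed"], "w") as fh:
        for t in result.truth:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\tDEL\t{t.zygosity}\n")
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    return paths
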