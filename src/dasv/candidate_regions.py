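"""From per-read CIGAR deletions to tiled candidate windows.

The caller frames "where to look" in four steps: extract every sufficiently
long D operation from each read's CIGAR, merge co-located evidence across
reads (single linkage with a gap allowance), keep clusters whose read support
is high relative to the mean sequencing depth, and tile the retained regions
into fixed 100-bp windows with a 50-bp stride for the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

from .alignment_io import AlignmentRecord

WINDOW_SIZE = 100
WINDOW_STRIDE = 50

DEFAULT_MIN_DEL_LEN = 30      # collects fragmented evidence of >=50 bp events
DEFAULT_MERGE_GAP = 50        # one stride; bridges error-fragmented D ops
DEFAULT_SUPPORT_FRACTION = 0.2
DEFAULT_REGION_PAD = 50       # breakpoints near edges land mid-window


@dataclass(frozen=True)
class DeletionEvidence:
    """A single D op from one read, 0-based half-open on the reference."""
    read_id: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class EvidenceCluster:
    """Merged deletion evidence; ``support`` counts contributing reads' D ops."""
    chrom: str
    start: int
    end: int
    members: List[DeletionEvidence] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int
    end: int
    source_cluster: EvidenceCluster = field(compare=False, hash=False)


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    width: int = WINDOW_SIZE

    @property
    def end(self) -> int:
        return self.start + self.width


def extract_evidence(record: AlignmentRecord,
                     min_del_len: int = DEFAULT_MIN_DEL_LEN
                     ) -> List[DeletionEvidence]:
    """Deletion intervals implied by the record's CIGAR D ops.

    Coordinates are found by walking reference-consuming ops from the record's
    0-based start; only D ops of at least ``min_del_len`` bp are reported.
    """
    out: List[DeletionEvidence] = []
    ref = record.ref_start
    for op, n in record.cigar:
        if n < 1 or op not in "MIDNSHP=X":
            raise ValueError(
                f"malformed CIGAR in record {record.query_name!r}: ({op},{n})")
        if op == "D":
            if n >= min_del_len:
                out.append(DeletionEvidence(record.query_name, record.ref_name,
                                            ref, ref + n))
            ref += n
        elif op in "M=XN":
            ref += n
    return out


def merge_evidence(evidences: Sequence[DeletionEvidence],
                   merge_gap: int = DEFAULT_MERGE_GAP) -> List[EvidenceCluster]:
    """Single-linkage clustering of deletion intervals on one chromosome.

    Two evidences belong to the same cluster iff their intervals overlap or
    lie within ``merge_gap`` bp of each other (transitively).  Since linkage
    is an interval relation, a sweep over start-sorted evidences computes the
    exact transitive closure; the result is independent of input order.
    """
    evs = sorted(evidences, key=lambda e: (e.start, e.end, e.read_id))
    clusters: List[EvidenceCluster] = []
    for e in evs:
        if clusters and e.start <= clusters[-1].end + merge_gap:
            c = clusters[-1]
            c.members.append(e)
            c.end = max(c.end, e.end)
        else:
            clusters.append(EvidenceCluster(e.chrom, e.start, e.end, [e]))
    return clusters


def support_threshold(avg_depth: float, min_support_fraction: float) -> int:
    """Minimum cluster support required at a given mean depth (floor of 2)."""
    return max(2, math.ceil(min_support_fraction * avg_depth))


def select_high_frequency(clusters: Iterable[EvidenceCluster],
                          avg_depth: float,
                          min_support_fraction: float = DEFAULT_SUPPORT_FRACTION
                          ) -> List[CandidateRegion]:
    """Keep clusters whose support clears the depth-scaled threshold."""
    if avg_depth <= 0:
        raise ValueError(f"avg_depth must be positive, got {avg_depth}")
    if not (0 < min_support_fraction <= 1):
        raise ValueError("min_support_fraction must be in (0, 1]")
    thr = support_threshold(avg_depth, min_support_fraction)
    return [CandidateRegion(c.chrom, c.start, c.end, c)
            for c in clusters if c.support >= thr]


def tile_region(region: CandidateRegion,
                window: int = WINDOW_SIZE,
                stride: int = WINDOW_STRIDE,
                pad: int = DEFAULT_REGION_PAD) -> List[Window]:
    """Fixed-size windows covering the region expanded by ``pad`` on each side.

    Window starts step by ``stride`` from the (clamped, padded) region start
    and continue while they fall before the padded end, so every base of the
    expanded region is covered and, with window = 2 x stride, interior bases
    are covered twice.
    """
    if window <= 0 or not (0 < stride <= window):
        raise ValueError("need window > 0 and 0 < stride <= window")
    lo = max(0, region.start - pad)
    hi = region.end + pad
    return [Window(region.chrom, s, window) for s in range(lo, hi, stride)]


def dedupe_windows(windows: Iterable[Window]) -> List[Window]:
    """Drop duplicate (chrom, start) windows, keeping genomic order."""
    seen = set()
    out = []
    for w in sorted(windows, key=lambda w: (w.chrom, w.start)):
        key = (w.chrom, w.start)
        if key not in seen:
            seen.add(key)
            out.append(w)
    return out


def regions_to_bed(regions: Iterable[CandidateRegion], path) -> None:
    """BED export (0-based half-open); support in column 5."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion\t"
                     f"{r.source_cluster.support}\n")
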