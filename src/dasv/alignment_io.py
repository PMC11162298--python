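"""Reading, writing and quality control of SAM/BAM alignments.

Long-read deletion calling starts from coordinate-sorted alignments.  This
module parses them into lightweight records, applies the caller's quality
filters (minimum mapping quality, removal of unmapped / secondary /
supplementary / duplicate alignments) and estimates mean sequencing depth,
which downstream candidate selection uses as its support scale.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, Tuple

import pysam

# SAM FLAG bits dropped by default quality control: unmapped reads carry no
# alignment evidence; secondary/supplementary placements would double-count
# a read; duplicates inflate apparent support.
FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800
DEFAULT_DROP_FLAGS = (FLAG_UNMAPPED | FLAG_SECONDARY
                      | FLAG_DUPLICATE | FLAG_SUPPLEMENTARY)

DEFAULT_MIN_MAPQ = 20

_REF_CONSUMING = frozenset("MD=XN")
_QUERY_CONSUMING = frozenset("MIS=X")

CigarOp = Tuple[str, int]


@dataclass
class AlignmentRecord:
    """One aligned read, 1-based leftmost position as in SAM."""

    query_name: str
    flag: int
    ref_name: str
    pos: int
    mapq: int
    cigar: Tuple[CigarOp, ...]
    seq: Optional[str] = None

    @property
    def ref_start(self) -> int:
        """0-based inclusive start on the reference."""
        return self.pos - 1

    @property
    def ref_span(self) -> int:
        """Number of reference bases consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    @property
    def ref_end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.ref_start + self.ref_span

    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)


_OPS = "MIDNSHP=X"


def _from_pysam(a: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = tuple((_OPS[op], int(n)) for op, n in (a.cigartuples or ()))
    return AlignmentRecord(
        query_name=a.query_name or "",
        flag=a.flag,
        ref_name=a.reference_name or "*",
        pos=(a.reference_start + 1) if a.reference_start is not None and a.reference_start >= 0 else 0,
        mapq=a.mapping_quality,
        cigar=cigar,
        seq=a.query_sequence,
    )


def load_alignments(path, region: Optional[Tuple[str, int, int]] = None
                    ) -> Iterator[AlignmentRecord]:
    """Stream records from a SAM/BAM file, optionally restricted to a region.

    ``region`` is (chrom, start, end) in 0-based half-open coordinates; using
    it requires an indexed BAM or a sorted SAM small enough to scan.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"alignment file not found: {path}")
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        if region is None:
            for a in af:
                yield _from_pysam(a)
            return
        chrom, start, end = region
        if chrom not in af.references:
            raise ValueError(f"unknown contig {chrom!r}: not in header")
        try:
            it = af.fetch(chrom, start, end)
        except ValueError:
            # no index: linear scan with an overlap test
            it = (a for a in af
                  if a.reference_name == chrom
                  and a.reference_start is not None
                  and a.reference_start < end
                  and a.reference_end is not None
                  and a.reference_end > start)
        for a in it:
            yield _from_pysam(a)


def write_alignments(records: Iterable[AlignmentRecord],
                     contigs: Sequence[Tuple[str, int]],
                     path) -> None:
    """Write records as SAM v1 with an @HD/@SQ header (sorted by coordinate)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in contigs],
    }
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.query_name
            a.flag = r.flag
            a.reference_id = out.header.get_tid(r.ref_name) if r.ref_name != "*" else -1
            a.reference_start = r.pos - 1
            a.mapping_quality = r.mapq
            a.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar) or None
            a.query_sequence = r.seq
            out.write(a)


def qc_filter(records: Iterable[AlignmentRecord],
              min_mapq: int = DEFAULT_MIN_MAPQ,
              drop_flags: int = DEFAULT_DROP_FLAGS) -> Iterator[AlignmentRecord]:
    """Drop low-quality alignments; preserves order and is idempotent.

    A record is retained iff its MAPQ is at least ``min_mapq`` and none of the
    ``drop_flags`` bits are set.
    """
    for r in records:
        if r.mapq >= min_mapq and not (r.flag & drop_flags):
            yield r


def average_depth(records: Iterable[AlignmentRecord], genome_span: int) -> float:
    """Mean coverage: total reference bases consumed divided by genome span."""
    if genome_span <= 0:
        raise ValueError(f"genome_span must be positive, got {genome_span}")
    return sum(r.ref_span for r in records) / float(genome_span)
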