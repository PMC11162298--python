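"""Per-window network inputs: sequence encoding S and images I1/I2.

Each candidate window is summarised three ways for the classifier:

* ``S`` — a length-100 integer consensus track over the window's columns.
  Deletion-majority columns are coded 9; otherwise the plurality base is
  coded A=2, C=3, T=4, G=5; uncovered columns are 0 (also the pad value).
* ``I1`` — a 100 x 100 RGB image on a white background.  Each pixel row is
  one read (top to bottom by alignment start); each column is one reference
  offset.  CIGAR ops colour the columns a read covers: M/=/X green (0,255,0),
  D red (255,0,0), soft clips blue (0,0,255) painted outward from the
  alignment ends, insertions a single black (0,0,0) column at their anchor.
* ``I2`` — the binary attention image: white exactly where I1 is red, black
  elsewhere.  It carries no independent information; it redirects the
  network's spatial attention to deletion evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .alignment_io import AlignmentRecord
from .candidate_regions import Window

CANVAS = 100
MAX_ROWS = 100

COLOR_BACKGROUND = (255, 255, 255)
COLOR_DELETION = (255, 0, 0)
COLOR_MATCH = (0, 255, 0)
COLOR_SOFTCLIP = (0, 0, 255)
COLOR_INSERTION = (0, 0, 0)

CODE_PAD = 0
CODE_A, CODE_C, CODE_T, CODE_G = 2, 3, 4, 5
CODE_DELETION = 9

_BASE_TO_CODE = np.zeros(256, dtype=np.uint8)
for _b, _c in zip("ACTG", (CODE_A, CODE_C, CODE_T, CODE_G)):
    _BASE_TO_CODE[ord(_b)] = _c
    _BASE_TO_CODE[ord(_b.lower())] = _c


class _AlignedRead:
    """A record pre-walked into reference-coordinate segments."""

    __slots__ = ("name", "ref_start", "ref_end", "match_segs", "del_segs",
                 "ins_anchors", "left_clip", "right_clip", "codes")

    def __init__(self, record: AlignmentRecord):
        self.name = record.query_name
        self.ref_start = record.ref_start
        self.match_segs = []    # (ref_lo, ref_hi, query_lo)
        self.del_segs = []      # (ref_lo, ref_hi)
        self.ins_anchors = []   # ref position of the base following the insert
        self.left_clip = 0
        self.right_clip = 0
        ref, query = record.ref_start, 0
        first = True
        for op, n in record.cigar:
            if op in "M=X":
                self.match_segs.append((ref, ref + n, query))
                ref += n
                query += n
            elif op == "D":
                self.del_segs.append((ref, ref + n))
                ref += n
            elif op == "N":
                ref += n
            elif op == "I":
                self.ins_anchors.append(ref)
                query += n
            elif op == "S":
                if first:
                    self.left_clip = n
                else:
                    self.right_clip = n
                query += n
            # H, P consume nothing drawable
            first = False
        self.ref_end = ref
        seq = record.seq or ""
        self.codes = _BASE_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)] \
            if seq else np.zeros(0, dtype=np.uint8)


def _prepare(records: Sequence[AlignmentRecord]) -> List[_AlignedRead]:
    reads = [_AlignedRead(r) for r in records]
    reads.sort(key=lambda r: (r.ref_start, r.name))
    return reads


def _overlapping(reads: Sequence[_AlignedRead], window: Window) -> List[_AlignedRead]:
    return [r for r in reads
            if r.ref_start < window.end and r.ref_end > window.start]


def _select_rows(reads: Sequence[_AlignedRead]) -> List[_AlignedRead]:
    # >100 reads are row-compressed by uniform rank subsampling, keeping the
    # visual depth structure without blending colours.
    n = len(reads)
    if n <= MAX_ROWS:
        return list(reads)
    k = int(np.ceil(n / MAX_ROWS))
    return list(reads[::k])[:MAX_ROWS]


def render_region_image(window: Window,
                        records: Sequence[AlignmentRecord],
                        _prepared: Optional[Sequence[_AlignedRead]] = None
                        ) -> np.ndarray:
    """The I1 image for one window: (100, 100, 3) uint8."""
    reads = _prepared if _prepared is not None else _prepare(records)
    rows = _select_rows(_overlapping(reads, window))
    img = np.full((MAX_ROWS, CANVAS, 3), 255, dtype=np.uint8)
    ws, we = window.start, window.end
    for row, r in enumerate(rows):
        for lo, hi, _q in r.match_segs:
            a, b = max(lo, ws), min(hi, we)
            if a < b:
                img[row, a - ws:b - ws] = COLOR_MATCH
        for lo, hi in r.del_segs:
            a, b = max(lo, ws), min(hi, we)
            if a < b:
                img[row, a - ws:b - ws] = COLOR_DELETION
        # soft clips: a blue footprint outward from each alignment end,
        # truncated to the columns available in the window
        if r.left_clip:
            a = max(r.ref_start - r.left_clip, ws)
            b = min(r.ref_start, we)
            if a < b:
                img[row, a - ws:b - ws] = COLOR_SOFTCLIP
        if r.right_clip:
            a = max(r.ref_end, ws)
            b = min(r.ref_end + r.right_clip, we)
            if a < b:
                img[row, a - ws:b - ws] = COLOR_SOFTCLIP
        for anchor in r.ins_anchors:
            if ws <= anchor < we:
                img[row, anchor - ws] = COLOR_INSERTION
    return img


def derive_attention_image(i1: np.ndarray) -> np.ndarray:
    """The I2 image: white where I1 is red, black everywhere else."""
    red = np.all(i1 == np.asarray(COLOR_DELETION, dtype=np.uint8), axis=-1)
    i2 = np.zeros_like(i1)
    i2[red] = 255
    return i2


def encode_sequence(window: Window,
                    records: Sequence[AlignmentRecord],
                    _prepared: Optional[Sequence[_AlignedRead]] = None
                    ) -> np.ndarray:
    """The S track for one window: (100,) int16 consensus codes.

    Per column, a read "covers" the position if an M/=/X or D op spans it.
    Code 9 wins when at least half the covering reads place a deletion there;
    otherwise the plurality base code is used (ties break to the lowest
    code); zero-coverage columns — including any part of the window past the
    contig end — stay 0.
    """
    reads = _prepared if _prepared is not None else _prepare(records)
    overlapping = _overlapping(reads, window)
    ws, we = window.start, window.end
    del_count = np.zeros(CANVAS, dtype=np.int32)
    base_count = np.zeros((4, CANVAS), dtype=np.int32)  # rows: A, C, T, G
    match_count = np.zeros(CANVAS, dtype=np.int32)
    code_row = {CODE_A: 0, CODE_C: 1, CODE_T: 2, CODE_G: 3}
    for r in overlapping:
        for lo, hi in r.del_segs:
            a, b = max(lo, ws), min(hi, we)
            if a < b:
                del_count[a - ws:b - ws] += 1
        for lo, hi, q in r.match_segs:
            a, b = max(lo, ws), min(hi, we)
            if a >= b:
                continue
            match_count[a - ws:b - ws] += 1
            if r.codes.size:
                codes = r.codes[q + (a - lo):q + (b - lo)]
                cols = np.arange(a - ws, b - ws)
                for code, rowi in code_row.items():
                    sel = codes == code
                    if sel.any():
                        base_count[rowi, cols[sel]] += 1
    covering = del_count + match_count
    s = np.zeros(CANVAS, dtype=np.int16)
    is_del = (covering > 0) & (2 * del_count >= covering)
    s[is_del] = CODE_DELETION
    rest = (covering > 0) & ~is_del
    best = base_count.argmax(axis=0)          # ties -> first row = lowest code
    has_base = base_count.max(axis=0) > 0
    codes_by_row = np.asarray([CODE_A, CODE_C, CODE_T, CODE_G], dtype=np.int16)
    s[rest & has_base] = codes_by_row[best[rest & has_base]]
    return s


@dataclass
class WindowSample:
    """One window's model inputs (and training label, when known)."""
    window: Window
    S: np.ndarray          # (100,) int16
    I1: np.ndarray         # (100, 100, 3) uint8
    I2: np.ndarray         # (100, 100, 3) uint8
    label: Optional[int] = None


def build_window_samples(windows: Iterable[Window],
                         records: Sequence[AlignmentRecord]
                         ) -> List[WindowSample]:
    """Encode many windows against one record set (reads walked once)."""
    reads = _prepare(records)
    starts = np.asarray([r.ref_start for r in reads], dtype=np.int64)
    ends = np.asarray([r.ref_end for r in reads], dtype=np.int64)
    out = []
    for w in windows:
        sel = np.nonzero((starts < w.end) & (ends > w.start))[0]
        sub = [reads[i] for i in sel]
        i1 = render_region_image(w, (), _prepared=sub)
        out.append(WindowSample(w, encode_sequence(w, (), _prepared=sub),
                                i1, derive_attention_image(i1)))
    return out


def save_png(image: np.ndarray, path) -> None:
    """Lossless PNG export of an I1/I2 image for inspection."""
    from PIL import Image
    Image.fromarray(image, mode="RGB").save(path, format="PNG")
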