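"""Benchmarking deletion calls against a truth set.

A call matches a truth deletion when they share a chromosome, both
breakpoints agree within a tolerance, and the reciprocal overlap (overlap
divided by the longer of the two intervals' relevant length on each side)
clears a floor — the community-standard criterion for SV comparison.
Matching is one-to-one, assigned greedily by descending overlap; precision,
recall and F1 follow the usual definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .training_and_calling import DeletionCall, TruthLike, _truth_interval

DEFAULT_BP_TOLERANCE = 500
DEFAULT_MIN_RECIPROCAL_OVERLAP = 0.5


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: List[Tuple[DeletionCall, Tuple[str, int, int]]] = field(
        default_factory=list)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1}


def _compatible(call_iv, truth_iv, bp_tolerance, min_ro):
    c_chrom, c_a, c_b = call_iv
    t_chrom, t_a, t_b = truth_iv
    if c_chrom != t_chrom:
        return None
    if abs(c_a - t_a) > bp_tolerance or abs(c_b - t_b) > bp_tolerance:
        return None
    ov = min(c_b, t_b) - max(c_a, t_a)
    if ov <= 0:
        return None
    if ov < min_ro * (c_b - c_a) or ov < min_ro * (t_b - t_a):
        return None
    return ov


def match_calls(calls: Sequence[DeletionCall],
                truth: Sequence[TruthLike],
                bp_tolerance: int = DEFAULT_BP_TOLERANCE,
                min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP
                ) -> MatchResult:
    """One-to-one greedy matching of calls to truth deletions."""
    truth_ivs = [_truth_interval(t) for t in truth]
    edges = []
    for ci, c in enumerate(calls):
        for ti, t in enumerate(truth_ivs):
            ov = _compatible((c.chrom, c.start, c.end), t,
                             bp_tolerance, min_reciprocal_overlap)
            if ov is not None:
                edges.append((ov, ci, ti))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    used_calls, used_truth = set(), set()
    pairs = []
    for _ov, ci, ti in edges:
        if ci in used_calls or ti in used_truth:
            continue
        used_calls.add(ci)
        used_truth.add(ti)
        pairs.append((calls[ci], truth_ivs[ti]))
    tp = len(pairs)
    if not calls and truth_ivs:
        warnings.warn("no calls to evaluate; precision defined as 0",
                      stacklevel=2)
    return MatchResult(tp=tp, fp=len(calls) - tp, fn=len(truth_ivs) - tp,
                       pairs=pairs)


def breakpoint_errors(result: MatchResult) -> List[int]:
    """Per-matched-pair breakpoint error: max of |start delta|, |end delta|."""
    return [max(abs(c.start - a), abs(c.end - b))
            for c, (_chrom, a, b) in result.pairs]
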