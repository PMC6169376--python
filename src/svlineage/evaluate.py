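"""Scoring called SVs against the simulator's truth table.

Planted loci are pairwise non-overlapping and kept >= 2 kb apart, so a call
can be assigned unambiguously to the nearest planted locus.  A true positive
requires the exact class; a call matching a locus with the wrong class
counts as both a false positive and a missed truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .simulate import TruthTable, TruthRecord
from .svcall import SVRecord, GAIN_TYPES, LOSS_TYPES

__all__ = ["RecoveryMetrics", "score_calls", "optical_recovery"]


@dataclass
class RecoveryMetrics:
    true_positives: int
    false_positives: int
    false_negatives: int
    per_class: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    breakpoint_errors: list[int] = field(default_factory=list)  # per matched indel

    @property
    def precision(self) -> float:
        d = self.true_positives + self.false_positives
        return self.true_positives / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.true_positives + self.false_negatives
        return self.true_positives / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def _locus_center(start: int, end: int) -> float:
    return (start + end) / 2.0


def _nearest_truth(call: SVRecord, truths: list[TruthRecord], window: int) -> TruthRecord | None:
    """Nearest planted locus on the call's chromosome whose (padded) interval
    is within ``window`` of the call, regardless of class."""
    best, best_d = None, None
    c = _locus_center(call.start, call.end)
    for t in truths:
        if t.chrom != call.chrom:
            continue
        if call.start > t.ref_end + window or call.end < t.ref_start - window:
            continue
        d = abs(c - _locus_center(t.ref_start, t.ref_end))
        if best is None or d < best_d:
            best, best_d = t, d
    return best


def score_calls(
    calls_by_line: dict[str, list[SVRecord]],
    truth: TruthTable,
    window: int = 800,
) -> RecoveryMetrics:
    """Line-by-line truth matching: each (line, planted locus) pair must be
    hit by exactly-classed call(s); unassigned or wrong-class calls are false
    positives.  Breakpoint errors (max of |start| and |end| deviation) are
    recorded for matched insertions and deletions."""
    tp = fp = fn = 0
    per_class: dict[str, list[int]] = {}
    bp_errors: list[int] = []
    for line, calls in sorted(calls_by_line.items()):
        truths = truth.for_line(line)
        hit: dict[int, bool] = {id(t): False for t in truths}
        for call in calls:
            t = _nearest_truth(call, truths, window)
            if t is not None and t.sv_type == call.sv_type:
                if not hit[id(t)]:
                    hit[id(t)] = True
                if call.sv_type in ("insertion", "deletion"):
                    bp_errors.append(
                        max(abs(call.start - t.ref_start), abs(call.end - t.ref_end))
                    )
            else:
                fp += 1
                key = call.sv_type
                per_class.setdefault(key, [0, 0, 0])[1] += 1
        for t in truths:
            cls = per_class.setdefault(t.sv_type, [0, 0, 0])
            if hit[id(t)]:
                tp += 1
                cls[0] += 1
            else:
                fn += 1
                cls[2] += 1
    return RecoveryMetrics(
        true_positives=tp, false_positives=fp, false_negatives=fn,
        per_class={k: tuple(v) for k, v in per_class.items()},
        breakpoint_errors=bp_errors,
    )


def optical_recovery(
    map_calls_by_line: dict[str, list[SVRecord]],
    truth: TruthTable,
    min_truth_size: int = 2000,
) -> tuple[float, int, int]:
    """Fraction of planted size-changing SVs >= ``min_truth_size`` detected
    by an optical call of the right sign overlapping the planted locus
    (padded by 3 kb, about one label interval beyond breakpoint smearing).

    Returns (fraction, detected, eligible).  Inversions are size-neutral and
    excluded.
    """
    pad = 3000
    detected = eligible = 0
    for line, calls in sorted(map_calls_by_line.items()):
        for t in truth.for_line(line):
            if t.signed_size == 0 or t.size_bp < min_truth_size:
                continue
            eligible += 1
            want = "insertion" if t.signed_size > 0 else "deletion"
            for c in calls:
                if (
                    c.sv_type == want
                    and c.chrom == t.chrom
                    and c.start < t.ref_end + pad
                    and t.ref_start - pad < c.end
                ):
                    detected += 1
                    break
    return (detected / eligible if eligible else 0.0), detected, eligible
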