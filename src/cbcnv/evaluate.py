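"""Benchmarking of call sets: overlap matching, sensitivity/FDR, P/R/F1, ODS.

Against a simulated truth set, a truth event counts as detected when some
call covers strictly more than half of it; a call counts as correct when it
covers more than half of some truth event.  From these:

* sensitivity = recall = detected truths / all truths;
* FDR = calls matching no truth / all calls (0 when there are no calls);
* precision = 1 - FDR; F1 = harmonic mean of precision and recall.

Sensitivity and FDR are additionally stratified by truth length level and
by event type (gain/loss).  Without a truth set, callers are compared by
the overlapping density score ODS = O_m * O_r, where O_m is a method's mean
number of events overlapping each other method's calls and O_r = O_m
divided by the method's total predicted events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvalReport",
    "overlap_match",
    "match_sets",
    "sensitivity_fdr",
    "precision_recall_f1",
    "evaluate_calls",
    "ods",
]

DEFAULT_LENGTH_LEVELS = (2_000, 6_000, 10_000, 30_000, 50_000, 100_000)


@dataclass
class EvalReport:
    """Aggregate accuracy of a call set against a truth set."""

    n_truth: int
    n_called: int
    n_tp: int
    n_fp: int
    sensitivity: float
    fdr: float
    precision: float
    recall: float
    f1: float
    per_length: dict = field(default_factory=dict)
    per_type: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_truth": self.n_truth,
            "n_called": self.n_called,
            "n_tp": self.n_tp,
            "n_fp": self.n_fp,
            "sensitivity": self.sensitivity,
            "fdr": self.fdr,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_length": {str(k): v for k, v in self.per_length.items()},
            "per_type": dict(self.per_type),
        }


def _interval(x):
    return x.chrom, int(x.start), int(x.end)


def overlap_match(call, truth) -> bool:
    """True iff the call covers strictly more than half of the truth event."""
    c_chrom, c_start, c_end = _interval(call)
    t_chrom, t_start, t_end = _interval(truth)
    if c_start >= c_end or t_start >= t_end:
        raise ValueError("zero-length interval")
    if c_chrom != t_chrom:
        return False
    ov = max(0, min(c_end, t_end) - max(c_start, t_start))
    return ov / (t_end - t_start) > 0.5


def match_sets(calls, truths):
    """Boolean match vectors: per-truth "detected", per-call "correct".

    A truth is detected if any call covers >50% of it; a call is correct
    if it covers >50% of any truth.  (Several calls may thus be credited to
    one truth; the truth still counts once.)
    """
    truth_hit = np.zeros(len(truths), dtype=bool)
    call_hit = np.zeros(len(calls), dtype=bool)
    for j, c in enumerate(calls):
        for i, t in enumerate(truths):
            if overlap_match(c, t):
                truth_hit[i] = True
                call_hit[j] = True
    return truth_hit, call_hit


def sensitivity_fdr(calls, truths):
    """(sensitivity, FDR); sensitivity is NaN without truths, FDR 0 without calls."""
    truth_hit, call_hit = match_sets(calls, truths)
    sens = float(truth_hit.sum() / len(truths)) if len(truths) else math.nan
    fdr = float((~call_hit).sum() / len(calls)) if len(calls) else 0.0
    return sens, fdr


def precision_recall_f1(calls, truths):
    """(precision, recall, F1) under the same >50%-of-truth matching."""
    truth_hit, call_hit = match_sets(calls, truths)
    precision = float(call_hit.sum() / len(calls)) if len(calls) else math.nan
    recall = float(truth_hit.sum() / len(truths)) if len(truths) else math.nan
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan if math.isnan(precision) or math.isnan(recall) else 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


def evaluate_calls(calls, truths, length_levels=DEFAULT_LENGTH_LEVELS) -> EvalReport:
    """Full accuracy report, stratified by truth length level and type."""
    truth_hit, call_hit = match_sets(calls, truths)
    n_truth, n_called = len(truths), len(calls)
    n_tp = int(truth_hit.sum())
    n_fp = int((~call_hit).sum())
    sens = n_tp / n_truth if n_truth else math.nan
    fdr = n_fp / n_called if n_called else 0.0
    precision = float(call_hit.sum() / n_called) if n_called else math.nan
    recall = sens
    if n_called and n_truth and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0 if (n_called and n_truth) else math.nan

    per_length: dict[int, dict] = {}
    if length_levels:
        lengths = np.array([t.end - t.start for t in truths])
        for level in length_levels:
            sel = np.flatnonzero(lengths == level) if n_truth else np.array([], int)
            if len(sel) == 0:
                continue
            per_length[int(level)] = {
                "n_truth": int(len(sel)),
                "sensitivity": float(truth_hit[sel].mean()),
            }

    per_type: dict[str, dict] = {}
    for typ in ("gain", "loss"):
        t_sel = [i for i, t in enumerate(truths) if getattr(t, "type", None) == typ]
        c_sel = [j for j, c in enumerate(calls) if getattr(c, "type", None) == typ]
        if not t_sel and not c_sel:
            continue
        t_hit_typ, c_hit_typ = match_sets(
            [calls[j] for j in c_sel], [truths[i] for i in t_sel]
        )
        per_type[typ] = {
            "n_truth": len(t_sel),
            "n_called": len(c_sel),
            "sensitivity": float(t_hit_typ.mean()) if len(t_sel) else math.nan,
            "fdr": float((~c_hit_typ).mean()) if len(c_sel) else 0.0,
        }

    return EvalReport(
        n_truth=n_truth, n_called=n_called, n_tp=n_tp, n_fp=n_fp,
        sensitivity=sens, fdr=fdr, precision=precision, recall=recall, f1=f1,
        per_length=per_length, per_type=per_type,
    )


def ods(noe_pairwise, npe: int):
    """Overlapping density score for truth-free caller comparison.

    ``noe_pairwise`` holds, for each other method, the number of this
    method's events overlapping that method's call set.  Then
    O_m = mean(noe_pairwise), O_r = O_m / npe, and ODS = O_m * O_r.
    Returns ``(o_m, o_r, ods)``.
    """
    if npe <= 0:
        raise ValueError("total predicted events must be positive")
    noe = np.asarray(noe_pairwise, dtype=float)
    if noe.size == 0:
        raise ValueError("need at least one pairwise overlap count")
    o_m = float(noe.mean())
    o_r = o_m / npe
    return o_m, o_r, o_m * o_r
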