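"""CNV calling from abnormal scores: Tukey's fences, gain/loss, origin.

Segments whose cluster-based abnormal score exceeds the upper Tukey fence

    T = Q3 + w * (Q3 - Q1)

are declared copy-number variants.  Adjacent flagged segments are merged
into one call; each call is typed gain or loss by comparing its mean read
depth against the bin-weighted mean depth of the non-called (normal)
segments, and a tumor call is classified germline when a matching call
(>= 50% reciprocal overlap by default) exists in the matched normal sample,
somatic otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import SegmentProfile

__all__ = [
    "FenceModel",
    "CnvCall",
    "tukey_threshold",
    "call_cnvs",
    "assign_gain_loss",
    "classify_origin",
    "calls_to_frame",
    "write_calls_bed",
    "read_calls_bed",
]


@dataclass(frozen=True)
class FenceModel:
    """Tukey's upper fence over the score distribution."""

    q1: float
    q3: float
    w: float
    T: float = field(init=False)

    def __post_init__(self) -> None:
        if self.q1 > self.q3:
            raise ValueError("q1 must not exceed q3")
        object.__setattr__(self, "T", self.q3 + self.w * (self.q3 - self.q1))


@dataclass
class CnvCall:
    """A called copy-number variant (0-based, half-open, bin-aligned)."""

    chrom: str
    start: int
    end: int
    type: str | None = None          # "gain" | "loss"
    origin: str = "NA"               # "somatic" | "germline" | "NA"
    cbas: float = float("nan")
    mean_rd: float = float("nan")
    first_segment: int = -1
    last_segment: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


def tukey_threshold(scores, w: float = 1.5) -> FenceModel:
    """Fit the upper fence T = Q3 + w * (Q3 - Q1) to the score profile.

    Quartiles use linear interpolation between order statistics.  At least
    four scores are required for the quartiles to be meaningful; with fewer
    segments, lower the bin size to obtain a longer profile.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 4:
        raise ValueError(
            "need at least 4 scores for Tukey's fences; "
            "use a smaller bin size to obtain more segments"
        )
    if w < 0:
        raise ValueError("abnormal weight w must be non-negative")
    q1, q3 = np.percentile(scores, [25.0, 75.0])
    return FenceModel(q1=float(q1), q3=float(q3), w=w)


def call_cnvs(segments: SegmentProfile, scores, fence: FenceModel,
              merge: bool = True) -> list[CnvCall]:
    """Candidate calls: segments with score strictly above the fence.

    Ties at T are treated as normal.  With ``merge=True`` runs of adjacent
    flagged segments become a single call whose score is the members'
    maximum and whose depth is their bin-weighted mean.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != segments.n_segments:
        raise ValueError("scores are not aligned to segments")
    flagged = scores > fence.T
    calls: list[CnvCall] = []
    idx = np.flatnonzero(flagged)
    if len(idx) == 0:
        return calls
    if merge:
        group_breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], group_breaks + 1])
        ends = np.concatenate([group_breaks, [len(idx) - 1]])
        groups = [(idx[a], idx[b]) for a, b in zip(starts, ends)]
    else:
        groups = [(i, i) for i in idx]
    for s0, s1 in groups:
        members = np.arange(s0, s1 + 1)
        weights = segments.n_bins[members]
        calls.append(
            CnvCall(
                chrom=segments.chrom,
                start=int(segments.start[s0]),
                end=int(segments.end[s1]),
                cbas=float(scores[members].max()),
                mean_rd=float(
                    np.sum(segments.value[members] * weights) / weights.sum()
                ),
                first_segment=int(s0),
                last_segment=int(s1),
            )
        )
    return calls


def assign_gain_loss(calls: list[CnvCall], segments: SegmentProfile,
                     scores=None, fence: FenceModel | None = None) -> list[CnvCall]:
    """Type each call by depth relative to the normal-area baseline.

    The baseline is the bin-weighted mean read depth over all segments not
    covered by any call; a call whose mean depth is greater than or equal
    to the baseline is a gain, otherwise a loss.  If every segment is
    called there is no baseline and the profile cannot be typed.
    """
    called = np.zeros(segments.n_segments, dtype=bool)
    for c in calls:
        if c.first_segment >= 0:
            called[c.first_segment : c.last_segment + 1] = True
    if scores is not None and fence is not None:
        # also exclude raw flagged segments (e.g. when calls were not merged)
        called |= np.asarray(scores, dtype=float) > fence.T
    if called.all():
        raise ValueError("every segment is called; no normal baseline exists")
    weights = segments.n_bins[~called]
    baseline = float(np.sum(segments.value[~called] * weights) / weights.sum())
    for c in calls:
        c.type = "gain" if c.mean_rd >= baseline else "loss"
    return calls


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def classify_origin(tumor_calls: list[CnvCall], normal_calls: list[CnvCall],
                    min_reciprocal: float = 0.5) -> list[CnvCall]:
    """Annotate tumor calls as germline or somatic.

    A tumor call sharing at least ``min_reciprocal`` reciprocal overlap
    (of both intervals) with any call in the matched normal sample is
    germline — the variant exists in both samples; all other tumor calls
    are somatic.
    """
    for tc in tumor_calls:
        tc.origin = "somatic"
        for nc in normal_calls:
            if nc.chrom != tc.chrom:
                continue
            ov = _overlap(tc.start, tc.end, nc.start, nc.end)
            if ov >= min_reciprocal * tc.length and ov >= min_reciprocal * nc.length:
                tc.origin = "germline"
                break
    return tumor_calls


# ---------------------------------------------------------------------------
# I/O


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "type": [c.type for c in calls],
            "score": [c.cbas for c in calls],
            "origin": [c.origin for c in calls],
        }
    )


def write_calls_bed(calls: list[CnvCall], path) -> None:
    """BED6-like TSV: chrom, start, end, type, score, origin."""
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, header=False,
                                 float_format="%.6g")


def read_calls_bed(path) -> list[CnvCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            typ = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else None
            score = float(parts[4]) if len(parts) > 4 else float("nan")
            origin = parts[5] if len(parts) > 5 else "NA"
            calls.append(CnvCall(chrom=chrom, start=start, end=end, type=typ,
                                 origin=origin, cbas=score))
    return calls
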