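"""Two-dimensional feature transform of the segment profile.

Each read-depth segment i becomes a point (CN_i, RDSD_i):

* CN_i = 2 * RDS_i / RDS_m — the copy-number estimate implied by depth
  proportionality (RDS_m is the profile mean, 2 the diploid reference);
* RDSD_i — the mean absolute difference between the segment's depth ratio
  RDSR_i = RDS_i / RDS_m and the ratios of its L left/right neighbours,
  a local-roughness feature with five explicit boundary cases.

CN gives the global (vertical) view of copy-number state; RDSD the local
(horizontal) view of how much a segment stands out from its neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import SegmentProfile

__all__ = [
    "FeatureMatrix",
    "compute_cn",
    "compute_rdsr",
    "compute_rdsd",
    "build_feature_matrix",
]

CN_NORM = 2.0


@dataclass
class FeatureMatrix:
    """Per-segment (CN, RDSD) points, in segment order."""

    cn: np.ndarray
    rdsd: np.ndarray
    L: int

    def __post_init__(self) -> None:
        if len(self.cn) != len(self.rdsd):
            raise ValueError("cn and rdsd must have equal length")

    @property
    def n_segments(self) -> int:
        return len(self.cn)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of feature points, the object set handed to clustering."""
        return np.column_stack([self.cn, self.rdsd])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"segment_index": np.arange(self.n_segments), "cn": self.cn, "rdsd": self.rdsd}
        )


def _mean_value(segments, weighting: str) -> float:
    if isinstance(segments, SegmentProfile):
        return segments.mean_value(weighting)
    values = np.asarray(segments, dtype=float)
    return float(values.mean())


def _values(segments) -> np.ndarray:
    if isinstance(segments, SegmentProfile):
        return np.asarray(segments.value, dtype=float)
    return np.asarray(segments, dtype=float)


def compute_cn(segments, weighting: str = "bin") -> np.ndarray:
    """Copy-number estimates CN_i = 2 * RDS_i / RDS_m."""
    values = _values(segments)
    rds_m = _mean_value(segments, weighting)
    if rds_m <= 0:
        raise ValueError("mean segment depth must be positive")
    return CN_NORM * values / rds_m


def compute_rdsr(segments, weighting: str = "bin") -> np.ndarray:
    """Depth ratios RDSR_i = RDS_i / RDS_m (so CN = 2 * RDSR)."""
    values = _values(segments)
    rds_m = _mean_value(segments, weighting)
    if rds_m <= 0:
        raise ValueError("mean segment depth must be positive")
    return values / rds_m


def compute_rdsd(rdsr: np.ndarray, L: int = 10, allow_any_L: bool = False) -> np.ndarray:
    """Neighbourhood mean-absolute-difference feature, five boundary cases.

    With n = len(rdsr) and 1-based index i (L in [5, 20] unless
    ``allow_any_L``):

    * i = 1:              mean over the L right neighbours j = 2..1+L;
    * 1 < i <= L:         sum over j = 1..i+L (self term is zero),
                          denominator i-1+L;
    * L < i <= n-L:       sum over j = i-L..i+L, denominator 2L;
    * n-L < i <= n-1:     sum over j = i-L..n-1 (note: excludes the last
                          element), denominator L+n-i-1;
    * i = n:              mean over the L left neighbours j = i-L..i-1.

    Cases are applied in the order listed (first match wins).  For profiles
    too short for a full window the ranges are clipped to valid indices and
    the denominator is the count of actual non-self terms.
    """
    rdsr = np.asarray(rdsr, dtype=float)
    n = len(rdsr)
    if n < 2:
        raise ValueError("need at least two segments for the RDSD feature")
    if not allow_any_L and not (5 <= L <= 20):
        raise ValueError("L must be in [5, 20] (pass allow_any_L=True to override)")
    if L < 1:
        raise ValueError("L must be a positive integer")

    out = np.empty(n)
    for t in range(n):  # t = i - 1
        i = t + 1
        if i == 1:
            lo, hi = 2, 1 + L                    # 1-based, inclusive
        elif i <= L:
            lo, hi = 1, i + L
        elif i <= n - L:
            lo, hi = i - L, i + L
        elif i <= n - 1:
            lo, hi = i - L, n - 1
        else:  # i == n
            lo, hi = i - L, i - 1
        lo = max(lo, 1)
        hi = min(hi, n)
        idx = np.arange(lo - 1, hi)              # back to 0-based
        denom = len(idx) - (1 if lo <= i <= hi else 0)
        if denom <= 0:
            out[t] = 0.0
            continue
        out[t] = np.sum(np.abs(rdsr[t] - rdsr[idx])) / denom
    return out


def build_feature_matrix(
    segments, L: int = 10, weighting: str = "bin", allow_any_L: bool = False
) -> FeatureMatrix:
    """Compose CN and RDSD into the 2-D feature set handed to clustering."""
    cn = compute_cn(segments, weighting)
    rdsr = compute_rdsr(segments, weighting)
    rdsd = compute_rdsd(rdsr, L=L, allow_any_L=allow_any_L)
    return FeatureMatrix(cn=cn, rdsd=rdsd, L=L)
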