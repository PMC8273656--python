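"""End-to-end orchestration: count tables in, typed and classified calls out.

Each sample is processed independently (GC correction, fused-lasso
segmentation, 2-D features, cluster-based scoring, Tukey's fences calling);
the tumor's calls are then classified somatic/germline by reciprocal
overlap against the matched normal's calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import caller as _caller
from . import features as _features
from . import preprocess as _pre
from . import scoring as _scoring
from .caller import CnvCall, FenceModel
from .features import FeatureMatrix
from .preprocess import BinProfile, SegmentProfile
from .scoring import ClusterScoreModel

__all__ = ["CallerParams", "SampleResult", "PairResult", "process_sample",
           "call_pair"]


@dataclass(frozen=True)
class CallerParams:
    """Tunable parameters of the caller with their defaults."""

    bin_size: int = 2000
    L: int = 10                 # RDSD neighbour half-width
    k: int = 5                  # k-means cluster count
    x: float = 0.9              # large-cluster mass ratio
    y: float = 5.0              # large/small size-gap multiple
    w: float = 1.5              # Tukey abnormal weight
    lam: float | None = None    # fused-lasso penalty (None -> data-driven)
    seed: int = 0
    merge: bool = True
    weighting: str = "bin"      # RDS_m convention: "bin" or "segment"


@dataclass
class SampleResult:
    """All intermediate artifacts of one sample's pass through the caller."""

    profile: BinProfile
    segments: SegmentProfile
    features: FeatureMatrix
    model: ClusterScoreModel
    fence: FenceModel
    calls: list = field(default_factory=list)


@dataclass
class PairResult:
    tumor: SampleResult
    normal: SampleResult

    @property
    def tumor_calls(self) -> list:
        return self.tumor.calls

    @property
    def normal_calls(self) -> list:
        return self.normal.calls


def process_sample(profile: BinProfile, params: CallerParams = CallerParams()) -> SampleResult:
    """Run one sample through correction, segmentation, scoring and calling."""
    corrected = _pre.gc_correct(profile)
    segments = _pre.denoise_and_segment(corrected, lam=params.lam)
    feats = _features.build_feature_matrix(segments, L=params.L,
                                           weighting=params.weighting)
    model = _scoring.score_segments(feats, k=params.k, x=params.x, y=params.y,
                                    seed=params.seed)
    fence = _caller.tukey_threshold(model.scores, w=params.w)
    calls = _caller.call_cnvs(segments, model.scores, fence, merge=params.merge)
    if calls:
        _caller.assign_gain_loss(calls, segments, model.scores, fence)
    return SampleResult(profile=corrected, segments=segments, features=feats,
                        model=model, fence=fence, calls=calls)


def call_pair(tumor: BinProfile, normal: BinProfile,
              params: CallerParams = CallerParams()) -> PairResult:
    """Process a matched pair and classify tumor calls somatic/germline."""
    t_res = process_sample(tumor, params)
    n_res = process_sample(normal, params)
    _caller.classify_origin(t_res.calls, n_res.calls)
    return PairResult(tumor=t_res, normal=n_res)
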