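"""Tukey's fences thresholding, call merging, typing and origin."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbcnv.caller import (CnvCall, FenceModel, assign_gain_loss, call_cnvs,
                          classify_origin, read_calls_bed, tukey_threshold,
                          write_calls_bed)
from conftest import make_segments


class TestTukeyThreshold:
    def test_direct_substitution(self):
        fence = FenceModel(q1=1.0, q3=3.0, w=1.5)
        assert fence.T == pytest.approx(6.0)

    def test_identical_scores_give_degenerate_fence(self):
        fence = tukey_threshold(np.full(10, 2.5), w=1.5)
        assert fence.T == pytest.approx(2.5)
        seg = make_segments(np.full(10, 5.0))
        assert call_cnvs(seg, np.full(10, 2.5), fence) == []

    def test_linear_interpolation_convention(self):
        # scores 1..8: Q1 = 2.75, Q3 = 6.25 (linear interpolation), T = 11.5
        fence = tukey_threshold(np.arange(1.0, 9.0), w=1.5)
        assert fence.q1 == pytest.approx(2.75)
        assert fence.q3 == pytest.approx(6.25)
        assert fence.T == pytest.approx(6.25 + 1.5 * 3.5)

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match="bin size"):
            tukey_threshold([1.0, 2.0, 3.0])

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            tukey_threshold(np.arange(10.0), w=-1.0)


class TestCallCnvs:
    def fence(self, t):
        return FenceModel(q1=0.0, q3=t, w=0.0)

    def test_no_scores_above_threshold_no_calls(self):
        seg = make_segments([5, 5, 5, 5.0])
        assert call_cnvs(seg, [0.1, 0.2, 0.1, 0.3], self.fence(1.0)) == []

    def test_tie_at_threshold_not_called(self):
        seg = make_segments([5, 5, 5, 5.0])
        assert call_cnvs(seg, [0.5, 1.0, 0.2, 0.1], self.fence(1.0)) == []

    def test_single_flagged_segment(self):
        seg = make_segments([5, 9, 5, 5.0])
        calls = call_cnvs(seg, [0.1, 2.0, 0.1, 0.1], self.fence(1.0))
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (2000, 4000)
        assert calls[0].cbas == pytest.approx(2.0)

    def test_adjacent_flagged_segments_merge(self):
        seg = make_segments([5, 9, 9, 9, 5.0], [1, 2, 1, 3, 1])
        calls = call_cnvs(seg, [0.1, 2.0, 3.0, 1.5, 0.1], self.fence(1.0))
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (2000, 14_000)
        assert calls[0].cbas == pytest.approx(3.0)  # max of members
        assert calls[0].mean_rd == pytest.approx(9.0)

    def test_no_merge_keeps_segment_calls(self):
        seg = make_segments([5, 9, 9, 5.0])
        calls = call_cnvs(seg, [0.1, 2.0, 3.0, 0.1], self.fence(1.0), merge=False)
        assert len(calls) == 2

    def test_merging_never_changes_member_segments(self, rng):
        seg = make_segments(rng.uniform(1, 10, 50))
        scores = rng.uniform(0, 2, 50)
        fence = self.fence(1.0)
        merged = call_cnvs(seg, scores, fence, merge=True)
        unmerged = call_cnvs(seg, scores, fence, merge=False)
        members_merged = {
            i for c in merged for i in range(c.first_segment, c.last_segment + 1)
        }
        assert members_merged == {c.first_segment for c in unmerged}
        assert members_merged == set(np.flatnonzero(scores > fence.T))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_called_segment_count_non_increasing_in_w(self, seed):
        # T is non-decreasing in w, so the set of called segments shrinks.
        # (Merged intervals can split when a middle segment drops out, so the
        # monotone quantity is segment membership, i.e. unmerged calls.)
        r = np.random.default_rng(seed)
        scores = r.exponential(1.0, 30)
        seg = make_segments(r.uniform(1, 10, 30))
        counts = [
            len(call_cnvs(seg, scores, tukey_threshold(scores, w), merge=False))
            for w in (0.0, 0.5, 1.0, 1.5, 2.0, 3.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestAssignGainLoss:
    def test_baseline_is_mean_of_uncalled_segments(self):
        seg = make_segments([4, 6, 20, 5, 5.0])
        calls = call_cnvs(seg, [0, 0, 9, 0, 0.0], FenceModel(0, 1, 0.0))
        assign_gain_loss(calls, seg)
        assert calls[0].type == "gain"
        # baseline = hand-computed bin-weighted mean of the other four
        assert (4 + 6 + 5 + 5) / 4 == pytest.approx(5.0)

    def test_tie_with_baseline_is_gain(self):
        seg = make_segments([5, 5, 5, 5.0])
        call = CnvCall("chr21", 2000, 4000, mean_rd=5.0, first_segment=1,
                       last_segment=1)
        assign_gain_loss([call], seg)
        assert call.type == "gain"

    def test_zero_depth_call_is_loss(self):
        seg = make_segments([5, 0, 5, 5.0])
        call = CnvCall("chr21", 2000, 4000, mean_rd=0.0, first_segment=1,
                       last_segment=1)
        assign_gain_loss([call], seg)
        assert call.type == "loss"

    def test_whole_profile_called_rejected(self):
        seg = make_segments([5, 9.0])
        calls = [CnvCall("chr21", 0, 4000, mean_rd=7.0, first_segment=0,
                         last_segment=1)]
        with pytest.raises(ValueError, match="baseline"):
            assign_gain_loss(calls, seg)


class TestClassifyOrigin:
    def test_identical_call_in_both_samples_is_germline(self):
        t = [CnvCall("chr21", 1000, 5000)]
        n = [CnvCall("chr21", 1000, 5000)]
        assert classify_origin(t, n)[0].origin == "germline"

    def test_unmatched_tumor_call_is_somatic(self):
        t = [CnvCall("chr21", 1000, 5000)]
        assert classify_origin(t, [])[0].origin == "somatic"

    def test_forty_percent_reciprocal_overlap_is_somatic(self):
        # overlap 4000/10000 = 40% of either interval
        t = [CnvCall("chr21", 0, 10_000)]
        n = [CnvCall("chr21", 6000, 16_000)]
        assert classify_origin(t, n)[0].origin == "somatic"

    def test_reciprocal_requires_both_directions(self):
        # normal call covers the tumor call fully, but the tumor call is
        # only 10% of the normal call
        t = [CnvCall("chr21", 0, 1000)]
        n = [CnvCall("chr21", 0, 10_000)]
        assert classify_origin(t, n)[0].origin == "somatic"

    def test_different_chromosome_never_matches(self):
        t = [CnvCall("chr21", 0, 1000)]
        n = [CnvCall("chr22", 0, 1000)]
        assert classify_origin(t, n)[0].origin == "somatic"


def test_calls_bed_round_trip(tmp_path):
    calls = [
        CnvCall("chr21", 0, 4000, type="gain", origin="somatic", cbas=1.25),
        CnvCall("chr21", 10_000, 12_000, type="loss", origin="germline", cbas=0.5),
    ]
    path = tmp_path / "calls.bed"
    write_calls_bed(calls, path)
    back = read_calls_bed(path)
    assert [(c.chrom, c.start, c.end, c.type, c.origin) for c in back] == [
        (c.chrom, c.start, c.end, c.type, c.origin) for c in calls
    ]
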