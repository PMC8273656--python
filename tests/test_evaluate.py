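"""Overlap matching and the accuracy/concordance metrics."""

import math

import numpy as np
import pytest

from cbcnv.caller import CnvCall
from cbcnv.evaluate import (evaluate_calls, ods, overlap_match,
                            precision_recall_f1, sensitivity_fdr)
from cbcnv.simulate import TruthRegion


def iv(start, end, chrom="chr21"):
    return CnvCall(chrom, start, end)


class _RawInterval:
    """Interval without constructor validation, for degenerate-input tests."""

    def __init__(self, chrom, start, end):
        self.chrom, self.start, self.end = chrom, start, end


def overlap_fraction_oracle(call, truth):
    """Per-base membership counting."""
    truth_bases = set(range(truth.start, truth.end))
    call_bases = set(range(call.start, call.end))
    if call.chrom != truth.chrom:
        return 0.0
    return len(truth_bases & call_bases) / len(truth_bases)


class TestOverlapMatch:
    def test_identical_intervals_match(self):
        t = TruthRegion("chr21", 0, 1000, 3)
        assert overlap_match(iv(0, 1000), t)

    def test_exactly_half_is_not_a_match(self):
        t = TruthRegion("chr21", 0, 1000, 3)
        assert not overlap_match(iv(0, 500), t)
        assert overlap_match(iv(0, 501), t)

    def test_zero_length_rejected(self):
        t = TruthRegion("chr21", 0, 1000, 3)
        with pytest.raises(ValueError):
            overlap_match(_RawInterval("chr21", 5, 5), t)

    def test_different_chromosomes_never_match(self):
        t = TruthRegion("chr22", 0, 1000, 3)
        assert not overlap_match(iv(0, 1000), t)

    def test_agrees_with_per_base_oracle(self, rng):
        for _ in range(100):
            c = sorted(rng.integers(0, 500, 2))
            t = sorted(rng.integers(0, 500, 2))
            if c[0] == c[1] or t[0] == t[1]:
                continue
            call = iv(int(c[0]), int(c[1]))
            truth = TruthRegion("chr21", int(t[0]), int(t[1]), 3)
            assert overlap_match(call, truth) == \
                (overlap_fraction_oracle(call, truth) > 0.5)


class TestSensitivityFdr:
    def test_perfect_calling(self):
        truths = [TruthRegion("chr21", i * 10_000, i * 10_000 + 5000, 3)
                  for i in range(4)]
        calls = [iv(t.start, t.end) for t in truths]
        assert sensitivity_fdr(calls, truths) == (1.0, 0.0)

    def test_zero_calls(self):
        truths = [TruthRegion("chr21", 0, 5000, 3)]
        assert sensitivity_fdr([], truths) == (0.0, 0.0)

    def test_zero_truths_sensitivity_na(self):
        sens, fdr = sensitivity_fdr([iv(0, 100)], [])
        assert math.isnan(sens)
        assert fdr == 1.0

    def test_hand_counted_toy_sets(self):
        # 22 truths, 20 matched; 30 calls of which 25 match some truth
        truths = [TruthRegion("chr21", i * 100_000, i * 100_000 + 10_000, 3)
                  for i in range(22)]
        calls = []
        for i in range(20):          # 20 truths matched...
            calls.append(iv(truths[i].start, truths[i].end))
        for i in range(5):           # ...5 extra calls matching truth 0
            calls.append(iv(truths[0].start, truths[0].end))
        for i in range(5):           # 5 calls matching nothing
            calls.append(iv(5_000_000 + i * 20_000, 5_000_000 + i * 20_000 + 1000))
        sens, fdr = sensitivity_fdr(calls, truths)
        assert sens == pytest.approx(20 / 22)
        assert fdr == pytest.approx(5 / 30)

    def test_order_independence(self, rng):
        truths = [TruthRegion("chr21", int(s), int(s) + 4000, 3)
                  for s in range(0, 200_000, 20_000)]
        calls = [iv(int(s) + 1000, int(s) + 6000) for s in range(0, 160_000, 20_000)]
        base = sensitivity_fdr(calls, truths)
        perm = list(rng.permutation(len(calls)))
        assert sensitivity_fdr([calls[i] for i in perm], truths) == base


class TestPrecisionRecallF1:
    def test_perfect(self):
        truths = [TruthRegion("chr21", 0, 5000, 3)]
        assert precision_recall_f1([iv(0, 5000)], truths) == (1.0, 1.0, 1.0)

    def test_harmonic_mean_of_equal_values(self):
        truths = [TruthRegion("chr21", 0, 5000, 3),
                  TruthRegion("chr21", 50_000, 55_000, 3)]
        calls = [iv(0, 5000), iv(500_000, 505_000)]
        p, r, f1 = precision_recall_f1(calls, truths)
        assert (p, r) == (0.5, 0.5)
        assert f1 == pytest.approx(0.5)

    def test_closed_form_f1(self):
        # precision 0.8, recall 0.5 -> F1 = 8/13
        truths = [TruthRegion("chr21", i * 100_000, i * 100_000 + 10_000, 3)
                  for i in range(10)]
        calls = [iv(truths[i].start, truths[i].end) for i in range(5)] + \
                [iv(truths[0].start, truths[0].end) for _ in range(3)] + \
                [iv(5_000_000, 5_010_000), iv(6_000_000, 6_010_000)]
        p, r, f1 = precision_recall_f1(calls, truths)
        assert p == pytest.approx(0.8)
        assert r == pytest.approx(0.5)
        assert f1 == pytest.approx(8 / 13)

    def test_sensitivity_equals_recall_on_random_instances(self, rng):
        for _ in range(20):
            truths = [TruthRegion("chr21", int(s), int(s + rng.integers(1000, 9000)), 3)
                      for s in rng.integers(0, 1_000_000, 8) * 10]
            calls = [iv(int(s), int(s + rng.integers(1000, 90_000)))
                     for s in rng.integers(0, 10_000_000, 12)]
            sens, _ = sensitivity_fdr(calls, truths)
            _, recall, _ = precision_recall_f1(calls, truths)
            assert sens == recall


class TestEvaluateCalls:
    def test_per_length_and_per_type_breakdown(self):
        truths = [
            TruthRegion("chr21", 0, 2000, 3),            # 2 kb gain, missed
            TruthRegion("chr21", 100_000, 200_000, 0),   # 100 kb loss, hit
        ]
        calls = [CnvCall("chr21", 100_000, 200_000, type="loss")]
        rep = evaluate_calls(calls, truths)
        assert rep.n_tp == 1 and rep.n_fp == 0
        assert rep.per_length[2000]["sensitivity"] == 0.0
        assert rep.per_length[100_000]["sensitivity"] == 1.0
        assert rep.per_type["loss"]["sensitivity"] == 1.0
        assert rep.per_type["gain"]["sensitivity"] == 0.0

    def test_report_serializes(self):
        rep = evaluate_calls([], [TruthRegion("chr21", 0, 2000, 3)])
        d = rep.to_dict()
        assert d["n_truth"] == 1 and d["n_called"] == 0


class TestOds:
    def test_direct_substitution(self):
        o_m, o_r, score = ods([10, 10], npe=20)
        assert (o_m, o_r, score) == (10.0, 0.5, 5.0)

    def test_zero_overlap_zero_score(self):
        assert ods([0, 0, 0], npe=7)[2] == 0.0

    def test_published_style_counts(self):
        # O_m = 80, NPE = 510 -> ODS = 80^2 / 510
        _, _, score = ods([80], npe=510)
        assert score == pytest.approx(80 ** 2 / 510)

    def test_scale_consistency(self):
        _, _, a = ods([40, 60], npe=200)
        _, _, b = ods([80, 120], npe=400)
        assert b == pytest.approx(2 * a)

    def test_zero_predictions_rejected(self):
        with pytest.raises(ValueError):
            ods([5], npe=0)
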