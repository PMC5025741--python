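"""Concordance statistics: RMSD, Pearson r, confusion metrics,
allele-count difference bins and marker accounting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from poolmaf import (
    ConfusionMatrix,
    allele_count_difference,
    concordance_report,
    confusion_matrix,
    marker_qc_accounting,
    pearson_r,
    performance_metrics,
    rmsd,
    validation_rate,
)
from poolmaf.evaluate import percentage


class TestRmsd:
    def test_identical_vectors(self):
        assert rmsd([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 0.0

    def test_hand_arithmetic(self):
        assert rmsd([0.10, 0.20], [0.14, 0.18]) == pytest.approx(
            np.sqrt((0.0016 + 0.0004) / 2)
        )

    def test_single_pair(self):
        assert rmsd([0.0], [0.5]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmsd([], [])

    @given(st.lists(st.tuples(st.floats(0, 0.5), st.floats(0, 0.5)),
                    min_size=2, max_size=20))
    def test_reorder_invariance_and_scaling(self, pairs):
        v = np.array([p[0] for p in pairs])
        e = np.array([p[1] for p in pairs])
        base = rmsd(v, e)
        perm = np.random.default_rng(0).permutation(len(v))
        assert rmsd(v[perm], e[perm]) == pytest.approx(base)
        assert rmsd(2 * v, 2 * e) == pytest.approx(2 * base, abs=1e-12)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(5.0)
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(5.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_textbook_value(self):
        assert pearson_r([0, 1, 2, 3], [1, 1, 3, 3]) == pytest.approx(0.8944, abs=1e-4)

    def test_constant_margin_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_affine_invariance(self):
        x = np.array([0.1, 0.4, 0.2, 0.35])
        y = np.array([0.12, 0.38, 0.25, 0.3])
        assert pearson_r(3 * x + 1, y) == pytest.approx(pearson_r(x, y))


class TestConfusionMatrix:
    def test_all_polymorphic(self):
        calls = {i: True for i in range(10)}
        cm = confusion_matrix(calls, calls)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 0, 0, 0)

    def test_toy_panel_counts(self):
        truth = {i: i < 10 for i in range(20)}  # 10 polymorphic, 10 monomorphic
        calls = dict(truth)
        calls[9] = False          # FN
        calls[10] = calls[11] = True  # 2 FP
        cm = confusion_matrix(calls, truth)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (9, 8, 2, 1)

    def test_disjoint_universes_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            confusion_matrix({1: True}, {2: True})

    def test_outer_sites_dropped(self, caplog):
        cm = confusion_matrix({1: True, 2: False}, {1: True, 3: True})
        assert cm.total == 1


class TestPerformanceMetrics:
    def test_hand_arithmetic(self):
        m = performance_metrics(ConfusionMatrix(tp=9, tn=8, fp=2, fn=1))
        assert m == {
            "sensitivity": 90.0,
            "specificity": 80.0,
            "precision": 81.82,
            "npv": 88.89,
            "accuracy": 85.0,
        }

    def test_perfect_classifier(self):
        m = performance_metrics(ConfusionMatrix(tp=5, tn=7, fp=0, fn=0))
        assert all(v == 100.0 for v in m.values())

    def test_zero_denominator_reported_as_nan(self):
        m = performance_metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
        assert np.isnan(m["sensitivity"])
        assert np.isnan(m["precision"])
        assert m["specificity"] == 100.0

    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_identities_on_random_matrices(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0 or tp + fn == 0 or tn + fp == 0:
            return
        m = performance_metrics(ConfusionMatrix(tp, tn, fp, fn), decimals=10)
        # sensitivity + miss rate = 100%
        assert m["sensitivity"] + 100.0 * fn / (tp + fn) == pytest.approx(100.0)
        # accuracy is the truth-class-weighted mean of sensitivity/specificity
        n_pos, n_neg = tp + fn, tn + fp
        weighted = (m["sensitivity"] * n_pos + m["specificity"] * n_neg) / (n_pos + n_neg)
        assert m["accuracy"] == pytest.approx(weighted)


class TestAlleleCountDifference:
    def test_identical_counts(self):
        res = allele_count_difference([1, 2, 3], [1, 2, 3], ploidy=20)
        assert res.bin_fractions["0"] == 1.0
        assert res.concordance_all == 1.0

    def test_direct_counting(self):
        seq = [2, 3, 4, 1, 0, 5]
        truth = [2, 3, 3, 0, 1, 3]  # diffs 0,0,1,1,1,2
        res = allele_count_difference(seq, truth, ploidy=20)
        assert res.bin_fractions == pytest.approx(
            {"0": 2 / 6, "1": 3 / 6, "2": 1 / 6, "3+": 0.0}
        )

    def test_monomorphic_in_both_excluded(self):
        res = allele_count_difference([0, 0, 2], [0, 0, 2], ploidy=20)
        assert res.n_polymorphic == 1
        assert res.n_total == 3
        assert res.bin_counts["0"] == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            allele_count_difference([25], [1], ploidy=20)

    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(0, 20)),
                    min_size=1, max_size=50))
    def test_fractions_sum_to_one(self, pairs):
        seq = [p[0] for p in pairs]
        truth = [p[1] for p in pairs]
        res = allele_count_difference(seq, truth, ploidy=20)
        if res.n_polymorphic:
            assert sum(res.bin_fractions.values()) == pytest.approx(1.0)


class TestMarkerAccounting:
    def test_per_pool_remaining(self):
        res = marker_qc_accounting(166_813, [1_945, 1_972], [100_415, 97_747])
        assert res["remaining_per_pool"] == [164_868, 164_841]
        assert res["monomorphic_universe"] == 198_162
        assert res["polymorphic_universe"] == 164_868 + 164_841 - 198_162

    def test_negative_remaining_rejected(self):
        with pytest.raises(ValueError):
            marker_qc_accounting(100, [200], [0])


class TestValidationRate:
    def test_two_study_pooling(self):
        assert validation_rate([43, 47], [1, 3]) == 95.6

    def test_no_monomorphic(self):
        assert validation_rate([10], [0]) == 100.0

    def test_all_monomorphic(self):
        assert validation_rate([10], [10]) == 0.0

    def test_zero_assayed_rejected(self):
        with pytest.raises(ValueError):
            validation_rate([0], [0])


class TestReportBundle:
    def test_percentage_helper(self):
        assert percentage(74_098, 79_677, 1) == 93.0

    def test_concordance_report_fields(self):
        v = [0.1, 0.2, 0.3, 0.05]
        e = [0.12, 0.18, 0.33, 0.05]
        bins = allele_count_difference([1, 2], [1, 3], ploidy=20)
        rep = concordance_report(v, e, bins=bins)
        assert rep["n_pairs"] == 4
        assert rep["rmsd"] == pytest.approx(rmsd(v, e))
        assert rep["allele_count_difference"]["n_polymorphic_pairs"] == 2
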