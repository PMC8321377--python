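import numpy as np
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

from oracles import wilcoxon_exact_oracle
from skinpost.evaluation import (PixelCounts, confusion_counts, grouped_eval,
                                 macro_f1, pooled_f1, pooled_precision_recall,
                                 report_table, signed_rank_test)


class TestConfusionCounts:
    def test_perfect_agreement(self):
        truth = np.zeros((10, 10), bool)
        truth[:1, :] = True
        c = confusion_counts(truth, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (10, 0, 0, 90)

    def test_empty_prediction(self):
        truth = np.zeros((5, 5), bool)
        truth[0, :] = True
        c = confusion_counts(np.zeros((5, 5), bool), truth)
        assert c.fn == 5 and c.tp == 0

    def test_counts_sum_to_total(self, rng):
        pred = rng.random((12, 12)) < 0.5
        truth = rng.random((12, 12)) < 0.5
        assert confusion_counts(pred, truth).total == 144

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2), bool), np.zeros((2, 3), bool))


class TestPooledF1:
    def test_direct_formula(self):
        assert pooled_f1(PixelCounts(2, 1, 1, 0)) == pytest.approx(2 * 2 / 6)

    def test_identical_masks_score_one(self):
        assert pooled_f1(PixelCounts(10, 0, 0, 90)) == 1.0

    def test_pooling_differs_from_macro_average(self):
        counts = [PixelCounts(1, 0, 1, 10), PixelCounts(3, 2, 0, 10)]
        assert pooled_f1(counts) == pytest.approx(8 / 11)
        per_image = [2 / 3, 6 / 8]
        assert macro_f1(counts) == pytest.approx(np.mean(per_image))
        assert pooled_f1(counts) != pytest.approx(macro_f1(counts))

    def test_partition_invariance(self, rng):
        """Only the pooled sums matter, not how pixels split into images."""
        tp, fp, fn, tn = 40, 7, 13, 140
        whole = pooled_f1(PixelCounts(tp, fp, fn, tn))
        for _ in range(10):
            k = int(rng.integers(2, 6))
            parts = []
            rem = [tp, fp, fn, tn]
            for i in range(k - 1):
                take = [int(rng.integers(0, r + 1)) for r in rem]
                parts.append(PixelCounts(*take))
                rem = [r - t for r, t in zip(rem, take)]
            parts.append(PixelCounts(*rem))
            assert pooled_f1(parts) == pytest.approx(whole)

    def test_all_negative_defined_as_one(self):
        assert pooled_f1(PixelCounts(0, 0, 0, 100)) == 1.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pooled_f1([])

    def test_precision_recall(self):
        p, r = pooled_precision_recall(PixelCounts(6, 2, 3, 0))
        assert p == pytest.approx(6 / 8) and r == pytest.approx(6 / 9)


class TestReportTable:
    def test_single_dataset_avg_is_value(self):
        table = report_table({"m": {"d1": 0.75}})
        assert table.loc["m", "Avg"] == pytest.approx(0.75)

    def test_identical_rows_identical_avgs(self):
        row = {"d1": 0.8, "d2": 0.9}
        table = report_table({"m1": row, "m2": dict(row)})
        assert table.loc["m1", "Avg"] == table.loc["m2", "Avg"]

    def test_missing_cell_rejected(self):
        with pytest.raises(ValueError):
            report_table({"m1": {"d1": 0.8, "d2": 0.9}, "m2": {"d1": 0.7}})

    def test_display_rounding(self):
        table = report_table({"m": {"d1": 0.12345, "d2": 0.2}}, decimals=3)
        assert table.loc["m", "d1"] == pytest.approx(0.123)


class TestSignedRank:
    def test_eleven_positive_differences_exact(self):
        a = [0.8 + 0.01 * i for i in range(11)]
        b = [x - 0.005 for x in a]
        assert signed_rank_test(a, b, "greater") == pytest.approx(2 ** -11)

    def test_identical_sequences_rejected(self):
        with pytest.raises(ValueError):
            signed_rank_test([1.0] * 6, [1.0] * 6)

    def test_symmetric_tied_differences_two_sided_is_one(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [0.5, 2.5, 2.5, 4.5, 4.5, 6.5]  # differences +-0.5 with ties
        assert signed_rank_test(a, b, "two-sided") == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            d = rng.normal(0.2, 1.0, 9)
            d = d[d != 0]
            a = np.cumsum(np.abs(d)) + 1.0
            b = a - d
            for alt in ("greater", "two-sided"):
                assert signed_rank_test(a, b, alt) == pytest.approx(
                    wilcoxon_exact_oracle(d, alt))

    def test_matches_scipy_exact_without_ties(self, rng):
        d = rng.normal(0.3, 1.0, 12)
        a = np.arange(12) + 10.0
        b = a - d
        got = signed_rank_test(a, b, "greater")
        expected = scipy_wilcoxon(d, alternative="greater", method="exact").pvalue
        assert got == pytest.approx(expected)

    def test_large_sample_uses_normal_approximation(self, rng):
        d = rng.normal(0.3, 1.0, 40)
        a = np.arange(40) + 10.0
        b = a - d
        got = signed_rank_test(a, b, "greater")
        expected = scipy_wilcoxon(d, alternative="greater",
                                  method="approx", correction=False).pvalue
        assert got == pytest.approx(expected, rel=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            signed_rank_test([1, 2, 3], [0, 1, 2])


class TestGroupedEval:
    def test_two_groups_two_scores(self):
        ones = np.ones((4, 4), bool)
        zeros = np.zeros((4, 4), bool)
        per_group, mean = grouped_eval([
            (ones, ones, "g1"), (zeros, ones, "g2"),
        ])
        assert per_group["g1"] == 1.0 and per_group["g2"] == 0.0
        assert mean == pytest.approx(0.5)

    def test_single_group_equals_pooled(self, rng):
        pairs = []
        counts = []
        for _ in range(3):
            pred = rng.random((8, 8)) < 0.5
            truth = rng.random((8, 8)) < 0.5
            pairs.append((pred, truth, "vid"))
            counts.append(confusion_counts(pred, truth))
        per_group, mean = grouped_eval(pairs)
        assert per_group["vid"] == pytest.approx(pooled_f1(counts))
        assert mean == pytest.approx(pooled_f1(counts))

    def test_group_pools_counts(self):
        pred1 = np.array([[True, False]])
        truth1 = np.array([[True, True]])   # tp=1, fn=1
        pred2 = np.array([[True, True, True, True, True]])
        truth2 = np.array([[True, True, True, False, False]])  # tp=3, fp=2
        per_group, _ = grouped_eval([(pred1, truth1, "g"), (pred2, truth2, "g")])
        assert per_group["g"] == pytest.approx(8 / 11)
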