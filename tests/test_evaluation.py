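import numpy as np
import pytest

from csmetapred.evaluation import (
    ConfigurationError,
    average_pr_curve,
    average_precision,
    aves,
    catalytic_ranks,
    confusion,
    coverage_curve,
    paired_signed_rank,
    per_protein_summary,
    pr_curve,
    rfr_curve,
    roc_curve,
    summarize_dataset,
    vertical_average_roc,
)
from csmetapred.score_io import GoldAnnotation, ResidueKey

from conftest import ranking_with_hits
from oracle import oracle_ap, oracle_aves, oracle_pr_points, oracle_roc_points


class TestConfusion:
    def test_perfect_top(self):
        pred, gold = ranking_with_hits(4, [1, 2])
        c = confusion(pred, gold, 2)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_interleaved(self):
        pred, gold = ranking_with_hits(4, [2, 4])
        c = confusion(pred, gold, 2)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_full_cutoff_boundary(self):
        pred, gold = ranking_with_hits(10, [3, 7])
        c = confusion(pred, gold, 10)
        assert c.fp == 10 - 2
        assert c.tn == 0

    def test_gold_absent_from_ranking_is_configuration_error(self):
        pred, _ = ranking_with_hits(4, [1])
        stray = GoldAnnotation("P", frozenset({ResidueKey("B", 99, "", "H")}))
        with pytest.raises(ConfigurationError, match="B99"):
            confusion(pred, stray, 2)

    def test_invariants_at_any_cutoff(self):
        pred, gold = ranking_with_hits(12, [2, 5, 9])
        for n in range(1, 13):
            c = confusion(pred, gold, n)
            assert c.tp + c.fn == 3
            assert c.tp + c.fp == n
            assert c.tp + c.fp + c.tn + c.fn == 12


class TestAveS:
    def test_perfect_ranking(self):
        pred, gold = ranking_with_hits(4, [1, 2])
        assert aves(pred, gold) == pytest.approx(1.0)

    def test_interleaved_hand_value(self):
        pred, gold = ranking_with_hits(4, [2, 4])
        assert aves(pred, gold) == pytest.approx(0.25)

    def test_single_positive_at_bottom(self):
        pred, gold = ranking_with_hits(10, [10])
        assert aves(pred, gold) == pytest.approx(0.0)


class TestAveragePrecision:
    def test_hand_value(self):
        pred, gold = ranking_with_hits(4, [1, 3])
        assert average_precision(pred, gold) == pytest.approx((1.0 + 2.0 / 3.0) / 2)

    def test_perfect(self):
        pred, gold = ranking_with_hits(9, [1, 2, 3])
        assert average_precision(pred, gold) == 1.0

    def test_single_hit(self):
        pred, gold = ranking_with_hits(9, [5])
        assert average_precision(pred, gold) == pytest.approx(0.2)


class TestROC:
    def test_perfect_ranking_has_unit_area(self):
        pred, gold = ranking_with_hits(50, [1, 2, 3])
        avg = vertical_average_roc([roc_curve(pred, gold)])
        assert avg.area == pytest.approx(1.0, abs=1e-9)
        assert all(y == pytest.approx(1.0) for x, y in avg.points if x > 0)

    def test_averaging_identical_curves_is_idempotent(self):
        pred, gold = ranking_with_hits(20, [2, 9])
        c = roc_curve(pred, gold)
        avg1 = vertical_average_roc([c])
        avg2 = vertical_average_roc([c, c])
        np.testing.assert_allclose(avg1.y, avg2.y)

    def test_vertical_mean_of_two_proteins(self):
        from csmetapred.evaluation import Curve

        grid = [0.5]
        a = Curve("roc", [(0.0, 0.0), (0.5, 0.4), (1.0, 1.0)])
        b = Curve("roc", [(0.0, 0.0), (0.5, 0.8), (1.0, 1.0)])
        avg = vertical_average_roc([a, b], grid=grid)
        assert avg.points[0] == (0.5, pytest.approx(0.6))


class TestPRCurve:
    def test_perfect_ranking(self):
        pred, gold = ranking_with_hits(30, [1, 2])
        curve = pr_curve(pred, gold)
        assert all(p == pytest.approx(1.0) for _, p in curve.points)
        assert curve.area == pytest.approx(1.0, abs=1e-9)

    def test_local_skew_interpolation_trace(self):
        # catalytic at ranks {1, 3} of 4: between recall 0.5 and 1.0 one FP
        # is added per TP (skew 1), ending at precision 2/3
        pred, gold = ranking_with_hits(4, [1, 3])
        curve = pr_curve(pred, gold)
        assert curve.points == [
            (0.5, pytest.approx(1.0)),
            (1.0, pytest.approx(2.0 / 3.0)),
        ]
        grid = np.array([0.75])
        from csmetapred.evaluation import _pr_precision_on_grid

        # TP = 1.5, FP = 0 + 1 * 0.5 -> precision 1.5/2.0
        assert _pr_precision_on_grid([1, 3], 2, grid)[0] == pytest.approx(0.75)

    def test_averaging_identical_proteins_is_idempotent(self):
        pred, gold = ranking_with_hits(15, [2, 7])
        one = average_pr_curve([(pred, gold)])
        two = average_pr_curve([(pred, gold), (pred, gold)])
        np.testing.assert_allclose(one.y, two.y)
        assert one.area == pytest.approx(two.area)


class TestDatasetSummary:
    def test_mas_is_mean_aves(self):
        p1 = per_protein_summary(*ranking_with_hits(4, [1, 2]))
        p2 = per_protein_summary(*ranking_with_hits(4, [2, 4]))
        summary = summarize_dataset([p1, p2])
        assert summary.mas == pytest.approx((1.0 + 0.25) / 2)

    def test_pooled_median_rank(self):
        p1 = per_protein_summary(*ranking_with_hits(40, [1, 2]))
        p2 = per_protein_summary(*ranking_with_hits(40, [7, 30]))
        summary = summarize_dataset([p1, p2])
        assert summary.median_rank == pytest.approx(4.5)

    def test_mas_map_bounds(self, rng):
        summaries = []
        for i in range(20):
            n = int(rng.integers(10, 40))
            hits = sorted(rng.choice(n, size=int(rng.integers(1, 4)), replace=False) + 1)
            summaries.append(per_protein_summary(*ranking_with_hits(n, list(hits))))
        s = summarize_dataset(summaries)
        assert 0.0 <= s.mas <= 1.0
        assert 0.0 <= s.map <= 1.0


class TestRFRAndCoverage:
    def test_rfr_hand_value(self):
        pred, gold = ranking_with_hits(100, [3, 60])
        curve = rfr_curve([(pred, gold)], ratios=[5.0])
        assert curve.points[0] == (0.05, pytest.approx(0.5))

    def test_rfr_boundary_full_ratio(self):
        pairs = [ranking_with_hits(33, [2, 31]), ranking_with_hits(70, [70])]
        curve = rfr_curve(pairs, ratios=[100.0])
        assert curve.points[0][1] == pytest.approx(1.0)

    def test_coverage_thresholds(self):
        pred, gold = ranking_with_hits(120, [2, 50])
        half, full = coverage_curve([(pred, gold)], thresholds=(0.5, 1.0))
        y_half = dict((round(x * 100), y) for x, y in half.points)
        y_full = dict((round(x * 100), y) for x, y in full.points)
        assert y_half[1] == 0.0 and y_half[2] == 1.0
        assert y_full[49] == 0.0 and y_full[50] == 1.0

    def test_coverage_single_positive_jump(self):
        pred, gold = ranking_with_hits(30, [10])
        (curve,) = coverage_curve([(pred, gold)], thresholds=(0.5,), max_rank=30)
        ys = dict((round(x * 30), y) for x, y in curve.points)
        assert ys[9] == 0.0 and ys[10] == 1.0

    def test_coverage_non_decreasing(self, rng):
        pairs = [ranking_with_hits(60, sorted(rng.choice(60, 3, replace=False) + 1))
                 for _ in range(5)]
        for curve in coverage_curve(pairs):
            ys = curve.y
            assert np.all(np.diff(ys) >= 0)


class TestSignedRank:
    def test_identical_series_gives_p_one(self, caplog):
        with caplog.at_level("WARNING"):
            assert paired_signed_rank([0.5] * 10, [0.5] * 10) == 1.0

    def test_strong_shift_is_significant(self, rng):
        a = rng.normal(0.8, 0.05, size=100)
        b = a - rng.uniform(0.1, 0.3, size=100)
        assert paired_signed_rank(a, b) < 1e-4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            paired_signed_rank([1.0, 2.0], [1.0])

    def test_antisymmetry(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        assert paired_signed_rank(a, b) == pytest.approx(paired_signed_rank(b, a))


class TestOracleEquivalence:
    """Every statistic must match literal enumeration over all cutoffs."""

    def random_case(self, rng):
        n = int(rng.integers(5, 31))
        npos = int(rng.integers(1, max(2, n // 3)))
        hits = sorted(rng.choice(n, size=npos, replace=False) + 1)
        return ranking_with_hits(n, list(hits))

    def test_statistics_match_brute_force(self, rng):
        for _ in range(40):
            pred, gold = self.random_case(rng)
            order = pred.keys
            positives = set(gold.catalytic)
            assert aves(pred, gold) == pytest.approx(oracle_aves(order, positives), abs=1e-12)
            assert average_precision(pred, gold) == pytest.approx(
                oracle_ap(order, positives), abs=1e-12)
            roc = roc_curve(pred, gold).points
            for got, want in zip(roc, oracle_roc_points(order, positives)):
                assert got == pytest.approx(want, abs=1e-12)
            pr = pr_curve(pred, gold).points
            for got, want in zip(pr, oracle_pr_points(order, positives)):
                assert got == pytest.approx(want, abs=1e-12)

    def test_random_ranking_roc_is_calibrated(self, rng):
        curves = []
        for i in range(500):
            n = int(rng.integers(20, 60))
            hits = sorted(rng.choice(n, size=3, replace=False) + 1)
            pred, gold = ranking_with_hits(n, list(hits))
            curves.append(roc_curve(pred, gold))
        avg = vertical_average_roc(curves)
        assert 0.47 <= avg.area <= 0.53
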