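"""ROC/AUC, DeLong CI, Youden point, KS, group tests, LR test."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import aortamorph as am
from aortamorph.errors import PerfectSeparationError
from oracles import brute_force_auc, brute_force_ks


def _cohort(rng, n1=15, n0=20, ties=True):
    pool = rng.integers(0, 10, n1 + n0).astype(float) if ties else rng.normal(
        size=n1 + n0
    )
    return pool, np.concatenate([np.ones(n1, int), np.zeros(n0, int)])


class TestRocAuc:
    def test_perfect_separation(self):
        roc = am.roc_auc([2.0, 3.0, 0.0, 1.0], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)

    def test_interleaved_four_pairs(self):
        """events {1,3} vs non-events {0,2}: 3 wins of 4 pairs."""
        values = [1.0, 3.0, 0.0, 2.0]
        outcomes = [1, 1, 0, 0]
        assert brute_force_auc(values, outcomes) == pytest.approx(0.75)
        assert am.roc_auc(values, outcomes).auc == pytest.approx(0.75)

    def test_trapezoid_equals_pair_counting_with_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            values, outcomes = _cohort(rng)
            roc = am.roc_auc(values, outcomes)
            assert roc.auc == pytest.approx(
                brute_force_auc(values, outcomes), abs=1e-12
            )
            assert roc.auc == pytest.approx(
                am.mannwhitney_auc(values, outcomes), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        for _ in range(20):
            values, outcomes = _cohort(rng)
            assert am.roc_auc(values, outcomes).auc == pytest.approx(
                roc_auc_score(outcomes, values), abs=1e-12
            )

    def test_complement_identity(self):
        rng = np.random.default_rng(12)
        values, outcomes = _cohort(rng)
        a1 = am.roc_auc(values, outcomes).auc
        a2 = am.roc_auc(-values, outcomes).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        values, outcomes = _cohort(rng)
        a1 = am.roc_auc(values, outcomes).auc
        a2 = am.roc_auc(np.exp(values / 3.0), outcomes).auc
        assert a1 == pytest.approx(a2, abs=1e-12)
        assert am.ks_statistic(values[outcomes == 1], values[outcomes == 0]) == (
            pytest.approx(
                am.ks_statistic(
                    np.exp(values[outcomes == 1] / 3.0),
                    np.exp(values[outcomes == 0] / 3.0),
                ),
                abs=1e-12,
            )
        )

    def test_direction_flag(self):
        values = [5.0, 4.0, 1.0, 2.0]  # smaller value = event
        outcomes = [0, 0, 1, 1]
        roc = am.roc_auc(values, outcomes, larger_is_positive=False)
        assert roc.auc == pytest.approx(1.0)

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(14)
        values, outcomes = _cohort(rng)
        roc = am.roc_auc(values, outcomes)
        assert np.all(np.diff(roc.sensitivity) <= 1e-12)  # thresholds ascend

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            am.roc_auc([1.0, 2.0], [1, 1])


class TestAucCI:
    def test_near_perfect_separation_clips_to_one(self):
        rng = np.random.default_rng(20)
        values = np.concatenate([rng.normal(4, 1, 50), rng.normal(0, 1, 50)])
        outcomes = np.concatenate([np.ones(50, int), np.zeros(50, int)])
        lo, hi = am.auc_confidence_interval(values, outcomes)
        assert hi == 1.0  # Wald upper bound clipped
        assert lo < 1.0

    def test_tiny_groups_give_wide_ordered_interval(self):
        values, outcomes = [3.0, 1.5, 1.0, 2.5], [1, 1, 0, 0]
        lo, hi = am.auc_confidence_interval(values, outcomes)
        auc = am.roc_auc(values, outcomes).auc
        assert lo < auc < hi

    def test_degenerate_all_tied(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = am.auc_confidence_interval([1.0] * 8, [1, 1, 1, 1, 0, 0, 0, 0])
        assert lo == hi == pytest.approx(0.5)

    def test_perfect_separation_collapses_with_warning(self):
        """Completely separated groups carry no placement variation, so
        the DeLong interval degenerates to (1, 1)."""
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = am.auc_confidence_interval(
                [10.0, 11.0, 12.0, 0.0, 1.0, 2.0], [1, 1, 1, 0, 0, 0]
            )
        assert lo == hi == 1.0

    def test_null_coverage(self):
        """Identical group distributions: the 95% CI contains 0.5 in
        >= 93% of replicates."""
        rng = np.random.default_rng(21)
        n_rep, hits = 300, 0
        for _ in range(n_rep):
            values = rng.normal(size=400)
            outcomes = np.concatenate([np.ones(200, int), np.zeros(200, int)])
            lo, hi = am.auc_confidence_interval(values, outcomes)
            hits += lo <= 0.5 <= hi
        assert hits / n_rep >= 0.93

    def test_bootstrap_alternative_close_to_delong(self):
        rng = np.random.default_rng(22)
        values = np.concatenate([rng.normal(1, 1, 60), rng.normal(0, 1, 60)])
        outcomes = np.concatenate([np.ones(60, int), np.zeros(60, int)])
        dlo, dhi = am.auc_confidence_interval(values, outcomes)
        blo, bhi = am.bootstrap_auc_ci(values, outcomes, seed=0)
        assert dlo == pytest.approx(blo, abs=0.05)
        assert dhi == pytest.approx(bhi, abs=0.05)


class TestYouden:
    def test_tie_breaks_toward_lowest_threshold(self):
        """events {3,4,5} vs non-events {1,2,3}: J peaks at thresholds 3
        and 4 (both 0.667); the lower one wins and keeps Se = 1."""
        values = [3.0, 4.0, 5.0, 1.0, 2.0, 3.0]
        outcomes = [1, 1, 1, 0, 0, 0]
        # exhaustive oracle over observed thresholds
        best = max(
            (
                (
                    np.mean([v >= t for v, o in zip(values, outcomes) if o == 1])
                    + np.mean([v < t for v, o in zip(values, outcomes) if o == 0])
                    - 1.0,
                    -t,
                )
                for t in sorted(set(values))
            ),
        )
        assert best[0] == pytest.approx(2.0 / 3.0)
        roc = am.youden_operating_point(am.roc_auc(values, outcomes))
        assert roc.youden_threshold == 3.0
        assert roc.se == pytest.approx(1.0)
        assert roc.sp == pytest.approx(2.0 / 3.0, abs=1e-9)

    def test_perfect_separation_all_ones(self):
        roc = am.youden_operating_point(
            am.roc_auc([4.0, 5.0, 1.0, 2.0], [1, 1, 0, 0])
        )
        assert (roc.se, roc.sp, roc.ppv, roc.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_degenerate_all_identical(self):
        roc = am.youden_operating_point(am.roc_auc([2.0] * 6, [1, 1, 1, 0, 0, 0]))
        assert roc.youden_threshold == 2.0
        assert roc.se == 1.0
        assert roc.sp == 0.0


class TestKs:
    def test_disjoint_supports(self):
        assert am.ks_statistic([1, 2, 3], [4, 5, 6]) == pytest.approx(1.0)

    def test_interleaved(self):
        assert am.ks_statistic([1.0, 3.0], [2.0, 4.0]) == pytest.approx(0.5)

    def test_self_distance_zero(self):
        x = [1.0, 2.0, 5.0]
        assert am.ks_statistic(x, x) == pytest.approx(0.0)

    def test_matches_pooled_ecdf_brute_force(self):
        rng = np.random.default_rng(30)
        for _ in range(50):
            a = rng.normal(size=rng.integers(3, 20))
            b = rng.normal(0.5, 1.2, size=rng.integers(3, 20))
            assert am.ks_statistic(a, b) == pytest.approx(
                brute_force_ks(a, b), abs=1e-12
            )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            am.ks_statistic([], [1.0])


class TestGroupDifference:
    def test_identical_groups_p_one(self):
        res = am.group_difference_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0)

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(31)
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 1, 30)
        assert am.group_difference_test(a, b).pvalue < 1e-3

    def test_force_nonparametric(self):
        rng = np.random.default_rng(32)
        a, b = rng.normal(size=40), rng.normal(size=40)
        res = am.group_difference_test(a, b, force_nonparametric=True)
        assert res.test == "mann-whitney"
        res = am.group_difference_test(a, b, paired=True, force_nonparametric=True)
        assert res.test == "wilcoxon"

    def test_skewed_small_samples_fall_back_to_ranks(self):
        rng = np.random.default_rng(33)
        a = np.exp(rng.normal(0, 1.5, 15))  # grossly lognormal
        b = np.exp(rng.normal(0, 1.5, 15))
        res = am.group_difference_test(a, b)
        assert res.test == "mann-whitney"

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError, match="equal"):
            am.group_difference_test([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)

    def test_type_one_error_rate(self):
        """Two identical normal populations, n=50: ~5% of replicates reject."""
        rng = np.random.default_rng(34)
        n_rep, hits = 500, 0
        for _ in range(n_rep):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            hits += am.group_difference_test(a, b).pvalue < 0.05
        assert 0.03 <= hits / n_rep <= 0.07


class TestLikelihoodRatio:
    def test_perfect_separation_raises(self):
        marker = np.array([0.01, 0.02, 0.99, 1.01])
        outcomes = np.array([0, 0, 1, 1])
        with pytest.raises(PerfectSeparationError):
            am.likelihood_ratio_test(marker, outcomes)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(40)
        x = rng.normal(size=120)
        p = 1 / (1 + np.exp(-(0.8 * x - 0.2)))
        y = rng.binomial(1, p)
        lr, pval = am.likelihood_ratio_test(x, y)
        fit = sm.Logit(y, sm.add_constant((x - x.mean()) / x.std())).fit(disp=0)
        assert lr == pytest.approx(2 * (fit.llf - fit.llnull), abs=1e-6)
        assert pval == pytest.approx(fit.llr_pvalue, abs=1e-9)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(41)
        detected = 0
        n_rep = 100
        for _ in range(n_rep):
            x = rng.normal(size=200)
            y = rng.binomial(1, 1 / (1 + np.exp(-x)))
            if 0 < y.sum() < 200:
                _, p = am.likelihood_ratio_test(x, y)
                detected += p < 1e-3
        assert detected / n_rep >= 0.95


class TestEvaluateMarker:
    def test_report_is_self_consistent(self):
        rng = np.random.default_rng(50)
        values = np.concatenate([rng.normal(22.4, 9.9, 39), rng.normal(10.0, 8.1, 44)])
        outcomes = np.concatenate([np.ones(39, int), np.zeros(44, int)])
        rep = am.evaluate_marker(values, outcomes)
        assert rep["auc_ci_low"] <= rep["auc"] <= rep["auc_ci_high"]
        for k in ("sensitivity", "specificity", "ppv", "pnv", "ks"):
            assert 0.0 <= rep[k] <= 1.0
        assert rep["n_event"] == 39 and rep["n_nonevent"] == 44
        assert rep["group_p"] < 0.01  # groups far apart by construction
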