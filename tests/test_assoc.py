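import numpy as np
import pytest
from scipy import stats

from rarpipe.assoc import (
    check_loss,
    classify_fatigability,
    cohens_d,
    group_comparison_tests,
    logistic_fatigability_or,
    median_regression,
    qr_likelihood_ratio_test,
    score_pfs,
)
from rarpipe.errors import (
    CollinearityError,
    ConfigError,
    DataError,
    UndefinedEffectError,
)

from _oracles import quantreg_vertex_oracle


class TestScorePfs:
    def test_all_fives_is_fifty(self):
        assert score_pfs([5] * 10) == (50, False)

    def test_all_zeros_is_zero(self):
        assert score_pfs([0] * 10) == (0, False)

    def test_person_mean_imputation(self):
        score, imputed = score_pfs([2] * 9 + [None])
        assert score == 20 and imputed

    def test_imputation_rounding(self):
        # 9 items sum 13, person mean 13/9; total 13 + 13/9 = 14.44 -> 14
        items = [2, 2, 2, 2, 1, 1, 1, 1, 1, None]
        assert score_pfs(items) == (14, True)

    def test_too_many_missing_is_missing(self):
        assert score_pfs([3] * 6 + [None] * 4) == (None, False)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            score_pfs([6] + [0] * 9)

    def test_wrong_item_count_rejected(self):
        with pytest.raises(DataError):
            score_pfs([1] * 9)

    def test_nan_treated_as_missing(self):
        score, imputed = score_pfs([3.0] * 9 + [float("nan")])
        assert score == 30 and imputed


class TestClassifyFatigability:
    @pytest.mark.parametrize("score,expected", [(15, True), (14, False), (0, False), (50, True)])
    def test_cutpoint_boundary(self, score, expected):
        assert classify_fatigability(score) is expected

    def test_missing_score_missing_class(self):
        assert classify_fatigability(None) is None
        assert classify_fatigability(float("nan")) is None

    def test_out_of_range(self):
        with pytest.raises(DataError):
            classify_fatigability(51)


class TestMedianRegression:
    def test_noiseless_exact_recovery(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        b = np.array([2.0, -1.5])
        res = median_regression(X @ b, X, bootstrap_B=0)
        np.testing.assert_allclose(res.estimates, b, atol=1e-8)
        assert res.check_loss == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_is_median(self):
        res = median_regression([1.0, 2.0, 100.0], np.ones((3, 1)), bootstrap_B=0)
        assert res.estimates[0] == pytest.approx(2.0, abs=1e-9)

    def test_intercept_only_odd_n_property(self, rng):
        for _ in range(10):
            y = rng.normal(size=11)
            res = median_regression(y, np.ones((11, 1)), bootstrap_B=0)
            assert res.estimates[0] == pytest.approx(np.median(y), abs=1e-9)

    def test_vertex_oracle_small_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = rng.normal(size=n)
            res = median_regression(y, X, bootstrap_B=0)
            best = quantreg_vertex_oracle(y, X)
            assert res.check_loss == pytest.approx(best, abs=1e-8)

    def test_vertex_oracle_p1(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 13))
            X = rng.normal(size=(n, 1)) + 2.0
            y = rng.normal(size=n)
            res = median_regression(y, X, bootstrap_B=0)
            assert res.check_loss == pytest.approx(quantreg_vertex_oracle(y, X), abs=1e-8)

    def test_collinear_design_rejected(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(CollinearityError):
            median_regression(rng.normal(size=20), X, bootstrap_B=0)

    def test_bootstrap_reproducible(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = X @ [1.0, 2.0] + rng.normal(size=40)
        r1 = median_regression(y, X, bootstrap_B=100, seed=5)
        r2 = median_regression(y, X, bootstrap_B=100, seed=5)
        np.testing.assert_array_equal(r1.ci_lower, r2.ci_lower)
        np.testing.assert_array_equal(r1.pvalues, r2.pvalues)

    def test_missing_rows_dropped(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = X @ [1.0, 0.5] + rng.normal(size=20) * 0.1
        y[3] = np.nan
        X2 = X.copy()
        X2[7, 1] = np.nan
        res = median_regression(y, X2, bootstrap_B=0)
        assert res.n == 18

    def test_invalid_tau(self):
        with pytest.raises(ConfigError):
            median_regression([1.0, 2.0], np.ones((2, 1)), tau=1.5)

    def test_coefficient_recovery_simulation(self, rng):
        # median shift of c per unit of x recovered within +/-0.2 at n=200,
        # sigma=4; slope SE ~ sqrt(pi/2)*sigma/(sqrt(n)*sd_x) ~ 0.10 here
        hits = 0
        for _ in range(40):
            x = rng.normal(7.5, 3.5, size=200)
            y = 10 + 1.38 * x + rng.normal(0, 4, size=200)
            res = median_regression(y, np.column_stack([np.ones(200), x]),
                                    bootstrap_B=0)
            hits += abs(res.estimates[1] - 1.38) < 0.2
        assert hits >= 36


class TestCheckLoss:
    def test_tau_half_is_half_l1(self, rng):
        r = rng.normal(size=50)
        assert check_loss(r, 0.5) == pytest.approx(0.5 * np.abs(r).sum())

    def test_asymmetry(self):
        assert check_loss(np.array([1.0]), 0.9) == pytest.approx(0.9)
        assert check_loss(np.array([-1.0]), 0.9) == pytest.approx(0.1)


class TestQrLrt:
    def _fit(self, y, X, names):
        return median_regression(y, X, names=names, bootstrap_B=0)

    def test_identical_models_p_one(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = rng.normal(size=50)
        full = self._fit(y, X, ["i", "x"])
        out = qr_likelihood_ratio_test(full, full)
        assert out.statistic == 0.0 and out.p_value == 1.0

    def test_non_nested_rejected(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        a = self._fit(rng.normal(size=30), X, ["i", "a"])
        b = self._fit(rng.normal(size=30), X, ["i", "b"])
        with pytest.raises(ConfigError):
            qr_likelihood_ratio_test(a, b)

    def test_null_calibration(self, rng):
        rejections = 0
        B = 200
        for _ in range(B):
            n = 200
            g = rng.integers(0, 4, size=n)
            y = rng.normal(10, 4, size=n)
            dummies = np.column_stack([(g == j).astype(float) for j in (1, 2, 3)])
            Xf = np.column_stack([np.ones(n), dummies])
            full = self._fit(y, Xf, ["i", "c1", "c2", "c3"])
            reduced = self._fit(y, np.ones((n, 1)), ["i"])
            if qr_likelihood_ratio_test(full, reduced).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / B <= 0.09

    def test_power_at_four_point_shift(self, rng):
        hits = 0
        B = 60
        for _ in range(B):
            n = 200
            g = rng.integers(0, 4, size=n)
            y = rng.normal(10, 4, size=n) + 4.0 * (g == 2)
            dummies = np.column_stack([(g == j).astype(float) for j in (1, 2, 3)])
            full = self._fit(y, np.column_stack([np.ones(n), dummies]),
                             ["i", "c1", "c2", "c3"])
            reduced = self._fit(y, np.ones((n, 1)), ["i"])
            if qr_likelihood_ratio_test(full, reduced).p_value < 0.05:
                hits += 1
        assert hits / B > 0.8


class TestGroupComparisons:
    def test_identical_groups(self):
        v = np.arange(10.0)
        out = group_comparison_tests({"a": v, "b": v.copy()})
        assert out["kruskal"]["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert out["kruskal"]["p_value"] == pytest.approx(1.0)

    def test_complete_separation_minimal_p(self, rng):
        out1 = group_comparison_tests({"a": [1, 2, 3], "b": [101, 102, 103]})
        out2 = group_comparison_tests({"a": [4, 5, 6], "b": [999.0, 1000.0, 1001.0]})
        p1 = out1["pairwise"][("a", "b")]["p_value"]
        assert p1 == pytest.approx(out2["pairwise"][("a", "b")]["p_value"])
        # no permutation of the pooled values can give a smaller p
        pooled = np.array([1, 2, 3, 101, 102, 103.0])
        for _ in range(50):
            rng.shuffle(pooled)
            out = group_comparison_tests({"a": pooled[:3], "b": pooled[3:]})
            assert out["pairwise"][("a", "b")]["p_value"] >= p1 - 1e-12

    def test_kruskal_matches_rank_formula(self, rng):
        for _ in range(10):
            groups = {
                "a": rng.normal(size=8),
                "b": rng.normal(size=10),
                "c": rng.normal(size=7),
            }
            out = group_comparison_tests(groups)
            # independent closed-form H with tie correction via scipy ranks
            vals = np.concatenate(list(groups.values()))
            ranks = stats.rankdata(vals)
            n = vals.size
            offset, H = 0, 0.0
            for v in groups.values():
                r = ranks[offset : offset + v.size]
                H += r.sum() ** 2 / v.size
                offset += v.size
            H = 12 / (n * (n + 1)) * H - 3 * (n + 1)
            ties = np.unique(vals, return_counts=True)[1]
            H /= 1 - ((ties**3 - ties).sum() / (n**3 - n))
            assert out["kruskal"]["statistic"] == pytest.approx(H, abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        groups = {"a": rng.normal(size=9), "b": rng.normal(size=12)}
        out1 = group_comparison_tests(groups)
        out2 = group_comparison_tests({k: np.exp(v) for k, v in groups.items()})
        assert out1["kruskal"]["p_value"] == pytest.approx(out2["kruskal"]["p_value"])

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigError):
            group_comparison_tests({"a": [1.0], "b": []})

    def test_single_group_rejected(self):
        with pytest.raises(ConfigError):
            group_comparison_tests({"a": [1.0, 2.0]})


class TestLogisticOr:
    def test_two_by_two_matches_cross_product(self):
        # 40 exposed (30 events), 60 unexposed (20 events)
        y = np.concatenate([np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)])
        x = np.concatenate([np.ones(40), np.zeros(60)])
        X = np.column_stack([np.ones(100), x])
        res = logistic_fatigability_or(y, X, names=["intercept", "exposed"])
        expected = (30 * 40) / (10 * 20)
        assert res.odds_ratios[1] == pytest.approx(expected, rel=1e-4)

    def test_scale_invariance(self, rng):
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.5 * x)))).astype(float)
        X1 = np.column_stack([np.ones(300), x])
        X2 = np.column_stack([np.ones(300), 2 * x])
        r1 = logistic_fatigability_or(y, X1)
        r2 = logistic_fatigability_or(y, X2)
        assert r1.odds_ratios[1] == pytest.approx(r2.odds_ratios[1] ** 2, rel=1e-4)

    def test_null_coverage(self, rng):
        covered = 0
        B = 60
        for _ in range(B):
            x = rng.normal(size=150)
            y = (rng.random(150) < 0.4).astype(float)
            res = logistic_fatigability_or(y, np.column_stack([np.ones(150), x]))
            if res.separation:
                continue
            covered += res.ci_lower[1] <= 1.0 <= res.ci_upper[1]
        assert covered / B >= 0.88

    def test_separation_flagged(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = x.copy()
        res = logistic_fatigability_or(y, np.column_stack([np.ones(20), x]))
        assert res.separation
        assert np.isnan(res.odds_ratios).all()


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_degenerate_sd_error(self):
        with pytest.raises(UndefinedEffectError):
            cohens_d([0.0, 0.0], [1.0, 1.0])

    def test_matches_direct_formula(self, rng):
        for _ in range(10):
            a = rng.normal(size=12)
            b = rng.normal(loc=1, size=9)
            pooled = np.sqrt(
                (11 * np.var(a, ddof=1) + 8 * np.var(b, ddof=1)) / 19
            )
            assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled)

    def test_too_small_group(self):
        with pytest.raises(DataError):
            cohens_d([1.0], [1.0, 2.0])
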