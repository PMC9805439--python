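"""Statistical machinery: rank/contingency tests, logistic and Cox fits,
Kaplan-Meier and log-rank, validated against exact enumeration, closed
forms, and the independent lifelines/statsmodels/scipy implementations."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency, mannwhitneyu, rankdata

from ppsp import stats as S


class TestMannWhitney:
    def test_identical_samples(self):
        res = S.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == 4.5  # n^2 / 2
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_samples_hit_the_extremes(self):
        lo = S.mann_whitney_u([1, 2, 3], [10, 11, 12, 13])
        hi = S.mann_whitney_u([10, 11, 12, 13], [1, 2, 3])
        assert lo.statistic == 0
        assert hi.statistic == 12  # n1 * n2

    @pytest.mark.parametrize("seed", range(10))
    def test_normal_approximation_close_to_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=5), rng.normal(size=5)
        p = S.mann_whitney_u(x, y).p_value

        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        mu = 5 * 5 / 2
        obs = abs(ranks[:5].sum() - 15 - mu)
        hits = total = 0
        for idx in itertools.combinations(range(10), 5):
            u = ranks[list(idx)].sum() - 15
            total += 1
            hits += abs(u - mu) >= obs - 1e-9
        assert p == pytest.approx(hits / total, abs=0.02)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, 30).astype(float)
        y = rng.integers(0, 6, 25).astype(float)
        mine = S.mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            S.mann_whitney_u([], [1.0])


class TestPearsonChiSquare:
    def test_published_parity_table(self):
        res = S.pearson_chi_square([[61, 14], [104, 52]])
        assert res.statistic == pytest.approx(5.34, abs=0.01)
        assert round(res.p_value, 3) == 0.021

    def test_identical_row_proportions_give_zero(self):
        res = S.pearson_chi_square([[10, 20], [30, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 40, size=(2, 3))
        mine = S.pearson_chi_square(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert mine.statistic == pytest.approx(((table - expected) ** 2 / expected).sum())
        ref = chi2_contingency(table, correction=False)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)
        assert mine.df == ref.dof

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            S.pearson_chi_square([[0, 0], [5, 3]])


class TestOddsRatio:
    def test_symmetric_table_is_null(self):
        est = S.odds_ratio_2x2(S.ContingencyTable(1, 1, 1, 1))
        assert est.point == 1.0

    def test_exposure_flip_inverts(self):
        t = S.ContingencyTable(12, 5, 7, 20)
        flipped = S.ContingencyTable(5, 12, 20, 7)
        a = S.odds_ratio_2x2(t)
        b = S.odds_ratio_2x2(flipped)
        assert a.point * b.point == pytest.approx(1.0)
        assert a.ci_low * b.ci_high == pytest.approx(1.0, rel=1e-9)

    def test_ci_brackets_point_and_shrinks_with_counts(self):
        base = S.ContingencyTable(12, 5, 7, 20)
        big = S.ContingencyTable(120, 50, 70, 200)
        e1, e2 = S.odds_ratio_2x2(base), S.odds_ratio_2x2(big)
        assert e1.ci_low <= e1.point <= e1.ci_high
        assert e2.point == pytest.approx(e1.point)
        assert (e2.ci_high - e2.ci_low) < (e1.ci_high - e1.ci_low)

    def test_zero_cell_requires_haldane(self):
        with pytest.raises(ValueError, match="Haldane"):
            S.odds_ratio_2x2(S.ContingencyTable(0, 5, 7, 20))
        est = S.odds_ratio_2x2(S.ContingencyTable(0, 5, 7, 20), haldane=True)
        assert est.point > 0


class TestLogistic:
    def test_single_binary_predictor_equals_2x2_odds_ratio(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 400)
        y = (rng.random(400) < 0.2 + 0.3 * x).astype(int)
        fit = S.fit_logistic(y, x, names=["x"])
        a = int(((x == 1) & (y == 1)).sum())
        b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        closed = S.odds_ratio_2x2(S.ContingencyTable(a, b, c, d))
        assert fit.estimates["x"].point == pytest.approx(closed.point, abs=1e-6)
        assert fit.estimates["x"].ci_low == pytest.approx(closed.ci_low, abs=1e-6)
        assert fit.estimates["x"].ci_high == pytest.approx(closed.ci_high, abs=1e-6)

    def test_intercept_only_recovers_event_fraction(self):
        y = np.array([1, 0, 0, 0, 1, 1, 0, 0])
        fit = S.fit_logistic(y)
        assert fit.extra["fitted_mean"] == pytest.approx(y.mean(), abs=1e-10)

    def test_matches_statsmodels_multivariable(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = np.column_stack([rng.integers(0, 2, 300), rng.normal(size=300)])
        eta = -1 + 0.8 * X[:, 0] + 0.5 * X[:, 1]
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = S.fit_logistic(y, X, names=["b", "z"])
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert fit.coef == pytest.approx(ref.params, abs=1e-6)
        assert fit.se == pytest.approx(ref.bse, abs=1e-6)

    def test_null_predictor_ci_coverage(self):
        """Wald CI for a null binary predictor should contain OR = 1
        in at least 94% of replicates (nominal 95%)."""
        rng = np.random.default_rng(0)
        n, reps = 5000, 200
        covered = 0
        for _ in range(reps):
            x = rng.integers(0, 2, n)
            y = (rng.random(n) < 0.3).astype(int)
            est = S.fit_logistic(y, x, names=["x"]).estimates["x"]
            covered += est.ci_low <= 1.0 <= est.ci_high
        assert covered / reps >= 0.94

    def test_perfect_separation_detected(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = np.array([0] * 20 + [1] * 20)
        with pytest.raises(S.ConvergenceError):
            S.fit_logistic(y, x)

    def test_rank_deficient_design_rejected(self):
        x = np.column_stack([np.arange(30.0), 2 * np.arange(30.0)])
        y = (np.arange(30) % 2).astype(int)
        with pytest.raises(ValueError, match="rank"):
            S.fit_logistic(y, x)


class TestCox:
    def test_score_test_equals_log_rank_on_tie_free_data(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 200)
        e = (rng.random(200) < 0.8).astype(int)
        g = rng.integers(0, 2, 200).astype(float)
        fit = S.fit_cox(t, e, g, names=["g"])
        lr = S.log_rank([(t[g == 1], e[g == 1]), (t[g == 0], e[g == 0])])
        assert fit.score_chi2 == pytest.approx(lr.statistic, abs=1e-6)

    def test_matches_lifelines_with_efron_ties(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 300
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        t = np.round(rng.exponential(10 * np.exp(-0.7 * x1 - 0.3 * x2))) + 1
        e = (rng.random(n) < 0.75).astype(int)
        fit = S.fit_cox(t, e, np.column_stack([x1, x2]), names=["x1", "x2"])
        ref = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2}), "t", "e"
        )
        assert fit.coef == pytest.approx(ref.params_.to_numpy(), abs=1e-5)
        assert fit.se == pytest.approx(ref.standard_errors_.to_numpy(), abs=1e-5)

    def test_recovers_known_hazard_ratio(self):
        rng = np.random.default_rng(2)
        n = 5000
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(20 * np.exp(-math.log(2.0) * g))
        e = (t <= 40).astype(int)
        t = np.minimum(t, 40)
        fit = S.fit_cox(t, e, g, names=["g"])
        assert 1.8 <= fit.estimates["g"].point <= 2.2

    def test_affine_covariate_rescaling(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(10 * np.exp(-0.5 * x))
        e = np.ones(n, int)
        a = S.fit_cox(t, e, x, names=["x"])
        b = S.fit_cox(t, e, 10 * x + 3, names=["x"])
        assert b.coef[0] == pytest.approx(a.coef[0] / 10, rel=1e-5)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="no information"):
            S.fit_cox([1, 2, 3], [1, 1, 0], [2.0, 2.0, 2.0])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            S.fit_cox([1, 2, 3], [0, 0, 0], [1.0, 2.0, 3.0])


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = S.kaplan_meier([5, 10, 15], [1, 0, 1])
        assert km.event_times.tolist() == [5, 15]
        assert km.survival == pytest.approx([2 / 3, 0.0])
        assert km.at_risk.tolist() == [3, 1]

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 80)
        km = S.kaplan_meier(t, np.ones(80, int))
        emp = [(t > u).mean() for u in km.event_times]
        assert km.survival == pytest.approx(emp, abs=1e-12)

    def test_all_censored_is_flat_one(self):
        km = S.kaplan_meier([3, 6, 9], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.probability_at(100.0) == 1.0

    def test_input_order_invariance(self):
        t = np.array([4.0, 1.0, 3.0, 2.0, 5.0])
        e = np.array([1, 0, 1, 1, 0])
        a = S.kaplan_meier(t, e)
        perm = [2, 0, 4, 1, 3]
        b = S.kaplan_meier(t[perm], e[perm])
        assert a.survival == pytest.approx(b.survival)

    def test_matches_lifelines_with_censoring(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(5)
        t = np.round(rng.exponential(10, 120)) + 1
        e = (rng.random(120) < 0.7).astype(int)
        km = S.kaplan_meier(t, e)
        ref = KaplanMeierFitter().fit(t, e)
        for u, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(float(ref.predict(u)), abs=1e-10)


class TestLogRank:
    def test_identical_groups_are_null(self):
        g = ([1, 2, 3, 4], [1, 1, 0, 1])
        res = S.log_rank([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_small_hand_computed_table(self):
        # event times 1, 2, 5; O-E = 0.5 + 0.2 + 0 = 0.7; V = 0.25 + 0.36
        res = S.log_rank([([1, 2, 3], [1, 1, 0]), ([2, 4, 5], [1, 0, 1])])
        assert res.statistic == pytest.approx(0.7**2 / 0.61, abs=1e-12)

    def test_group_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(8, 100)
        e = (rng.random(100) < 0.8).astype(int)
        g = rng.integers(0, 2, 100)
        a = S.log_rank([(t[g == 0], e[g == 0]), (t[g == 1], e[g == 1])])
        b = S.log_rank([(t[g == 1], e[g == 1]), (t[g == 0], e[g == 0])])
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_three_groups_match_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(5)
        t = rng.exponential(8, 300)
        e = (rng.random(300) < 0.8).astype(int)
        grp = rng.integers(0, 3, 300)
        mine = S.log_rank([(t[grp == k], e[grp == k]) for k in range(3)])
        ref = multivariate_logrank_test(t, grp, e)
        assert mine.statistic == pytest.approx(ref.test_statistic, abs=1e-9)
        assert mine.df == 2

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            S.log_rank([([1, 2], [0, 0]), ([3, 4], [0, 0])])
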