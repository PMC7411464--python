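import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernaforge import simulate, survival
from cernaforge.io import ExpressionMatrix


def efron_partial_loglik(beta, times, events, x):
    """Independent Efron partial log-likelihood (oracle for the Cox fit)."""
    ll = 0.0
    eta = beta * np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        at_risk = times >= t
        d = tied.sum()
        sum_tied = np.exp(eta[tied]).sum()
        sum_risk = np.exp(eta[at_risk]).sum()
        ll += eta[tied].sum()
        for j in range(d):
            ll -= math.log(sum_risk - (j / d) * sum_tied)
    return ll


def _clin(times, events, index=None):
    idx = index or [f"S{i}" for i in range(len(times))]
    return pd.DataFrame(
        {"sample_id": idx, "time": times, "event": events}
    ).set_index("sample_id", drop=False)


class TestFitCoxUnivariate:
    def test_matches_grid_maximum_on_toy_cohort(self):
        times = [5, 8, 8, 12, 14, 20, 21, 25, 30, 42]
        events = [1, 1, 1, 0, 1, 1, 0, 1, 0, 1]
        x = [1.2, 0.3, 2.1, -0.5, 1.8, 0.0, 0.7, 2.5, -1.0, 1.1]
        clin = _clin(times, events)
        vec = pd.Series(x, index=clin.index, name="G")
        fit = survival.fit_cox_univariate(vec, clin)
        grid = np.arange(-3, 3, 1e-3)
        lls = [efron_partial_loglik(b, times, events, x) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert fit.coef == pytest.approx(best, abs=1e-3)
        assert fit.ci_low <= fit.hr <= fit.ci_high

    def test_type_one_error_calibrated_under_null(self):
        rejections = 0
        n_runs = 60
        for seed in range(n_runs):
            expr = simulate.generate_expression(["G"], 300, 0, set(), 0.0, 0.0, seed=seed)
            clin = simulate.generate_survival(expr.samples, {"G": 0.0}, expr,
                                              censor_rate=5e-4, seed=seed + 1000)
            vec = expr.values.loc["G"].rename("G")
            if survival.fit_cox_univariate(vec, clin).p < 0.05:
                rejections += 1
        assert 0.0 <= rejections / n_runs <= 0.12

    def test_recovers_planted_binary_hazard_ratio(self):
        hrs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, size=300).astype(float)
            expr = ExpressionMatrix(values=pd.DataFrame(
                [x], index=["G"], columns=[f"S{i}" for i in range(300)]))
            clin = simulate.generate_survival(
                expr.samples, {"G": math.log(3)}, expr, censor_rate=5e-4,
                seed=seed + 500, center=False,
            )
            hrs.append(survival.fit_cox_univariate(expr.values.loc["G"].rename("G"), clin).hr)
        assert 2.4 <= float(np.median(hrs)) <= 3.8

    def test_constant_covariate_rejected(self):
        clin = _clin([1, 2, 3, 4], [1, 1, 1, 0])
        vec = pd.Series([1.0, 1, 1, 1], index=clin.index, name="G")
        with pytest.raises(ValueError, match="no information"):
            survival.fit_cox_univariate(vec, clin)

    def test_monotone_likelihood_flagged_not_raised(self):
        # perfect separation: all events in the high group
        clin = _clin([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0])
        vec = pd.Series([5.0, 5, 5, 0, 0, 0], index=clin.index, name="G")
        fit = survival.fit_cox_univariate(vec, clin)
        assert not fit.converged


class TestRiskScore:
    def test_hand_computed_linear_combination(self):
        expr = ExpressionMatrix(values=pd.DataFrame(
            {"P1": [2.0, 1.0]}, index=["G1", "G2"]))
        model = survival.RiskModel(genes=["G1", "G2"], coefs={"G1": 0.5, "G2": -0.2})
        assert survival.risk_score(model, expr)["P1"] == pytest.approx(0.8)

    def test_zero_coefficients_zero_scores(self):
        expr = ExpressionMatrix(values=pd.DataFrame(
            np.arange(6.0).reshape(2, 3), index=["G1", "G2"], columns=list("abc")))
        model = survival.RiskModel(genes=["G1", "G2"], coefs={"G1": 0.0, "G2": 0.0})
        assert (survival.risk_score(model, expr) == 0).all()

    def test_single_gene_identity(self):
        expr = ExpressionMatrix(values=pd.DataFrame(
            {"a": [3.0], "b": [7.0]}, index=["G1"]))
        model = survival.RiskModel(genes=["G1"], coefs={"G1": 1.0})
        scores = survival.risk_score(model, expr)
        assert scores.tolist() == [3.0, 7.0]

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        expr = ExpressionMatrix(values=pd.DataFrame(
            rng.normal(size=(3, 5)), index=["A", "B", "C"]))
        coefs = {"A": 0.3, "B": -1.2, "C": 0.8}
        s1 = survival.risk_score(survival.RiskModel(["A", "B", "C"], coefs), expr)
        s2 = survival.risk_score(survival.RiskModel(["C", "A", "B"], coefs), expr)
        assert np.allclose(s1, s2)

    def test_missing_expression_scores_nan(self):
        expr = ExpressionMatrix(values=pd.DataFrame(
            {"a": [1.0, np.nan], "b": [2.0, 3.0]}, index=["G1", "G2"]))
        model = survival.RiskModel(genes=["G1", "G2"], coefs={"G1": 1.0, "G2": 1.0})
        scores = survival.risk_score(model, expr)
        assert np.isnan(scores["a"]) and scores["b"] == 5.0


class TestStratifyByMean:
    def test_tie_at_mean_goes_low(self):
        groups = survival.stratify_by_mean(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert groups["c"] == "high"
        assert groups["a"] == groups["b"] == "low"

    def test_two_samples_split(self):
        groups = survival.stratify_by_mean(pd.Series([0.0, 10.0], index=list("ab")))
        assert groups.tolist() == ["low", "high"]

    def test_symmetric_scores_equal_groups(self):
        groups = survival.stratify_by_mean(pd.Series([-2.0, -1.0, 1.0, 2.0]))
        assert (groups == "high").sum() == 2

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            survival.stratify_by_mean(pd.Series([1.0, 1.0, 1.0]))


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        km = survival.kaplan_meier([5, 8, 12], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_two_events_product_limit(self):
        km = survival.kaplan_meier([1, 2], [1, 1])
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(0.5)
        assert lookup[2.0] == pytest.approx(0.0)

    def test_non_increasing_and_matches_empirical_without_censoring(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10, size=50)
        km = survival.kaplan_meier(times, np.ones(50, int))
        s = km["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()
        # with no censoring KM equals the empirical survival function
        for t, surv in zip(km["time"], s):
            assert surv == pytest.approx((times > t).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        stat, p = survival.logrank_test([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_four_subject_example(self):
        # group A events at 1, 2; group B censored at 3, 4
        # O_A = 2, E_A = 1/2 + 1/3 = 5/6, V = 1/4 + 2/9 = 17/36
        # chi2 = (7/6)^2 / (17/36) = 49/17
        stat, p = survival.logrank_test([1, 2], [1, 1], [3, 4], [0, 0])
        assert stat == pytest.approx(49 / 17, rel=1e-9)
        assert p == pytest.approx(float(stats.chi2.sf(49 / 17, 1)), rel=1e-9)

    def test_power_against_planted_hazard(self):
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            rng = np.random.default_rng(seed + 2000)
            t_a = rng.exponential(1.0, 200)
            t_b = rng.exponential(1 / 3, 200)  # hazard ratio 3
            _, p = survival.logrank_test(t_a, np.ones(200, int), t_b, np.ones(200, int))
            if p < 0.01:
                hits += 1
        assert hits / n_runs >= 0.95

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            survival.logrank_test([], [], [1, 2], [1, 1])


class TestCompareExpressionGroups:
    def test_exact_rank_sum_matches_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        stat, p = survival.compare_expression_groups(
            np.concatenate([x, y]), np.array(["a"] * 6 + ["b"] * 5)
        )
        # enumeration oracle: distribution of U over all 6-of-11 label splits
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)

        def u_stat(idx):
            r = ranks[list(idx)].sum()
            return r - 6 * 7 / 2

        observed = u_stat(range(6))
        n_extreme = 0
        combos = list(itertools.combinations(range(11), 6))
        mean_u = 6 * 5 / 2
        for c in combos:
            if abs(u_stat(c) - mean_u) >= abs(observed - mean_u) - 1e-12:
                n_extreme += 1
        assert p == pytest.approx(n_extreme / len(combos), abs=1e-12)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        labels = np.array(["n"] * 50 + ["t"] * 50)
        _, p = survival.compare_expression_groups(x, labels)
        assert p < 1e-3

    def test_null_p_uniformish_on_average(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            x = rng.normal(size=20)
            labels = np.array(["a"] * 10 + ["b"] * 10)
            ps.append(survival.compare_expression_groups(x, labels)[1])
        assert 0.4 < float(np.mean(ps)) < 0.6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            survival.compare_expression_groups([1, 2, 3, 4, 5.0], ["a", "a", "b", "b", "b"][:5])


class TestModulePrognosis:
    def _planted_cohort(self, seed, coefs):
        genes = [f"G{i}" for i in range(len(coefs))] + ["X1", "X2"]
        expr = simulate.generate_expression(genes, 250, 0, set(), 0.0, 0.0, seed=seed)
        risk = {f"G{i}": c for i, c in enumerate(coefs)}
        clin = simulate.generate_survival(expr.samples, risk, expr,
                                          censor_rate=5e-4, seed=seed + 100)
        return expr, clin

    def test_planted_signal_detected_in_most_seeds(self):
        hits = 0
        for seed in range(20):
            expr, clin = self._planted_cohort(seed, [0.6, 0.6, 0.6, -0.6])
            cohort = survival.module_prognosis([f"G{i}" for i in range(4)], expr, clin)
            if cohort.logrank_p < 0.05:
                hits += 1
        assert hits >= 18

    def test_single_noise_gene_calibrated(self):
        # with one gene the mean-split group assignment does not depend on
        # the fitted coefficient, so the log-rank test stays calibrated
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            expr, clin = self._planted_cohort(seed + 3000, [0.0])
            cohort = survival.module_prognosis(["G0"], expr, clin)
            if cohort.logrank_p < 0.05:
                hits += 1
        assert 0.005 <= hits / n_runs <= 0.12

    def test_subset_filter_and_errors(self):
        expr, clin = self._planted_cohort(7, [0.5, 0.5])
        cohort = survival.module_prognosis(["G0", "G1"], expr, clin,
                                           subset_filter={"subtype": "LumA"})
        assert set(cohort.groups.unique()) == {"high", "low"}
        with pytest.raises(ValueError, match="zero samples"):
            survival.module_prognosis(["G0"], expr, clin, subset_filter={"subtype": "nope"})
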