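"""Risk scoring and survival machinery against closed-form and external oracles."""

import numpy as np
import pandas as pd
import pytest

from dmegnet import (
    RiskModel,
    cox_univariate,
    km_estimate,
    logrank_test,
    make_expression,
    make_survival,
    maxstat_cutoff,
    risk_score,
    stability_select,
    td_auc,
    zscore,
)
from dmegnet.prognosis import assign_risk_groups, breslow_loglik

from conftest import pairwise_auc

PUBLISHED_SUM = -0.283  # hand sum of the ten published coefficients


@pytest.fixture(scope="module")
def published():
    return RiskModel.load_published()


class TestRiskScore:
    def test_zero_expression_scores_zero(self, published):
        expr = pd.DataFrame(0.0, index=published.genes, columns=["s1", "s2"])
        assert (risk_score(expr, published) == 0).all()

    def test_one_hot_returns_each_coefficient(self, published):
        expr = pd.DataFrame(np.eye(10), index=published.genes, columns=published.genes)
        scores = risk_score(expr, published)
        for gene in published.genes:
            assert scores[gene] == pytest.approx(published.coefficients[gene])

    def test_all_ones_returns_coefficient_sum(self, published):
        expr = pd.DataFrame(1.0, index=published.genes, columns=["s"])
        assert risk_score(expr, published)["s"] == pytest.approx(PUBLISHED_SUM)

    def test_linearity(self, published):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(size=(10, 4)), index=published.genes)
        y = pd.DataFrame(rng.normal(size=(10, 4)), index=published.genes)
        lhs = risk_score(2 * x + 3 * y, published)
        rhs = 2 * risk_score(x, published) + 3 * risk_score(y, published)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_missing_gene_named_in_error(self, published):
        expr = pd.DataFrame(
            1.0, index=[g for g in published.genes if g != "RP11-44K6.2"], columns=["s"]
        )
        with pytest.raises(KeyError, match="RP11-44K6.2"):
            risk_score(expr, published)


class TestZscore:
    def test_simple_example(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            zscore([2, 2, 2])

    def test_output_moments(self):
        z = zscore(np.random.default_rng(1).normal(3, 2, 100))
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1)


class TestKaplanMeier:
    def test_all_censored_survival_is_one(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.at([0.5, 2.5]).tolist() == [1.0, 1.0]

    def test_no_censoring_closed_form(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(curve.survival, [3 / 4, 1 / 2, 1 / 4, 0])

    def test_single_event(self):
        curve = km_estimate([5.0], [1])
        assert curve.at(5.0)[0] == 0.0

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 40)
        curve = km_estimate(t, np.ones(40, dtype=int))
        for tau in np.quantile(t, [0.2, 0.5, 0.9]):
            assert curve.at(tau)[0] == pytest.approx(np.mean(t > tau))

    def test_matches_lifelines_with_censoring(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        t = rng.exponential(5, 60)
        e = (rng.random(60) < 0.7).astype(int)
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for tau, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(float(kmf.predict(tau)), abs=1e-10)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
        e = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        g = np.array(["low"] * 4 + ["high"] * 4)
        res = logrank_test(t, e, g)
        assert res.chi2 == pytest.approx(0, abs=1e-12)

    def test_hand_tabulated_six_sample_dataset(self):
        # times/events: group1 = {1+, 3, 5}, group0 = {2, 4, 6}
        t = np.array([1, 3, 5, 2, 4, 6], dtype=float)
        e = np.array([0, 1, 1, 1, 1, 1])
        in1 = np.array([True, True, True, False, False, False])
        # hand O/E/V tabulation over event times 2,3,4,5,6:
        # t=2: n=5 n1=2 d=1 -> e1 += 2/5,  v += (2/5)(3/5)
        # t=3: n=4 n1=2 d=1 -> e1 += 1/2,  v += 1/4
        # t=4: n=3 n1=1 d=1 -> e1 += 1/3,  v += (1/3)(2/3)
        # t=5: n=2 n1=1 d=1 -> e1 += 1/2,  v += 1/4
        # t=6: n=1 n1=0 d=1 -> e1 += 0,    v += 0
        o1 = 2.0
        e1 = 2 / 5 + 1 / 2 + 1 / 3 + 1 / 2
        v = (2 / 5) * (3 / 5) + 1 / 4 + (1 / 3) * (2 / 3) + 1 / 4
        res = logrank_test(t, e, in1)
        assert res.observed1 == pytest.approx(o1)
        assert res.expected1 == pytest.approx(e1)
        assert res.variance == pytest.approx(v)
        assert res.chi2 == pytest.approx((o1 - e1) ** 2 / v)
        assert res.hr == pytest.approx(np.exp((o1 - e1) / v))

    def test_matches_lifelines_statistic(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(5)
        t = rng.exponential(4, 50)
        e = (rng.random(50) < 0.8).astype(int)
        g = rng.random(50) < 0.5
        res = logrank_test(t, e, g)
        ref = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_invariant_to_monotone_time_transform(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(4, 30)
        e = (rng.random(30) < 0.8).astype(int)
        g = rng.random(30) < 0.5
        res1 = logrank_test(t, e, g)
        res2 = logrank_test(np.exp(t / 5), e, g)
        assert res1.chi2 == pytest.approx(res2.chi2)

    def test_power_under_strong_hazard_ratio(self):
        """Hazard ratio 3 at n=200 is detected in nearly every replicate."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            g = np.repeat([0, 1], 100).astype(bool)
            rate = np.where(g, 3.0, 1.0)
            t = rng.exponential(1 / rate)
            res = logrank_test(t, np.ones(200, dtype=int), g)
            hits += res.p < 0.05
        assert hits >= 9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], np.array([True, True]))


class TestMaxstat:
    @staticmethod
    def _oracle_scan(scores, t, e, min_frac):
        """Independent exhaustive scan using the lifelines log-rank statistic."""
        from lifelines.statistics import logrank_test as ll_logrank

        s = np.asarray(scores, dtype=float)
        uniq = np.unique(s)
        best = None
        for cut in (uniq[:-1] + uniq[1:]) / 2:
            high = s > cut
            if high.sum() < min_frac * s.size or (~high).sum() < min_frac * s.size:
                continue
            chi2 = ll_logrank(t[high], t[~high], e[high], e[~high]).test_statistic
            if best is None or chi2 > best[1]:
                best = (cut, chi2)
        return best

    def test_separating_scores_put_cutoff_between_clusters(self):
        rng = np.random.default_rng(0)
        n = 40
        scores = np.concatenate([rng.uniform(0, 1, n // 2), rng.uniform(3, 4, n // 2)])
        t = np.concatenate([rng.exponential(10, n // 2), rng.exponential(1, n // 2)])
        cut, chi2 = maxstat_cutoff(scores, t, np.ones(n, dtype=int))
        # the chosen split reproduces the cluster split up to one sample
        assert np.sum((scores > cut) != (scores >= 3)) <= 1

    def test_matches_exhaustive_oracle_on_permutations(self):
        rng = np.random.default_rng(1)
        n = 25
        scores = rng.normal(size=n)
        t = rng.exponential(2, n)
        e = (rng.random(n) < 0.8).astype(int)
        for _ in range(5):
            perm = rng.permutation(n)
            got = maxstat_cutoff(scores, t[perm], e[perm], min_group_frac=0.1)
            want = self._oracle_scan(scores, t[perm], e[perm], 0.1)
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1], rel=1e-9)

    def test_half_split_forced_on_odd_n(self):
        rng = np.random.default_rng(2)
        n = 11
        scores = np.arange(n, dtype=float)
        t = rng.exponential(2, n)
        cut, _ = maxstat_cutoff(scores, t, np.ones(n, dtype=int), min_group_frac=0.45)
        assert cut == pytest.approx(4.5)  # only admissible midpoint: 5 vs 6

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            maxstat_cutoff(np.ones(12), np.arange(1, 13, dtype=float), np.ones(12, dtype=int))

    def test_group_assignment_is_strict(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert assign_risk_groups(scores, 2.0).tolist() == ["low", "low", "high"]


class TestCoxUnivariate:
    def test_matches_partial_likelihood_grid_search(self):
        rng = np.random.default_rng(3)
        n = 10
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * x))
        e = np.ones(n, dtype=int)
        fit = cox_univariate(x, t, e)
        grid = np.arange(-4, 4, 1e-4)
        lls = [breslow_loglik(b * x, t, e) for b in grid]
        assert fit.beta == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_matches_lifelines_without_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(4)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        e = (rng.random(n) < 0.8).astype(int)
        fit = cox_univariate(x, t, e)
        df = pd.DataFrame({"x": x, "t": t, "e": e})
        ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.beta == pytest.approx(float(ref.params_["x"]), rel=1e-5)
        assert fit.se == pytest.approx(float(ref.standard_errors_["x"]), rel=1e-4)

    def test_wald_ci_covers_null_for_independent_covariate(self):
        covered = 0
        n_rep = 30
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=60)
            t = rng.exponential(1, 60)
            fit = cox_univariate(x, t, np.ones(60, dtype=int))
            covered += fit.ci_low <= 1.0 <= fit.ci_high
        assert covered >= 24  # ~95% nominal coverage, 3-sigma slack

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate(np.ones(10), np.arange(1, 11, dtype=float), np.ones(10, dtype=int))


class TestTdAuc:
    def test_perfect_ranking_without_censoring(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(5, 30)
        scores = -t  # shorter survival = higher risk, perfectly ranked
        aucs = td_auc(scores, t, np.ones(30, dtype=int), [np.quantile(t, 0.5)])
        assert list(aucs.values())[0] == pytest.approx(1.0)

    def test_equals_pair_counting_without_censoring(self):
        rng = np.random.default_rng(6)
        n = 50
        t = rng.exponential(5, n)
        scores = rng.normal(size=n)
        tau = float(np.quantile(t, 0.4))
        auc = td_auc(scores, t, np.ones(n, dtype=int), [tau])[tau]
        assert auc == pytest.approx(pairwise_auc(scores, t <= tau))

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(7)
        n = 300
        t = rng.exponential(5, n)
        e = (rng.random(n) < 0.8).astype(int)
        scores = rng.normal(size=n)
        tau = float(np.quantile(t, 0.5))
        auc = td_auc(scores, t, e, [tau])[tau]
        assert abs(auc - 0.5) < 3 * 0.05

    def test_horizon_outside_range_rejected(self):
        with pytest.raises(ValueError):
            td_auc([1.0, 2.0], [1.0, 2.0], [1, 1], [5.0])


class TestStabilitySelect:
    @staticmethod
    def _prognostic_dataset(n=80, p=10, coef=1.2, seed=0):
        expr, _ = make_expression(n_genes=p, n_per_group=n // 2, lfc=0.0, n_up=0, n_down=0, sd=1.0, seed=seed)
        expr = expr.drop(index="PD1")
        surv, _ = make_survival(expr, {"G00000": coef}, baseline_rate=0.2, censor_rate=0.02, seed=seed + 1)
        return expr, surv

    def test_deterministic_under_fixed_seed(self):
        expr, surv = self._prognostic_dataset()
        f1 = stability_select(expr, surv, B=2, k_folds=3, seed=9)
        f2 = stability_select(expr, surv, B=2, k_folds=3, seed=9)
        assert f1.gene_counts == f2.gene_counts
        assert f1.combination_counts == f2.combination_counts

    def test_prognostic_gene_gets_top_count(self):
        expr, surv = self._prognostic_dataset(n=100, p=10, coef=1.2, seed=3)
        freq = stability_select(expr, surv, B=15, k_folds=3, seed=1)
        top = max(freq.gene_counts, key=freq.gene_counts.get)
        assert top == "G00000"
        assert "G00000" in freq.modal_combination

    def test_combination_counts_sum_to_B(self):
        expr, surv = self._prognostic_dataset(seed=5)
        freq = stability_select(expr, surv, B=4, k_folds=3, seed=2)
        assert sum(freq.combination_counts.values()) == 4
        assert all(c <= 4 for c in freq.gene_counts.values())

    def test_all_null_genes_no_dominant_combination(self):
        expr, surv = self._prognostic_dataset(n=80, p=10, coef=0.0, seed=7)
        freq = stability_select(expr, surv, B=12, k_folds=3, seed=4)
        nonempty = {c: k for c, k in freq.combination_counts.items() if c}
        if nonempty:
            assert max(nonempty.values()) < 0.5 * freq.B
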