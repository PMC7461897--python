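"""Self-implemented statistics against brute-force oracles and reference fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from itertools import combinations
from scipy import stats as sps
from scipy.optimize import minimize

import mmtraj as m


def enumerate_two_sided_p(x, y):
    """Independent enumeration of the symmetric two-sided exact p-value."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx, n = len(x), len(pooled)
    w = ranks[:nx].sum()
    mu = nx * (n + 1) / 2
    hits = total = 0
    for idx in combinations(range(n), nx):
        total += 1
        if abs(sum(ranks[i] for i in idx) - mu) >= abs(w - mu) - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxonRankSum:
    def test_textbook_exact_example(self):
        r = m.wilcoxon_rank_sum([1, 2], [3, 4], alternative="less")
        assert r.p_value == pytest.approx(1 / 6)

    def test_identical_samples_two_sided_p_is_one(self):
        r = m.wilcoxon_rank_sum([1, 2, 2, 5], [2, 1, 5, 2], mode="exact")
        assert r.p_value == pytest.approx(1.0)

    def test_one_sided_exact_matches_scipy_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 12 - nx))
            x = rng.integers(0, 6, nx).astype(float)
            y = rng.integers(0, 6, ny).astype(float)

            def stat(a, b):
                return sps.rankdata(np.concatenate([a, b]))[: len(a)].sum()

            for alt in ("greater", "less"):
                mine = m.wilcoxon_rank_sum(x, y, mode="exact", alternative=alt)
                ref = sps.permutation_test(
                    (x, y), stat, permutation_type="independent",
                    n_resamples=np.inf, alternative=alt,
                )
                assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(4)
        diffs = []
        for _ in range(100):
            nx = int(rng.integers(8, 10))
            ny = 18 - nx
            x = rng.normal(size=nx).round(1)
            y = rng.normal(size=ny).round(1)
            pe = m.wilcoxon_rank_sum(x, y, mode="exact").p_value
            pn = m.wilcoxon_rank_sum(x, y, mode="normal").p_value
            diffs.append(abs(pe - pn))
        assert max(diffs) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            m.wilcoxon_rank_sum([], [1.0])


class TestMannKendall:
    def test_monotone_sequence_counts_all_pairs(self):
        assert m.mann_kendall([1, 2, 3, 4]).statistic == 6

    def test_constant_sequence_no_trend(self):
        r = m.mann_kendall([5, 5, 5, 5])
        assert r.statistic == 0 and r.p_value == 1.0

    def test_matches_bruteforce_pairwise_count(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.integers(0, 5, size=int(rng.integers(3, 12))).astype(float)
            s = sum(
                np.sign(x[j] - x[i])
                for i in range(len(x))
                for j in range(i + 1, len(x))
            )
            assert m.mann_kendall(x).statistic == s

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.integers(min_value=-5, max_value=5), min_size=3, max_size=12)
    )
    def test_antisymmetry_under_reversal(self, seq):
        fwd = m.mann_kendall(seq)
        rev = m.mann_kendall(seq[::-1])
        assert fwd.statistic == -rev.statistic
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            m.mann_kendall([1, 2])


class TestCoxPH:
    def make_data(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        x1 = rng.binomial(1, 0.4, n).astype(float)
        x2 = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.7 * x1 - 0.3 * x2), n)
        e = (t < 2.0).astype(int)
        return np.minimum(t, 2.0), e, np.column_stack([x1, x2])

    def test_matches_lifelines_untied(self):
        from lifelines import CoxPHFitter

        t, e, X = self.make_data()
        fit = m.cox_ph(t, e, X, names=["x1", "x2"])
        df = pd.DataFrame({"t": t, "e": e, "x1": X[:, 0], "x2": X[:, 1]})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.params.values, ref.params_.values, atol=1e-4)
        assert np.allclose(fit.se().values, ref.standard_errors_.values, atol=1e-4)

    def test_matches_statsmodels_breslow_with_ties(self):
        from statsmodels.duration.hazard_regression import PHReg

        t, e, X = self.make_data(seed=1)
        t = np.round(t, 1)  # induce heavy ties
        fit = m.cox_ph(t, e, X)
        ref = PHReg(t, X, status=e, ties="breslow").fit()
        assert np.allclose(fit.params.values, ref.params, atol=1e-6)

    def test_coefficient_maximizes_partial_likelihood_on_grid(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        model = m.CoxPH(time, event, x[:, None])
        beta = model.fit().params.iloc[0]
        best = model.loglik([beta])
        grid = beta + np.linspace(-2, 2, 101)
        assert all(model.loglik([b]) <= best + 1e-10 for b in grid)

    def test_constant_exposure_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            m.cox_ph([1, 2, 3], [1, 1, 0], np.ones((3, 1)))

    def test_separated_design_reported(self):
        # exposed all fail before any unexposed: monotone likelihood
        t = np.r_[np.arange(1, 6), np.arange(10, 15)].astype(float)
        e = np.ones(10, dtype=int)
        x = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(m.ConvergenceError, match="separation"):
            m.cox_ph(t, e, x[:, None])

    def test_two_group_exponential_recovers_rate_ratio(self):
        rng = np.random.default_rng(7)
        n = 10_000
        x = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(1 / np.exp(np.log(2) * x))
        fit = m.cox_ph(t, np.ones(n, dtype=int), x[:, None])
        assert 1.85 <= float(np.exp(fit.params.iloc[0])) <= 2.15


class TestPoissonRR:
    def test_saturated_model_reduces_to_risk_ratio(self):
        y = np.r_[np.ones(10), np.zeros(90), np.ones(5), np.zeros(95)]
        x = np.r_[np.ones(100), np.zeros(100)]
        fit = m.poisson_rr(y, np.column_stack([np.ones(200), x]),
                           names=["const", "exposed"])
        assert np.exp(fit.params["exposed"]) == pytest.approx(2.0, abs=1e-10)

    def test_matches_direct_likelihood_maximization(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(12), rng.integers(0, 2, 12),
                             rng.normal(size=12)])
        y = rng.poisson(np.exp(0.2 + 0.5 * X[:, 1] - 0.3 * X[:, 2]))

        def negll(beta):
            mu = np.exp(X @ beta)
            return -(y * np.log(mu) - mu).sum()

        ref = minimize(negll, np.zeros(3), method="BFGS",
                       options={"gtol": 1e-10}).x
        fit = m.poisson_rr(y, X)
        assert np.allclose(fit.params.values, ref, atol=1e-6)

    def test_matches_statsmodels_hc0(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(200), rng.binomial(1, 0.3, 200)])
        y = rng.binomial(1, 0.1 + 0.1 * X[:, 1])
        fit = m.poisson_rr(y, X)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC0")
        assert np.allclose(fit.params.values, ref.params, atol=1e-8)
        assert np.allclose(fit.se(robust=True).values, ref.bse, atol=1e-8)

    def test_sandwich_collapses_to_model_variance_when_equidispersed(self):
        # within each covariate pattern, sum (y - mean)^2 == sum mean exactly:
        # pattern A has y = {0, 2} (mean 1), pattern B has y = {2, 6} (mean 4)
        y = np.array([0.0, 2.0, 2.0, 6.0])
        X = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        fit = m.poisson_rr(y, X)
        assert np.allclose(fit.cov_robust.values, fit.cov.values, atol=1e-10)

    def test_frequency_weights_equal_expanded_rows(self):
        y = np.array([1, 0, 1, 0])
        x = np.array([1.0, 1.0, 0.0, 0.0])
        w = np.array([10, 90, 5, 95])
        X = np.column_stack([np.ones(4), x])
        agg = m.poisson_rr(y, X, freq_weights=w)
        y_full = np.repeat(y, w)
        X_full = np.repeat(X, w, axis=0)
        full = m.poisson_rr(y_full, X_full)
        assert np.allclose(agg.params.values, full.params.values, atol=1e-10)
        assert np.allclose(agg.cov_robust.values, full.cov_robust.values, atol=1e-10)

    def test_all_zero_outcome_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            m.poisson_rr(np.zeros(5), np.ones((5, 1)))


class TestBenjaminiHochberg:
    def test_stepup_rule_by_hand(self):
        reject, _ = m.benjamini_hochberg([0.01, 0.02, 0.03, 0.04, 0.05], q=0.05)
        assert reject.all()

    def test_single_large_p(self):
        reject, qv = m.benjamini_hochberg([0.5], q=0.05)
        assert not reject.any() and qv[0] == pytest.approx(0.5)

    def test_matches_bruteforce_max_index_definition(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            q = 0.05
            reject, _ = m.benjamini_hochberg(p, q=q)
            order = np.argsort(p)
            ranked = p[order]
            k = 0
            for i in range(1, len(p) + 1):
                if ranked[i - 1] <= i * q / len(p):
                    k = i
            expected = np.zeros(len(p), dtype=bool)
            expected[order[:k]] = True
            assert np.array_equal(reject, expected)

    def test_qvalues_match_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        p = rng.random(60)
        reject, qv = m.benjamini_hochberg(p, q=0.1)
        ref_rej, ref_q, _, _ = multipletests(p, alpha=0.1, method="fdr_bh")
        assert np.array_equal(reject, ref_rej)
        assert np.allclose(qv, ref_q, atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                 min_size=1, max_size=30)
    )
    def test_rejections_superset_of_bonferroni(self, pvals):
        q = 0.05
        reject, _ = m.benjamini_hochberg(pvals, q=q)
        bonf = np.asarray(pvals) <= q / len(pvals)
        assert np.all(reject | ~bonf)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            m.benjamini_hochberg([0.5], q=1.5)
        with pytest.raises(ValueError):
            m.benjamini_hochberg([1.5], q=0.05)
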