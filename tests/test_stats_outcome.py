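import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methage.stats_outcome import (
    adonis,
    cmh_test,
    cox_interaction_fit,
    pca,
    two_way_wald_table,
    variation_partition,
    wald_hc3,
)
from methage.synthetic import SurvivalParams, simulate_survival


class TestPca:
    def test_trace_conservation(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 2, (30, 8)))
        res = pca(X)
        assert res.eigenvalues.sum() == pytest.approx(
            X.var(axis=0, ddof=1).sum(), abs=1e-8
        )
        assert (np.diff(res.eigenvalues) <= 1e-10).all()

    def test_rank_one_single_eigenvalue(self):
        rng = np.random.default_rng(1)
        u, v = rng.normal(size=20), rng.normal(size=5)
        res = pca(pd.DataFrame(np.outer(u, v)))
        assert res.eigenvalues[0] > 1e-8
        assert np.all(res.eigenvalues[1:] < 1e-10)

    def test_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (25, 10)), rng.normal(4, 1, (25, 10))])
        res = pca(pd.DataFrame(X))
        scores = res.scores["PC1"].to_numpy()
        labels = np.array([0] * 25 + [1] * 25)
        # AUC of PC1 scores for the two clusters
        ranks = stats.rankdata(scores)
        auc = (ranks[labels == 1].sum() - 25 * 26 / 2) / (25 * 25)
        assert max(auc, 1 - auc) > 0.95


class TestAdonis:
    def test_equals_anova_r2_univariate(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 40)
        g = np.repeat(["a", "b", "c", "d"], 10)
        res = adonis(y[:, None], g, n_perm=49, seed=0)
        gm = y.mean()
        ssb = sum(
            len(y[g == lv]) * (y[g == lv].mean() - gm) ** 2 for lv in "abcd"
        )
        sst = ((y - gm) ** 2).sum()
        assert res.r2 == pytest.approx(ssb / sst, abs=1e-10)

    def test_identical_groups_zero_r2(self):
        y = np.tile(np.arange(5.0), 2)[:, None]
        g = np.repeat(["a", "b"], 5)
        assert adonis(y, g, n_perm=49, seed=0).r2 == pytest.approx(0.0, abs=1e-12)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(1)
        hits = 0
        reps = 500
        for k in range(reps):
            y = rng.normal(0, 1, (24, 2))
            g = np.repeat(["a", "b"], 12)
            if adonis(y, g, n_perm=199, seed=k).p < 0.05:
                hits += 1
        assert 0.03 <= hits / reps <= 0.07

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (20, 3))
        g = np.repeat(["a", "b"], 10)
        D = stats.distance_matrix if False else None
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(X))
        r1 = adonis(D, g, n_perm=9, seed=0, is_distance=True).r2
        r2 = adonis(3.7 * D, g, n_perm=9, seed=0, is_distance=True).r2
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            adonis(np.zeros((4, 1)), ["a"] * 4, n_perm=9)

    def test_matches_skbio_permanova_pseudo_f(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (15, 4)), rng.normal(1, 1, (15, 4))])
        g = np.repeat(["a", "b"], 15)
        from scipy.spatial.distance import pdist, squareform

        dm = skbio.DistanceMatrix(squareform(pdist(X)))
        ref = skbio.stats.distance.permanova(dm, g, permutations=9)
        res = adonis(X, g, n_perm=9, seed=0)
        assert res.f == pytest.approx(ref["test statistic"], rel=1e-10)


class TestVariationPartition:
    @staticmethod
    def _orthogonal_blocks(n=64, seed=0):
        rng = np.random.default_rng(seed)
        # orthogonal designs via a QR factorization
        Q, _ = np.linalg.qr(rng.normal(size=(n, 3)))
        a, b, c = Q.T
        a, b, c = a - a.mean(), b - b.mean(), c - c.mean()
        # re-orthogonalize after centering
        b -= a * (a @ b) / (a @ a)
        c -= a * (a @ c) / (a @ a) + b * (b @ c) / (b @ b)
        y = 2 * a + 1 * b + 0.5 * c + 0.05 * rng.normal(size=n)
        Y = pd.DataFrame({"y": y})
        return Y, pd.Series(a, index=Y.index), pd.Series(b, index=Y.index), pd.Series(c, index=Y.index)

    def test_orthogonal_blocks_no_shared_fractions(self):
        Y, a, b, c = self._orthogonal_blocks()
        res = variation_partition(Y, a, b, c, adjusted=False)
        for key in ("AB", "BC", "AC", "ABC"):
            assert abs(res.fractions[key]) < 1e-8
        assert res.fractions["A"] == pytest.approx(res.r2_models["A"], abs=1e-8)

    def test_duplicated_block_is_fully_shared(self):
        Y, a, b, c = self._orthogonal_blocks(seed=1)
        res = variation_partition(Y, c, b, c, adjusted=False)
        assert abs(res.fractions["A"]) < 1e-8
        assert abs(res.fractions["C"]) < 1e-8
        assert res.fractions["AC"] + res.fractions["ABC"] == pytest.approx(
            res.r2_models["C"], abs=1e-8
        )

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        Y = pd.DataFrame(rng.normal(size=(40, 3)))
        a = pd.Series(rng.normal(size=40), index=Y.index)
        b = pd.Series(rng.choice(["u", "v"], 40), index=Y.index)
        c = pd.Series(rng.normal(size=40), index=Y.index)
        res = variation_partition(Y, a, b, c, adjusted=False)
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-10)

    def test_block_order_permutation_invariance(self):
        Y, a, b, c = self._orthogonal_blocks(seed=3)
        r1 = variation_partition(Y, a, b, c, adjusted=False)
        r2 = variation_partition(Y, b, a, c, adjusted=False)
        assert r1.fractions["A"] == pytest.approx(r2.fractions["B"], abs=1e-10)
        assert r1.fractions["ABC"] == pytest.approx(r2.fractions["ABC"], abs=1e-10)


class TestWaldHc3:
    def test_hand_computed_covariance_tiny(self):
        # n=6, intercept + one slope, elementwise HC3 oracle
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 1.5, 4.0, 3.0, 6.0])
        X = np.column_stack([np.ones(6), x])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        e = y - X @ beta
        h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
        omega = np.diag(e**2 / (1 - h) ** 2)
        cov_oracle = XtX_inv @ X.T @ omega @ X @ XtX_inv

        import statsmodels.api as sm

        fit = sm.OLS(y, sm.add_constant(pd.DataFrame({"x": x}))).fit(cov_type="HC3")
        assert np.abs(np.asarray(fit.cov_params()) - cov_oracle).max() < 1e-10

        f, p = wald_hc3(y, pd.DataFrame({"x": x}), "x")
        f_oracle = beta[1] ** 2 / cov_oracle[1, 1]
        assert f == pytest.approx(f_oracle, rel=1e-10)

    def test_agrees_with_classical_f_homoscedastic(self):
        rng = np.random.default_rng(0)
        n = 2000
        x = rng.normal(size=n)
        y = 0.5 + 0.2 * x + rng.normal(size=n)
        f_hc3, _ = wald_hc3(y, pd.DataFrame({"x": x}), "x")
        import statsmodels.api as sm

        classical = sm.OLS(y, sm.add_constant(x)).fit()
        f_classical = classical.tvalues[1] ** 2
        assert abs(f_hc3 - f_classical) / f_classical < 0.1

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        hits, reps = 0, 500
        for _ in range(reps):
            x = rng.normal(size=60)
            z = rng.normal(size=60)
            y = 1.0 + 0.5 * z + rng.normal(size=60)
            _, p = wald_hc3(y, pd.DataFrame({"x": x, "z": z}), "x")
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.08

    def test_rank_deficient_raises(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="rank"):
            wald_hc3(x, pd.DataFrame({"a": x, "b": 2 * x}), "a")

    def test_two_way_table_structure(self):
        rng = np.random.default_rng(2)
        n = 90
        a = pd.Series(rng.choice(["MES", "RTK_I", "RTK_II"], n))
        b = pd.Series(rng.choice(["s1", "s2"], n), index=a.index)
        y = pd.Series(rng.normal(size=n) + (a == "RTK_II") * 2.0, index=a.index)
        tab = two_way_wald_table(y, a, b, names=("Class", "Study"))
        assert list(tab.index) == ["Class", "Study", "Class x Study"]
        assert tab.loc["Class", "Pr(>F)"] < 0.001
        assert tab.loc["Study", "Pr(>F)"] > 0.01


class TestCox:
    def test_null_covariate_recovery(self):
        rng = np.random.default_rng(0)
        params = SurvivalParams(log_hr_accel_per_year=0.0)
        covered, close = 0, 0
        reps = 200
        for _ in range(reps):
            n = 500
            trt = rng.integers(0, 2, n)
            mg = rng.integers(0, 2, n)
            cov = rng.normal(0, 1, n)
            t, e, _ = simulate_survival(trt, mg, cov * 0, params, rng)
            fit = cox_interaction_fit(t, e, trt, mg, cov)
            hr = fit.hr("covariate")
            se = fit.summary.loc["covariate", "se"]
            lo, hi = np.exp(np.log(hr) - 1.96 * se), np.exp(np.log(hr) + 1.96 * se)
            covered += lo <= 1.0 <= hi
            close += abs(hr - 1.0) < 0.1
        assert covered / reps >= 0.93
        assert close / reps >= 0.93

    def test_acceleration_hr_recovery(self):
        rng = np.random.default_rng(1)
        params = SurvivalParams()  # log HR -0.0147/year of acceleration
        hrs = []
        for _ in range(200):
            n = 400
            trt = rng.integers(0, 2, n)
            mg = rng.integers(0, 2, n)
            accel = rng.normal(36.8, 24.0, n)
            t, e, _ = simulate_survival(trt, mg, accel, params, rng)
            hrs.append(cox_interaction_fit(t, e, trt, mg, accel).hr("covariate"))
        assert 0.98 <= float(np.mean(hrs)) <= 0.99

    def test_interaction_power(self):
        rng = np.random.default_rng(2)
        params = SurvivalParams(log_hr_interaction=-1.3)
        sig = 0
        reps = 100
        for _ in range(reps):
            n = 600
            trt = rng.integers(0, 2, n)
            mg = rng.integers(0, 2, n)
            accel = rng.normal(36.8, 24.0, n)
            t, e, _ = simulate_survival(trt, mg, accel, params, rng)
            fit = cox_interaction_fit(t, e, trt, mg, accel)
            sig += fit.p("treatment_x_mgmt") < 0.05
        assert sig / reps >= 0.8

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="events"):
            cox_interaction_fit(
                np.ones(20), np.zeros(20), np.zeros(20), np.zeros(20), np.zeros(20)
            )

    def test_monotone_partial_likelihood(self):
        # the fitted model's log partial likelihood beats the null model's
        rng = np.random.default_rng(3)
        n = 300
        trt = rng.integers(0, 2, n)
        mg = rng.integers(0, 2, n)
        accel = rng.normal(36.8, 24.0, n)
        t, e, _ = simulate_survival(trt, mg, accel, SurvivalParams(), rng)
        from lifelines import CoxPHFitter

        df = pd.DataFrame(
            {"time": t, "event": e, "treatment": trt, "mgmt": mg,
             "covariate": accel, "treatment_x_mgmt": trt * mg}
        )
        cph = CoxPHFitter().fit(df, "time", "event")
        lr = cph.log_likelihood_ratio_test()
        assert lr.test_statistic >= -1e-8  # fitted ll never below the null ll


class TestCmh:
    def test_single_stratum_closed_form(self):
        t = np.array([[12.0, 5.0], [6.0, 13.0]])
        stat, p = cmh_test([t])
        n = t.sum()
        a = t[0, 0]
        ea = t[0].sum() * t[:, 0].sum() / n
        va = (
            t[0].sum() * t[1].sum() * t[:, 0].sum() * t[:, 1].sum()
            / (n**2 * (n - 1))
        )
        stat_oracle = (a - ea) ** 2 / va
        assert stat == pytest.approx(stat_oracle, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(stat_oracle, 1), abs=1e-12)

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        hits, reps = 0, 400
        for _ in range(reps):
            tables = []
            for _ in range(3):
                x = rng.integers(0, 2, 40)
                y = rng.integers(0, 2, 40)
                tab = np.array(
                    [
                        [np.sum((x == 1) & (y == 1)), np.sum((x == 1) & (y == 0))],
                        [np.sum((x == 0) & (y == 1)), np.sum((x == 0) & (y == 0))],
                    ],
                    dtype=float,
                )
                tables.append(tab)
            _, p = cmh_test(tables)
            hits += p < 0.05
        assert 0.02 <= hits / reps <= 0.08

    def test_degenerate_stratum_skipped(self):
        good = np.array([[10.0, 5.0], [5.0, 10.0]])
        bad = np.array([[7.0, 0.0], [3.0, 0.0]])  # zero column margin
        with pytest.warns(UserWarning, match="zero margin"):
            stat, _ = cmh_test([good, bad])
        stat_solo, _ = cmh_test([good])
        assert stat == pytest.approx(stat_solo, abs=1e-12)

    def test_all_degenerate_raises(self):
        bad = np.array([[5.0, 0.0], [3.0, 0.0]])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                cmh_test([bad])
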