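import numpy as np
import pytest
from scipy import stats

from mrsplit import (SimConfig, classify_ivs, debiased_lasso_select,
                     lasso_select, partial_f, select_ivs, simulate_dataset,
                     sis_screen)
from mrsplit.iv_selection import partial_f_all


class TestSISScreen:
    def test_exposure_equal_to_one_column(self, rng):
        G = rng.binomial(2, 0.3, (50, 6)).astype(float)
        idx = sis_screen(G[:, 4].copy(), G, keep=1)
        assert list(idx) == [4]

    def test_keep_all_orders_by_correlation(self, rng):
        G = rng.binomial(2, 0.3, (200, 5)).astype(float)
        x = rng.normal(size=200)
        idx = sis_screen(x, G, keep=5)
        r = [abs(np.corrcoef(x, G[:, j])[0, 1]) for j in range(5)]
        assert list(idx) == sorted(range(5), key=lambda j: (-r[j], j))

    def test_matches_marginal_regression_ranking(self):
        """Oracle: rank SNPs by |t| from p separate marginal OLS fits."""
        cfg = SimConfig(n=400, h2=0.5, rho=0.0, beta=0.0, p_snps=50, seed=3)
        data, truth = simulate_dataset(cfg)
        x, G = data.exposure, data.genotypes
        tstats = []
        for j in range(G.shape[1]):
            Z = np.column_stack([np.ones(len(x)), G[:, j]])
            coef, *_ = np.linalg.lstsq(Z, x, rcond=None)
            r = x - Z @ coef
            s2 = r @ r / (len(x) - 2)
            se = np.sqrt(s2 * np.linalg.inv(Z.T @ Z)[1, 1])
            tstats.append(abs(coef[1] / se))
        oracle = sorted(range(50), key=lambda j: (-tstats[j], j))[:25]
        got = sis_screen(x, G, keep=25)
        assert set(got) == set(oracle)
        assert set(truth.causal_indices) <= set(got)

    def test_zero_variance_columns_excluded(self, rng):
        G = rng.binomial(2, 0.3, (50, 4)).astype(float)
        G[:, 2] = 1.0
        idx = sis_screen(rng.normal(size=50), G, keep=4)
        assert 2 not in idx and len(idx) == 3

    def test_keep_larger_than_p_rejected(self, rng):
        G = rng.binomial(2, 0.3, (20, 3)).astype(float)
        with pytest.raises(ValueError):
            sis_screen(rng.normal(size=20), G, keep=4)


class TestLassoSelect:
    def test_noiseless_single_column_recovery(self, rng):
        G = rng.binomial(2, 0.3, (100, 1)).astype(float)
        idx, coef = lasso_select(G[:, 0].copy(), G, seed=0)
        assert list(idx) == [0]
        assert coef[0] == pytest.approx(1.0, abs=0.05)

    def test_null_design_selects_sparsely(self):
        """Under alpha = 0 the CV-chosen penalty keeps selection far from
        saturating the candidate set."""
        frac = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            G = rng.binomial(2, 0.3, (120, 40)).astype(float)
            x = rng.normal(size=120)
            idx, _ = lasso_select(x, G, seed=seed)
            frac.append(len(idx) / 40)
        assert np.mean(frac) < 0.5

    def test_strong_snps_selected_under_scenario_design(self):
        """The two largest-share causal SNPs are picked in nearly every
        replicate of the unequal-effects design at h2 = 0.3."""
        hits = 0
        reps = 40
        for seed in range(reps):
            data, truth = simulate_dataset(
                SimConfig(n=1000, h2=0.3, rho=0.0, beta=0.0, seed=seed))
            scr = sis_screen(data.exposure, data.genotypes, 250)
            idx, _ = lasso_select(data.exposure, data.genotypes[:, scr], seed=seed)
            chosen = set(scr[idx])
            hits += {0, 1} <= chosen
        assert hits / reps > 0.95

    def test_seeded_folds_reproducible(self, toy_data):
        a = lasso_select(toy_data.exposure, toy_data.genotypes, seed=5)
        b = lasso_select(toy_data.exposure, toy_data.genotypes, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_allclose(a[1], b[1])


class TestDebiasedLasso:
    def test_matches_ols_pvalues_in_orthogonal_lowdim_design(self, rng):
        """Oracle: with few, nearly orthogonal columns the desparsified
        estimates and p-values approach exact OLS inference."""
        n, p = 300, 6
        G = rng.binomial(2, 0.3, (n, p)).astype(float)
        x = 0.5 * G[:, 2] + rng.normal(size=n)
        idx, eff, pv = debiased_lasso_select(x, G, p_threshold=0.05, seed=0)
        assert 2 in idx
        j = list(idx).index(2)
        # OLS oracle
        Z = np.column_stack([np.ones(n), G])
        coef, *_ = np.linalg.lstsq(Z, x, rcond=None)
        r = x - Z @ coef
        s2 = r @ r / (n - p - 1)
        se = np.sqrt(s2 * np.linalg.inv(Z.T @ Z)[3, 3])
        assert eff[j] == pytest.approx(coef[3], abs=3 * se)
        assert pv[j] < 1e-3
        assert pv[j] == min(pv)

    def test_null_retention_near_threshold_rate(self):
        """Type-I calibration: the retained fraction under the global null
        stays near the p-value threshold."""
        retained = []
        for seed in range(25):
            rng = np.random.default_rng(seed + 1000)
            G = rng.binomial(2, 0.3, (150, 30)).astype(float)
            x = rng.normal(size=150)
            idx, _, _ = debiased_lasso_select(x, G, p_threshold=0.05, seed=seed)
            retained.append(len(idx) / 30)
        assert np.mean(retained) == pytest.approx(0.05, abs=0.05)

    def test_agrees_with_lasso_on_strong_signal(self, rng):
        n, p = 400, 20
        G = rng.binomial(2, 0.3, (n, p)).astype(float)
        x = 0.9 * G[:, 3] + 0.7 * G[:, 11] + rng.normal(size=n)
        li, lc = lasso_select(x, G, seed=1)
        di, dc, _ = debiased_lasso_select(x, G, seed=1)
        top_l = set(np.asarray(li)[np.argsort(-np.abs(lc))][:2])
        top_d = set(np.asarray(di)[np.argsort(-np.abs(dc))][:2])
        assert top_l == top_d == {3, 11}

    def test_screened_dim_must_stay_below_n(self, rng):
        G = rng.binomial(2, 0.3, (20, 25)).astype(float)
        with pytest.raises(ValueError, match="keep"):
            debiased_lasso_select(rng.normal(size=20), G)


class TestPartialF:
    def test_duplicated_column_gives_zero_f(self, rng):
        G = rng.binomial(2, 0.3, (40, 2)).astype(float)
        Gs = np.column_stack([G[:, 0], G[:, 1], G[:, 0]])
        x = G @ [0.5, 0.3] + rng.normal(size=40)
        res = partial_f(x, Gs, target=2)
        assert res.f_value == pytest.approx(0.0, abs=1e-8)
        assert res.rss_reduced == pytest.approx(res.rss_full, rel=1e-10)

    def test_matches_two_explicit_ols_fits(self):
        """Oracle: direct normal-equations solve of full and reduced models
        on a tiny fixture."""
        x = np.array([1.2, 0.8, 2.5, 1.9, 3.1, 2.2, 0.4, 1.7])
        Gs = np.array([[0, 1], [1, 0], [2, 1], [1, 1],
                       [2, 2], [1, 2], [0, 0], [2, 0]], dtype=float)

        def rss(y, X):
            Z = np.column_stack([np.ones(len(y)), X])
            b = np.linalg.solve(Z.T @ Z, Z.T @ y)
            r = y - Z @ b
            return r @ r

        rss_f, rss_r = rss(x, Gs), rss(x, Gs[:, [1]])
        expected = (rss_r - rss_f) / (rss_f / (8 - 2 - 1))
        res = partial_f(x, Gs, target=0)
        assert res.f_value == pytest.approx(expected, rel=1e-12)

    def test_single_iv_equals_squared_t(self, rng):
        G = rng.binomial(2, 0.3, (60, 1)).astype(float)
        x = 0.4 * G[:, 0] + rng.normal(size=60)
        res = partial_f(x, G, target=0)
        t = stats.linregress(G[:, 0], x)
        assert res.f_value == pytest.approx((t.slope / t.stderr) ** 2, rel=1e-9)

    def test_vectorized_agrees_with_per_target(self, rng):
        G = rng.binomial(2, 0.3, (80, 6)).astype(float)
        x = G @ rng.normal(size=6) + rng.normal(size=80)
        fa = partial_f_all(x, G)
        fb = [partial_f(x, G, j).f_value for j in range(6)]
        np.testing.assert_allclose(fa, fb, rtol=1e-9, atol=1e-9)

    def test_scale_and_location_free_in_exposure(self, rng):
        G = rng.binomial(2, 0.3, (50, 3)).astype(float)
        x = G @ [0.5, 0.2, 0.1] + rng.normal(size=50)
        f1 = partial_f(x, G, 1).f_value
        f2 = partial_f(7.3 * x - 2.1, G, 1).f_value
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_too_many_ivs_rejected(self, rng):
        G = rng.binomial(2, 0.3, (6, 5)).astype(float)
        with pytest.raises(ValueError, match="instruments"):
            partial_f(rng.normal(size=6), G, 0)


class TestClassifyIVs:
    def test_boundary_straddle(self):
        sel = classify_ivs(np.array([10, 20]), np.array([0.5, 0.4]),
                           np.array([31.0, 29.0]), f_threshold=30.0)
        assert list(sel.major) == [10] and list(sel.weak) == [20]

    def test_all_weak_is_valid(self):
        sel = classify_ivs(np.array([1, 2, 3]), np.ones(3),
                           np.array([5.0, 12.0, 29.9]), f_threshold=30.0)
        assert len(sel.major) == 0 and len(sel.weak) == 3

    def test_threshold_monotonicity(self, rng):
        selected = np.arange(8)
        f = rng.uniform(0, 60, size=8)
        major50 = set(classify_ivs(selected, np.ones(8), f, 50.0).major)
        major10 = set(classify_ivs(selected, np.ones(8), f, 10.0).major)
        assert major50 <= major10


def test_select_ivs_pipeline_on_strong_signal(toy_data):
    sel = select_ivs(toy_data.exposure, toy_data.genotypes, seed=1)
    assert {2, 7} <= set(sel.selected)
    assert set(sel.major) | set(sel.weak) == set(sel.selected)
    assert len(sel.alpha_hat) == len(sel.partial_f) == sel.n_selected
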