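import numpy as np
import pytest

from comsiakit import field_contributions, field_scan, loo_q2, pls_fit
from comsiakit.pls import PLSError, fit_combo, regression_summary


def _random_instance(seed, n=10, p=6, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + 1.5 + noise * rng.normal(size=n)
    return X, y


class TestPLSFit:
    def test_exact_single_column(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        X = x[:, None]
        y = 3.0 * x + 2.0
        model = pls_fit(X, y, 1)
        assert model.r2 == pytest.approx(1.0)
        assert model.see == pytest.approx(0.0, abs=1e-10)

    def test_rank2_target_in_column_space(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(9, 2))
        X = np.hstack([base, base @ rng.normal(size=(2, 3))])  # rank 2
        y = base @ [1.0, -2.0] + 0.5
        model = pls_fit(X, y, 2)
        assert np.max(np.abs(model.fitted - y)) < 1e-8

    def test_full_rank_equals_ols(self):
        X, y = _random_instance(2)
        model = pls_fit(X, y, 6)
        X1 = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.solve(X1.T @ X1, X1.T @ y)  # normal-equations oracle
        np.testing.assert_allclose(model.coef, beta[1:], atol=1e-6)
        np.testing.assert_allclose(model.predict(X), X1 @ beta, atol=1e-6)

    def test_matches_sklearn_nipals(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_instance(3, n=15, p=8, noise=0.5)
        model = pls_fit(X, y, 3)
        sk = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y[:, None])
        np.testing.assert_allclose(model.predict(X), sk.predict(X).ravel(), atol=1e-8)

    def test_component_cap_warns(self):
        X, y = _random_instance(4, n=5, p=3)
        with pytest.warns(UserWarning, match="capped"):
            model = pls_fit(X, y, 10)
        assert model.n_components <= 3

    def test_column_order_and_zero_column_invariance(self):
        X, y = _random_instance(5)
        base = pls_fit(X, y, 3).predict(X)
        perm = np.random.default_rng(5).permutation(X.shape[1])
        permuted = pls_fit(X[:, perm], y, 3).predict(X[:, perm])
        np.testing.assert_allclose(permuted, base, atol=1e-9)
        Xz = np.hstack([X, np.zeros((len(y), 1))])
        np.testing.assert_allclose(pls_fit(Xz, y, 3).predict(Xz), base, atol=1e-9)


class TestLOO:
    def test_noiseless_q2_near_one(self):
        X, y = _random_instance(6, n=14, p=4)
        res = loo_q2(X, y, n_max=4)
        assert res.q2_opt >= 0.999

    def test_permuted_targets_give_nonpositive_median_q2(self):
        q2s = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(12, 5))
            y = rng.normal(size=12)   # independent of X
            q2s.append(loo_q2(X, y, n_max=3).q2_opt)
        assert np.median(q2s) <= 0.0

    def test_exact_loo_matches_fold_oracle(self):
        """At full rank PLS equals OLS, so a naive per-fold OLS loop is an
        independent oracle for the LOO machinery."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        res = loo_q2(X, y, n_max=3)
        press, ss = 0.0, 0.0
        for i in range(8):
            keep = np.arange(8) != i
            X1 = np.column_stack([np.ones(7), X[keep]])
            beta = np.linalg.solve(X1.T @ X1, X1.T @ y[keep])
            pred = np.concatenate([[1.0], X[i]]) @ beta
            press += (y[i] - pred) ** 2
            ss += (y[i] - y[keep].mean()) ** 2
        assert res.q2[2] == pytest.approx(1 - press / ss, abs=1e-10)
        assert res.press[2] == pytest.approx(press, abs=1e-10)

    def test_sep_formula(self):
        X, y = _random_instance(8, n=12, p=4, noise=1.0)
        res = loo_q2(X, y, n_max=3)
        n = 12
        for a in range(3):
            assert res.sep[a] == pytest.approx(np.sqrt(res.press[a] / (n - (a + 1) - 1)))

    def test_q2_never_exceeds_r2_at_same_n(self, train_blocks):
        blocks, y = train_blocks
        row, model = fit_combo(blocks, y, ("S", "A"), n_max=6)
        assert row["q2"] <= model.r2 + 1e-12

    def test_too_few_rows_rejected(self):
        with pytest.raises(PLSError):
            loo_q2(np.zeros((3, 2)), np.zeros(3), n_max=1)


class TestFieldScan:
    def test_five_blocks_give_31_ranked_rows(self):
        rng = np.random.default_rng(9)
        blocks = {k: rng.normal(scale=2, size=(10, 4)) for k in "SEHDA"}
        y = blocks["S"][:, 0] + rng.normal(scale=0.1, size=10)
        scan, models = field_scan(blocks, y, n_max=3, filter_threshold=0.5)
        assert len(scan) == 31
        assert set(scan["model"]) == {"".join(c) for c in _all_combos("SEHDA")}
        q2 = scan["q2"].to_numpy()
        assert np.all(np.diff(q2[~np.isnan(q2)]) <= 1e-12)  # descending

    def test_two_blocks_give_three_rows(self):
        rng = np.random.default_rng(10)
        blocks = {k: rng.normal(scale=2, size=(9, 3)) for k in "SA"}
        y = rng.normal(size=9)
        scan, _ = field_scan(blocks, y, n_max=2, filter_threshold=0.5)
        assert list(sorted(scan["model"])) == ["A", "S", "SA"]

    def test_contributions_sum_to_one(self, train_blocks):
        blocks, y = train_blocks
        scan, _ = field_scan(blocks, y, n_max=4, block_scale=True)
        contrib_cols = [c for c in scan.columns if c.startswith("contrib_")]
        sums = scan[contrib_cols].sum(axis=1, skipna=True)
        fitted = scan["q2"].notna()
        np.testing.assert_allclose(sums[fitted], 1.0, atol=1e-9)

    def test_f_statistic_closed_form(self, train_blocks):
        blocks, y = train_blocks
        row, model = fit_combo(blocks, y, ("S",), n_max=4)
        n, k, r2 = model.n_train, model.n_components, model.r2
        assert model.f_stat == pytest.approx((r2 / k) / ((1 - r2) / (n - k - 1)))


def _all_combos(kinds):
    import itertools

    out = []
    for r in range(1, len(kinds) + 1):
        out.extend(itertools.combinations(kinds, r))
    return out


class TestFieldContributions:
    def test_single_active_block(self):
        coef = np.array([1.0, -2.0, 0.0])
        sigma = np.array([1.0, 1.0, 3.0])
        fields = np.array(["S", "S", "A"], dtype=object)
        contrib = field_contributions(coef, sigma, fields)
        assert contrib["S"] == pytest.approx(1.0)
        assert contrib["A"] == pytest.approx(0.0)

    def test_symmetric_split(self):
        contrib = field_contributions(np.array([1.0, -1.0]), np.array([2.0, 2.0]),
                                      np.array(["S", "A"], dtype=object))
        assert contrib["S"] == pytest.approx(0.5)

    def test_planted_two_to_one_ratio(self):
        contrib = field_contributions(np.array([2.0, 1.0]), np.array([1.0, 1.0]),
                                      np.array(["S", "A"], dtype=object))
        assert contrib["S"] == pytest.approx(2 / 3, abs=1e-9)
        assert contrib["A"] == pytest.approx(1 / 3, abs=1e-9)

    def test_zero_mass_warns_uniform(self):
        with pytest.warns(UserWarning, match="uniform"):
            contrib = field_contributions(np.zeros(2), np.ones(2),
                                          np.array(["S", "A"], dtype=object))
        assert contrib == {"S": 0.5, "A": 0.5}


def test_regression_summary_exact_fit_flags_infinite_f():
    y = np.arange(5.0)
    r2, see, f = regression_summary(y, y, 1)
    assert (r2, see) == (1.0, 0.0)
    assert np.isinf(f)


def test_parameter_recovery_as_noise_vanishes():
    """Planted linear coefficients are recovered in the zero-noise limit."""
    rng = np.random.default_rng(12)
    X = rng.normal(size=(30, 4))
    beta = np.array([1.0, -0.5, 2.0, 0.25])
    model = pls_fit(X, X @ beta + 3.0, 4)
    np.testing.assert_allclose(model.coef, beta, atol=1e-8)
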