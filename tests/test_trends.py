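"""Trend, change-point, correlation and PCA checks against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fire_dynamics as fd
from fire_dynamics import AnnualSeries


def series(values, start=2001, name="x"):
    values = np.asarray(values, dtype=float)
    return AnnualSeries(np.arange(start, start + len(values)), values, name)


def mk_s_oracle(x):
    """O(n^2) pairwise sign sum, coded independently of the implementation."""
    s = 0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            s += int(x[j] > x[i]) - int(x[j] < x[i])
    return s


def pettitt_u_oracle(x):
    """Double-loop U_t for t = 1..n-1."""
    n = len(x)
    out = []
    for t in range(1, n):
        u = 0
        for i in range(t):
            for j in range(t, n):
                u += int(x[j] > x[i]) - int(x[j] < x[i])
        out.append(u)
    return np.array(out)


class TestMannKendall:
    def test_strictly_increasing(self):
        r = fd.mann_kendall(series(np.arange(5)))
        assert r.s == 10 and r.tau == 1.0 and r.direction == "increasing"

    def test_constant_series(self):
        r = fd.mann_kendall(series(np.full(10, 3.3)))
        assert r.s == 0 and r.p_value == 1.0 and r.direction == "none"
        assert r.var_s == 0.0

    def test_worked_example(self):
        r = fd.mann_kendall(series([3, 1, 4, 1, 5, 9, 2, 6]))
        assert r.s == 11
        assert r.s == mk_s_oracle([3, 1, 4, 1, 5, 9, 2, 6])

    def test_s_matches_oracle_with_ties(self, rng):
        for _ in range(200):
            n = rng.integers(4, 51)
            x = rng.integers(0, 8, size=n).astype(float)  # many ties
            r = fd.mann_kendall(series(x))
            assert r.s == mk_s_oracle(x)
            assert abs(r.s) <= n * (n - 1) / 2

    def test_tau_and_p_match_scipy_no_ties(self, rng):
        # scipy.stats.kendalltau is the independent cross-check for the
        # normal-approximation path
        for _ in range(20):
            x = rng.standard_normal(22)
            r = fd.mann_kendall(series(x))
            tau, _ = stats.kendalltau(np.arange(22), x)
            assert r.tau == pytest.approx(tau, abs=1e-12)

    def test_sign_negates_under_value_negation(self, rng):
        x = rng.standard_normal(15)
        assert fd.mann_kendall(series(x)).s == -fd.mann_kendall(series(-x)).s

    def test_requires_min_length(self):
        with pytest.raises(ValueError):
            fd.mann_kendall(series([1, 2, 3]))


class TestPettitt:
    def test_worked_example(self):
        r = fd.pettitt(series([5, 5, 5, 10, 10, 10]))
        assert r.k == 9 and r.change_index == 3
        assert r.p_value == pytest.approx(2 * np.exp(-486 / 252), abs=1e-12)
        assert r.change_year == 2004  # first year of the shifted regime

    def test_constant_series(self):
        r = fd.pettitt(series(np.full(8, 2.0)))
        assert r.k == 0 and r.p_value == 1.0 and r.change_year is None

    def test_u_matches_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(4, 40)
            x = rng.standard_normal(n)
            if rng.random() < 0.5:
                x = np.round(x)  # inject ties
            assert np.array_equal(fd.pettitt(series(x)).u, pettitt_u_oracle(x))

    def test_k_invariant_to_constant_shift(self, rng):
        x = rng.standard_normal(20)
        assert fd.pettitt(series(x)).k == fd.pettitt(series(x + 123.4)).k

    def test_u_negates_under_sign_flip(self, rng):
        x = rng.standard_normal(20)
        assert np.array_equal(fd.pettitt(series(x)).u,
                              -fd.pettitt(series(-x)).u)

    def test_earliest_argmax_wins_on_ties(self):
        # symmetric single-bump series: |U| ties resolve to the earliest t
        x = np.array([0.0, 1.0, 0.0, 1.0])
        u = pettitt_u_oracle(x)
        r = fd.pettitt(series(x))
        ties = np.flatnonzero(np.abs(u) == np.abs(u).max())
        assert r.change_index == ties[0] + 1


class TestPearson:
    def test_self_correlation_is_one(self):
        s = series(np.random.default_rng(1).standard_normal(10), name="a")
        t = AnnualSeries(s.years, s.values.copy(), "b")
        corr = fd.pearson_matrix([s, t])
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_exact_negative(self):
        s = series([1, 2, 3, 4, 5.0], name="a")
        t = series([-1, -2, -3, -4, -5.0], name="b")
        assert fd.pearson_matrix([s, t]).loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_reported_missing(self):
        s = series([1, 2, 3, 4.0], name="a")
        t = series([5, 5, 5, 5.0], name="b")
        corr = fd.pearson_matrix([s, t])
        assert np.isnan(corr.loc["a", "b"])
        assert corr.loc["b", "b"] == 1.0

    def test_matrix_symmetric_psd(self, rng):
        ss = [series(rng.standard_normal(22), name=f"v{i}") for i in range(4)]
        corr = fd.pearson_matrix(ss).to_numpy()
        assert np.allclose(corr, corr.T, atol=1e-12)
        assert np.linalg.eigvalsh(corr).min() > -1e-10

    def test_inner_join_on_years(self):
        a = AnnualSeries(np.arange(2001, 2011), np.arange(10.0), "a")
        b = AnnualSeries(np.arange(2005, 2015), np.arange(10.0), "b")
        df = fd.align_series([a, b])
        assert list(df.index) == list(range(2005, 2011))


class TestPca:
    def test_perfectly_correlated_pair_is_rank_one(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = fd.pca(df)
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_explained_variance_normalized_and_monotone(self, rng):
        df = pd.DataFrame(rng.standard_normal((30, 5)),
                          columns=list("abcde"))
        res = fd.pca(df)
        assert res.explained_variance.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.cumulative_variance) >= -1e-12)
        assert res.cumulative_variance[-1] == pytest.approx(1.0)

    def test_reconstruction_of_standardized_data(self, rng):
        df = pd.DataFrame(rng.standard_normal((25, 4)), columns=list("abcd"))
        res = fd.pca(df)
        X = df.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, Z, atol=1e-8)

    def test_loadings_unit_norm_and_orthogonal(self, rng):
        df = pd.DataFrame(rng.standard_normal((40, 4)), columns=list("wxyz"))
        L = fd.pca(df).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(4), atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        df = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        L = fd.pca(df).loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_constant_variable_named_in_error(self):
        df = pd.DataFrame({"a": np.arange(5.0), "flat": np.ones(5)})
        with pytest.raises(ValueError, match="flat"):
            fd.pca(df)


def test_trend_table_shape_and_columns(rng):
    ss = [series(rng.standard_normal(10), name=f"v{i}") for i in range(3)]
    table = fd.trend_table(ss)
    assert list(table.columns) == ["variable", "test", "statistic",
                                   "p_value", "change_year", "direction"]
    assert len(table) == 6
    assert set(table["test"]) == {"mann_kendall", "pettitt"}


def test_annual_series_rejects_unordered_years():
    with pytest.raises(ValueError):
        AnnualSeries(np.array([2001, 2001, 2002]), np.zeros(3))
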