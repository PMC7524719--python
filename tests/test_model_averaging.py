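"""Model averaging against independent enumeration oracles."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palmfrug import model_averaging as ma


def _random_fixture(seed, n=60, p=3, collinear=True):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if collinear and p >= 2:
        X[:, 1] = 0.6 * X[:, 0] + 0.8 * X[:, 1]
    beta = rng.uniform(-1, 1, p)
    y = X @ beta + rng.standard_normal(n)
    return y, pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])


def oracle_model_average(y, X):
    """Brute-force all-subsets averaging written from scratch with lstsq."""
    n, cols = len(y), list(X.columns)
    p_all = len(cols)
    models = []
    for r in range(p_all + 1):
        for subset in combinations(cols, r):
            D = np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in subset])
            beta, *_ = np.linalg.lstsq(D, y, rcond=None)
            resid = y - D @ beta
            sigma2 = resid @ resid / n
            ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
            k = len(subset) + 2
            ic = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            cov = sigma2 * n / (n - len(subset) - 1) * np.linalg.inv(D.T @ D)
            se = dict(zip(subset, np.sqrt(np.diag(cov))[1:]))
            models.append((dict(zip(subset, beta[1:])), se, ic))
    ics = np.array([m[2] for m in models])
    w = np.exp(-(ics - ics.min()) / 2)
    w /= w.sum()
    avg = {c: sum(wi * m[0].get(c, 0.0) for wi, m in zip(w, models)) for c in cols}
    se_out = {}
    for c in cols:
        se_out[c] = sum(
            wi * np.sqrt(m[1].get(c, 0.0) ** 2 + (m[0].get(c, 0.0) - avg[c]) ** 2)
            for wi, m in zip(w, models))
    return avg, se_out


class TestFitOls:
    def test_perfect_fit(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        y = 2.0 + 3.0 * X["x"].to_numpy()
        fit = ma.fit_ols(y, X)
        assert fit.r2 == pytest.approx(1.0)
        assert np.abs(fit.resid).max() < 1e-10

    def test_intercept_only_returns_mean(self):
        y = np.array([1.0, 2.0, 6.0, 7.0])
        fit = ma.fit_ols(y, None)
        assert fit.params["const"] == pytest.approx(4.0)
        assert fit.r2 == 0.0

    def test_matches_normal_equations(self):
        y, X = _random_fixture(4)
        fit = ma.fit_ols(y, X)
        D = np.column_stack([np.ones(len(y)), X.to_numpy()])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert np.abs(fit.params.to_numpy() - beta).max() < 1e-10


class TestAicc:
    def test_worked_example(self):
        # AIC = -2(-10) + 2*3 = 26; correction 2*3*4/(20-4) = 1.5
        assert ma.aicc(-10.0, 3, 20) == pytest.approx(27.5)

    def test_converges_to_aic(self):
        assert ma.aicc(-10.0, 3, 10**9) == pytest.approx(26.0, abs=1e-6)

    def test_decreasing_in_n(self):
        vals = [ma.aicc(-10.0, 3, n) for n in (10, 20, 50, 1000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            ma.aicc(-10.0, 3, 4)


class TestAkaikeWeights:
    def test_symmetry_and_known_delta(self):
        assert np.allclose(ma.akaike_weights([100.0, 100.0]), [0.5, 0.5])
        w = ma.akaike_weights([10.0, 12.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-4)  # 0.7311
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8),
           st.floats(-100, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sum_one_and_shift_invariant(self, vals, shift):
        w = ma.akaike_weights(vals)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w, ma.akaike_weights(np.asarray(vals) + shift), atol=1e-9)


class TestModelAverage:
    def test_single_candidate_unchanged(self):
        y, X = _random_fixture(1, p=1)
        full = ma.fit_ols(y, X)
        cs = ma.CandidateSet(fits=[full], table=pd.DataFrame({
            "predictors": ["x0"], "loglik": [full.loglik], "k": [full.k],
            "aicc": [0.0], "weight": [1.0]}))
        res = ma.model_average(y, X, candidates=cs)
        assert res.coef["x0"] == pytest.approx(full.params["x0"], abs=1e-12)

    def test_hand_weighted_zero_fill(self):
        # two models with weights .75/.25; predictor absent from the second
        coefs = pd.DataFrame({"x": [0.4, 0.0]})
        ses = pd.DataFrame({"x": [0.0, 0.0]})
        res = ma._average(coefs, ses, np.array([0.75, 0.25]), "unit-variance",
                          pd.DataFrame())
        assert res.coef["x"] == pytest.approx(0.30, abs=1e-12)

    @pytest.mark.parametrize("seed,p", [(11, 3), (12, 3), (13, 4)])
    def test_matches_enumeration_oracle(self, seed, p):
        y, X = _random_fixture(seed, p=p)
        res = ma.model_average(y, X)
        avg, se = oracle_model_average(y, X)
        for c in X.columns:
            assert res.coef[c] == pytest.approx(avg[c], abs=1e-10)
            assert res.se[c] == pytest.approx(se[c], abs=1e-10)
        assert res.candidates["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_ci_contains_point_estimate(self):
        y, X = _random_fixture(2)
        res = ma.model_average(y, X)
        assert ((res.ci_lower <= res.coef) & (res.coef <= res.ci_upper)).all()

    def test_ci_coverage_on_known_slope(self):
        # 95% unconditional CIs should cover the true coefficient in the
        # vast majority of replicates
        rng = np.random.default_rng(99)
        n, hits = 300, 0
        for _ in range(100):
            X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
            y = 0.5 * X["a"].to_numpy() + rng.standard_normal(n)
            res = ma.model_average(y, X)
            hits += res.ci_lower["a"] <= 0.5 <= res.ci_upper["a"]
        assert hits >= 90


class TestPartialSd:
    def test_formula_value(self):
        # build x with sample SD 2 and VIF exactly 4 against one companion
        n = 20
        rng = np.random.default_rng(5)
        A = rng.standard_normal((n, 2))
        A -= A.mean(axis=0)
        q, _ = np.linalg.qr(A)
        u1, u2 = q[:, 0], q[:, 1]
        x = 2 * np.sqrt(n - 1) * (np.sqrt(0.75) * u1 + np.sqrt(0.25) * u2)
        x = pd.Series(x, name="x")
        others = pd.DataFrame({"z": u1})
        psd = ma.partial_sd(x, others, n=n, p=3)
        assert psd == pytest.approx(2 * 0.5 * np.sqrt(19 / 17), abs=1e-8)

    def test_orthogonal_limit_matches_unit_variance(self):
        rng = np.random.default_rng(6)
        n = 500
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        y = X @ np.array([0.5, -0.3, 0.2]) + rng.standard_normal(n)
        unit = ma.model_average(y.to_numpy(), X)
        part = ma.partial_sd_standardize(y.to_numpy(), X)
        # partial-SD rescaling ~ SD(x)/SD(y) per coefficient when VIF ~ 1
        sd_y = y.std(ddof=1)
        for c in X.columns:
            expected = unit.coef[c] * X[c].std(ddof=1) / sd_y
            assert part.coef[c] == pytest.approx(expected, rel=0.05)


class TestVif:
    def test_orthogonal_is_one(self):
        A = np.random.default_rng(7).standard_normal((40, 3))
        A -= A.mean(axis=0)  # center before QR so columns stay mean-zero
        q, _ = np.linalg.qr(A)
        X = pd.DataFrame(q, columns=list("abc"))
        assert np.allclose(ma.vif(X), 1.0, atol=1e-10)

    def test_known_pairwise_correlation(self):
        n = 100
        rng = np.random.default_rng(8)
        A = rng.standard_normal((n, 2))
        A -= A.mean(axis=0)
        q, _ = np.linalg.qr(A)
        u1, u2 = q[:, 0], q[:, 1]
        X = pd.DataFrame({"a": u1, "b": 0.8 * u1 + 0.6 * u2})
        v = ma.vif(X)
        assert v["a"] == pytest.approx(1 / (1 - 0.64), abs=1e-8)
        assert v["b"] == pytest.approx(2.7778, abs=1e-3)

    def test_duplicate_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        X["b"] = X["a"]
        with pytest.raises(ValueError, match="collinearity"):
            ma.vif(X)


class TestLmg:
    def test_single_predictor_share_is_r2(self):
        y, X = _random_fixture(9, p=1, collinear=False)
        vs = ma.lmg_shares(y, X)
        assert vs.shares["x0"] == pytest.approx(vs.r2_full, abs=1e-12)

    def test_orthogonal_additivity(self):
        A = np.random.default_rng(10).standard_normal((80, 2))
        A -= A.mean(axis=0)
        q, _ = np.linalg.qr(A)
        X = pd.DataFrame(q, columns=["a", "b"])
        y = 1.0 * X["a"].to_numpy() + 0.5 * X["b"].to_numpy() \
            + 0.3 * np.random.default_rng(11).standard_normal(80)
        vs = ma.lmg_shares(y, X)
        r2a = ma.fit_ols(y, X[["a"]]).r2
        r2b = ma.fit_ols(y, X[["b"]]).r2
        assert vs.shares["a"] == pytest.approx(r2a, abs=1e-6)
        assert vs.shares["b"] == pytest.approx(r2b, abs=1e-6)
        assert vs.shares.sum() == pytest.approx(vs.r2_full, abs=1e-10)

    def test_matches_ordering_enumeration_oracle(self):
        y, X = _random_fixture(12, p=3)
        vs = ma.lmg_shares(y, X)
        cols = list(X.columns)
        totals = {c: 0.0 for c in cols}
        orders = list(permutations(cols))
        for order in orders:
            r2_prev = 0.0
            for i, c in enumerate(order):
                r2_now = ma.fit_ols(y, X[list(order[:i + 1])]).r2
                totals[c] += r2_now - r2_prev
                r2_prev = r2_now
        for c in cols:
            assert vs.shares[c] == pytest.approx(totals[c] / len(orders), abs=1e-10)

    def test_permutation_invariance(self):
        y, X = _random_fixture(13, p=3)
        a = ma.lmg_shares(y, X)
        b = ma.lmg_shares(y, X[list(X.columns)[::-1]])
        for c in X.columns:
            assert a.shares[c] == pytest.approx(b.shares[c], abs=1e-12)
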