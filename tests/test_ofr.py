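"""Forward orthogonal regression, iterative refinement, model prediction,
and the lag/nonlinearity diagnostics."""

import numpy as np
import pytest
from sklearn.base import clone

import gaitproxy as gp
from gaitproxy import Monomial, OFRRegressor, StoppingRule
from gaitproxy.errors import DomainError, ParameterError
from gaitproxy.ofr import _frols, _iofr


def random_problem(seed, n=80, m=15, k=3, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, m))
    support = rng.choice(m, size=k, replace=False)
    theta = rng.uniform(0.5, 2.0, size=k) * rng.choice([-1, 1], size=k)
    y = X[:, support] @ theta + noise * rng.standard_normal(n)
    return X, y, support, theta


class TestFrols:
    def test_exact_single_column_target(self):
        X, y, support, theta = random_problem(0, k=1)
        res = _frols(X, y, StoppingRule(n_terms=1))
        assert res.selected == [support[0]]
        assert res.err[0] == pytest.approx(1.0, abs=1e-12)
        assert res.sum_err == pytest.approx(1.0, abs=1e-12)
        assert res.theta[0] == pytest.approx(theta[0])

    def test_linear_oracle_recovery_through_dictionary(self):
        # y = 2 u(k-1) - 0.5 u(k-2), noiseless, full degree-2 dictionary
        rng = np.random.default_rng(3)
        u = rng.standard_normal(500)
        sig = gp.DecomposedSignals(channels={"u": u})
        d = gp.build_dictionary(["u"], max_lag=5, max_degree=2)
        design = gp.evaluate_dictionary(d, sig)
        y = 2.0 * u[4:-1] - 0.5 * u[3:-2]
        res = gp.ofr_select(design, y, StoppingRule(n_terms=2))
        got = {str(d[i]): theta for i, theta in zip(res.selected, res.theta)}
        assert got["u(k-1)"] == pytest.approx(2.0, abs=1e-8)
        assert got["u(k-2)"] == pytest.approx(-0.5, abs=1e-8)
        # against direct least squares on the true support
        cols = [d.terms.index(Monomial((("u", 1, 1),))),
                d.terms.index(Monomial((("u", 2, 1),)))]
        lstsq_theta, *_ = np.linalg.lstsq(design.X[:, cols], y, rcond=None)
        np.testing.assert_allclose(sorted(res.theta), sorted(lstsq_theta),
                                   atol=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_err_and_orthogonality_invariants(self, seed):
        X, y, _, _ = random_problem(seed, n=120, m=20, k=4, noise=0.3)
        res = _frols(X, y, StoppingRule(n_terms=8))
        assert np.all(res.err >= 0) and np.all(res.err <= 1)
        assert res.sum_err <= 1 + 1e-9
        # orthogonalized selected columns pairwise orthogonal
        W = res.W
        G = W.T @ W
        norms = np.sqrt(np.diag(G))
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off) / np.outer(norms, norms)) < 1e-8
        # back-substituted coefficients match least squares on the support
        lstsq_theta, *_ = np.linalg.lstsq(X[:, res.selected], y, rcond=None)
        np.testing.assert_allclose(res.theta, lstsq_theta, rtol=1e-8)
        resid = y - X[:, res.selected] @ lstsq_theta
        assert res.rss == pytest.approx(float(resid @ resid), rel=1e-8)

    def test_rss_decreases_along_selection(self):
        X, y, _, _ = random_problem(1, n=100, m=12, k=3, noise=0.5)
        res = _frols(X, y, StoppingRule(n_terms=6))
        # cumulative ERR increasing <=> RSS non-increasing step by step
        assert np.all(res.err >= -1e-12)

    def test_duplicate_columns_skipped_as_degenerate(self):
        X, y, _, _ = random_problem(2, n=60, m=6, k=2)
        X = np.hstack([X, X])  # every column duplicated
        res = _frols(X, y, StoppingRule(n_terms=8))
        assert res.truncated  # runs out of non-degenerate candidates at 6
        assert res.n_terms <= 6

    def test_forced_first_terms_admitted_in_order(self):
        X, y, _, _ = random_problem(4, n=80, m=10, k=3)
        res = _frols(X, y, StoppingRule(n_terms=4), forced_first=[7, 2])
        assert res.selected[:2] == [7, 2]

    def test_err_threshold_stops_when_target_explained(self):
        X, y, support, _ = random_problem(5, k=3, noise=0.0)
        res = _frols(X, y, StoppingRule(mode="err_threshold",
                                        err_tolerance=1e-10))
        assert res.n_terms == 3
        assert set(res.selected) == set(support)


class TestIofr:
    def test_fixed_point_when_greedy_optimal(self):
        X, y, support, _ = random_problem(6, k=2, noise=0.0)
        plain = _frols(X, y, StoppingRule(n_terms=2))
        refined = _iofr(X, y, StoppingRule(n_terms=2), max_iterations=5)
        assert sorted(refined.selected) == sorted(plain.selected)
        assert refined.rss == pytest.approx(plain.rss, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_refined_rss_never_worse_than_greedy(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 80, 12
        X = rng.standard_normal((n, m))
        # correlated candidates make greedy fallible
        X[:, 5] = X[:, 0] + X[:, 1] + 0.2 * rng.standard_normal(n)
        y = X[:, 0] + 0.8 * X[:, 1] + 0.5 * X[:, 2] + 0.05 * rng.standard_normal(n)
        plain = _frols(X, y, StoppingRule(n_terms=3))
        refined = _iofr(X, y, StoppingRule(n_terms=3), max_iterations=5)
        assert refined.rss <= plain.rss + 1e-12


class TestOFRRegressorAPI:
    def test_sklearn_estimator_contract(self):
        est = OFRRegressor(n_terms=3, refine_iterations=2)
        params = est.get_params()
        assert params["n_terms"] == 3
        cloned = clone(est)
        X, y, support, _ = random_problem(7, k=3)
        cloned.fit(X, y)
        assert sorted(cloned.support_) == sorted(support)
        assert np.count_nonzero(cloned.coef_) == 3
        pred = cloned.predict(X)
        assert pred.shape == y.shape
        assert cloned.score(X, y) > 0.999

    def test_parameter_recovery_under_noise(self):
        # median relative coefficient error stays small at 5% output noise
        rel_errors = []
        for seed in range(50):
            X, y, support, theta = random_problem(100 + seed, n=300, m=12,
                                                  k=3, noise=0.0)
            scale = np.std(y)
            rng = np.random.default_rng(seed)
            y = y + 0.05 * scale * rng.standard_normal(len(y))
            res = _frols(X, y, StoppingRule(n_terms=3))
            if sorted(res.selected) != sorted(support):
                rel_errors.append(np.inf)
                continue
            order = np.argsort(res.selected)
            true_order = np.argsort(support)
            err = np.abs(res.theta[order] - theta[true_order]) \
                / np.abs(theta[true_order])
            rel_errors.append(np.median(err))
        assert np.median(rel_errors) < 0.05


class TestPredictNMA:
    def test_delayed_impulse(self):
        model = gp.NMAModel(terms=[Monomial((("u", 1, 1),))],
                            coefficients=[1.0], max_lag=1)
        u = np.zeros(10)
        u[4] = 1.0
        sig = gp.DecomposedSignals(channels={"u": u})
        pred = model.predict(sig)
        assert np.isnan(pred[0])
        expected = np.zeros(10)
        expected[5] = 1.0  # unit impulse delayed by one sample
        np.testing.assert_array_equal(pred[1:], expected[1:])

    def test_predictions_ignore_output_entirely(self):
        # input-only model: no value of the reference output can alter it
        rng = np.random.default_rng(8)
        sig = gp.DecomposedSignals(channels={"u": rng.standard_normal(50)})
        model = gp.NMAModel(terms=[Monomial((("u", 0, 2),))],
                            coefficients=[0.7], max_lag=3)
        p1 = model.predict(sig)
        p2 = model.predict(sig)
        np.testing.assert_array_equal(p1[3:], p2[3:])


class TestDiagnostics:
    def test_crosscorrelation_finds_constructed_delay(self):
        rng = np.random.default_rng(10)
        u = rng.standard_normal(2000)
        y = np.roll(u, 7)
        y[:7] = 0.0
        analysis = gp.max_lag_by_crosscorrelation(u, y, max_lag=20)
        assert np.argmax(np.abs(analysis.correlation)) == 7
        assert analysis.lag >= 7

    def test_zero_delay_dominant_lag_zero(self):
        rng = np.random.default_rng(11)
        u = rng.standard_normal(1000)
        analysis = gp.max_lag_by_crosscorrelation(u, 3 * u, max_lag=10)
        assert np.argmax(np.abs(analysis.correlation)) == 0
        assert analysis.lag == 0

    def test_independent_noise_mostly_insignificant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            u, y = rng.standard_normal(1500), rng.standard_normal(1500)
            a = gp.max_lag_by_crosscorrelation(u, y, max_lag=18)
            hits += int(np.any(np.abs(a.correlation) > a.band))
        # with 19 lags at a 5% per-lag level, occasional hits are expected,
        # but most trials stay inside the band
        assert hits <= 10

    def test_constant_input_rejected(self):
        with pytest.raises(DomainError):
            gp.max_lag_by_crosscorrelation(np.ones(100), np.ones(100))

    def test_linear_system_passes_linearity_check(self):
        rng = np.random.default_rng(12)
        u = rng.standard_normal(3000)
        y = 1.2 * np.roll(u, 1) - 0.4 * np.roll(u, 3)
        y[:3] = 0
        y += 0.05 * rng.standard_normal(3000)
        report = gp.nonlinearity_test(u, y, max_lag=10)
        assert report.verdict == "linear"

    def test_squared_input_detected_as_nonlinear(self):
        rng = np.random.default_rng(13)
        u = rng.standard_normal(3000)
        y = np.roll(u, 1) ** 2
        y[0] = 0
        report = gp.nonlinearity_test(u, y, max_lag=10)
        assert report.verdict == "nonlinear"

    def test_statistic_is_normalized(self):
        rng = np.random.default_rng(14)
        u = rng.standard_normal(500)
        y = u ** 2 + rng.standard_normal(500)
        report = gp.nonlinearity_test(u, y, max_lag=8)
        assert np.all(report.statistic >= -1) and np.all(report.statistic <= 1)
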