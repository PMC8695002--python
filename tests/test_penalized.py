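"""Elastic net penalized fitting, the lambda path, and BIC selection."""

import numpy as np
import pytest
from scipy.optimize import minimize

from difnet.ordinal import OrdinalLogit
from difnet.penalized import ElasticNetOrdinalLogit, bic, penalty_term

from test_ordinal import simulate_po


def brute_force_objective(model, lam):
    """Independent minimizer of the penalized objective (L-BFGS-B on the
    split beta = beta+ - beta- reformulation of the L1 term)."""
    lik = model._plik
    na, p = lik.n_alpha, lik.n_slopes
    w = model.weight_w

    def obj(z):
        gamma, bp, bm = z[:na], z[na:na + p], z[na + p:]
        beta = bp - bm
        v = lik.nll(np.concatenate([gamma, beta])) / model.n_obs
        if not np.isfinite(v):
            return 1e8
        return v + lam * (w * np.sum(bp + bm) + 0.5 * (1 - w) * np.sum(beta**2))

    z0 = np.concatenate([model._null_start()[:na], np.zeros(2 * p)])
    bounds = [(None, None)] * na + [(0, None)] * (2 * p)
    res = minimize(obj, z0, method="L-BFGS-B", bounds=bounds,
                   options=dict(maxiter=3000, ftol=1e-14))
    return res.fun


class TestPenaltyArithmetic:
    def test_mixed_penalty_value(self):
        # 0.1 * (0.5*(|2|+|-1|) + 0.5*0.5*(4+1)) = 0.275
        assert penalty_term([2.0, -1.0], 0.1, 0.5) == pytest.approx(0.275)

    def test_lambda_zero_eliminates_penalty(self):
        assert penalty_term([3.0, -7.0], 0.0, 0.3) == 0.0

    def test_pure_lasso(self):
        assert penalty_term([1.0, 1.0], 1.0, 1.0) == pytest.approx(2.0)

    def test_bic_closed_form(self):
        assert bic(-100.0, 100, 5) == pytest.approx(200 + 5 * np.log(100), abs=1e-10)
        assert bic(-42.0, 50, 0) == pytest.approx(84.0)


class TestPenalizedFit:
    def test_lambda_zero_matches_ml(self):
        y, x = simulate_po(150, [1.0, -0.4], seed=4)
        ml = OrdinalLogit(y, x).fit()
        pen = ElasticNetOrdinalLogit(y, x, weight_w=0.5).fit(lam=0.0)
        np.testing.assert_allclose(pen.params, ml.params, atol=1e-5)

    def test_near_zero_lambda_limit(self):
        y, x = simulate_po(120, [0.8], seed=9)
        ml = OrdinalLogit(y, x).fit()
        pen = ElasticNetOrdinalLogit(y, x, weight_w=1.0).fit(lam=1e-8)
        np.testing.assert_allclose(pen.params, ml.params, atol=1e-5)

    @pytest.mark.parametrize("w", [1.0, 0.5])
    def test_full_shrinkage_at_lambda_max(self, w):
        y, x = simulate_po(200, [1.2, -0.6], seed=6)
        model = ElasticNetOrdinalLogit(y, x, weight_w=w)
        lam_max = model.lambda_sequence()[0]
        fit = model.fit(lam=lam_max)
        np.testing.assert_array_equal(fit.slopes, 0.0)
        # intercepts equal the intercept-only ML fit
        null = OrdinalLogit(y).fit()
        np.testing.assert_allclose(fit.intercepts, null.params, atol=1e-6)

    def test_ridge_shrinks_without_zeroing(self):
        y, x = simulate_po(80, [1.0, -0.8], seed=8)
        model = ElasticNetOrdinalLogit(y, x, weight_w=0.0)
        ml = OrdinalLogit(y, x).fit()
        fit = model.fit(lam=0.5)
        assert np.all(fit.slopes != 0.0)
        assert np.all(np.abs(fit.slopes_std) < np.abs(ml.slopes * model._x_sd) + 1e-12)

    @pytest.mark.parametrize("w", [0.0, 0.5, 1.0])
    def test_brute_force_oracle_matches_objective(self, w):
        y, x = simulate_po(60, [0.9, -0.5], seed=13)
        model = ElasticNetOrdinalLogit(y, x, weight_w=w)
        lam = model.lambda_sequence()[8]
        fit = model.fit(lam=lam)
        oracle = brute_force_objective(model, lam)
        assert fit.objective <= oracle + 1e-4

    def test_objective_consistency_invariant(self):
        y, x = simulate_po(100, [1.0], seed=15)
        model = ElasticNetOrdinalLogit(y, x, weight_w=0.7)
        fit = model.fit(lam=0.05)
        recomputed = -fit.llf / model.n_obs + penalty_term(
            fit.slopes_std, fit.lam, fit.weight_w
        )
        assert fit.objective == pytest.approx(recomputed, abs=1e-10)

    def test_warm_start_never_worsens_objective(self):
        y, x = simulate_po(100, [1.0, -0.7], seed=16)
        model = ElasticNetOrdinalLogit(y, x, weight_w=1.0)
        lams = model.lambda_sequence()
        prev = model.fit(lam=lams[0])
        for lam in lams[1:6]:
            start_obj = model._objective(prev.params_std, lam)
            fit = model.fit(lam=lam, start_params=prev.params_std)
            assert fit.objective <= start_obj + 1e-12
            prev = fit


class TestLambdaPath:
    def test_geometric_sequence_shape(self):
        y, x = simulate_po(100, [1.0], seed=2)
        model = ElasticNetOrdinalLogit(y, x, weight_w=0.5)
        lams = model.lambda_sequence(n_lambda=20, min_ratio=0.01)
        assert len(lams) == 20
        assert np.all(np.diff(lams) < 0)
        ratios = lams[1:] / lams[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)
        assert lams[-1] == pytest.approx(lams[0] * 0.01)

    def test_path_scale_invariance_under_standardization(self):
        y, x = simulate_po(150, [1.0, -0.5], seed=3)
        m1 = ElasticNetOrdinalLogit(y, x, weight_w=1.0)
        m2 = ElasticNetOrdinalLogit(y, x * np.array([2.0, 10.0]), weight_w=1.0)
        np.testing.assert_allclose(m1.lambda_sequence(), m2.lambda_sequence(),
                                   rtol=1e-10)

    def test_null_data_selects_empty_model(self):
        rng = np.random.default_rng(21)
        y = rng.integers(1, 6, size=150)
        x = rng.standard_normal((150, 2))
        path = ElasticNetOrdinalLogit(y, x, weight_w=1.0).fit_path()
        np.testing.assert_array_equal(path.selected.slopes, 0.0)

    def test_strong_signal_is_retained(self):
        y, x = simulate_po(500, [2.0], seed=22)
        path = ElasticNetOrdinalLogit(y, x, weight_w=1.0).fit_path()
        assert path.selected.slopes[0] != 0.0

    def test_singleton_path(self):
        y, x = simulate_po(100, [1.0], seed=23)
        path = ElasticNetOrdinalLogit(y, x, weight_w=1.0).fit_path(lambdas=[0.05])
        assert path.selected_index == 0
        assert path.selected_lambda == 0.05

    def test_selected_index_minimizes_bic(self):
        y, x = simulate_po(200, [1.0, 0.0], seed=24)
        path = ElasticNetOrdinalLogit(y, x, weight_w=0.5).fit_path()
        assert path.selected_index == int(np.argmin(path.bic_values))

    def test_sparsity_nonincreasing_in_lambda(self):
        y, x = simulate_po(200, [1.2, -0.8], seed=25)
        path = ElasticNetOrdinalLogit(y, x, weight_w=1.0).fit_path()
        nnz = np.array([np.sum(f.slopes_std != 0) for f in path.fits])
        # allow single-index violations due to path discreteness
        violations = np.sum(np.diff(nnz) < 0)
        assert violations <= 1

    def test_path_report_columns(self):
        y, x = simulate_po(100, [1.0], seed=26)
        frame = ElasticNetOrdinalLogit(y, x, weight_w=1.0).fit_path().to_frame()
        assert list(frame.columns) == [
            "lambda", "bic", "loglik", "n_nonzero", "converged", "selected"
        ]
        assert frame["selected"].sum() == 1
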