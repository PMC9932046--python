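import numpy as np
import pytest

from ivmedsurv import (
    PenaltySpec,
    fit_penalized_cox,
    fit_penalized_logistic,
    mcp_penalty,
    select_ivs,
    select_mediators,
    sis_screen,
)
from ivmedsurv._cd import LASSO, MCP, _coord_update
from ivmedsurv.penalized_models import kkt_residuals

TIGHT = dict(inner_tol=1e-12, outer_tol=1e-11, max_outer=200, max_sweep=5000)


def _logistic_problem(rng, n=200, p=3, beta=(0.8, -0.5, 0.0)):
    X = rng.normal(size=(n, p))
    eta = X @ np.asarray(beta) - 0.2
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


def _cox_problem(rng, n=120, p=2, beta=(0.7, -0.4)):
    X = rng.normal(size=(n, p))
    T = rng.exponential(1.0, size=n) / np.exp(X @ np.asarray(beta))
    C = rng.exponential(np.quantile(T, 0.7) * 3, size=n)
    return X, np.minimum(T, C), (T <= C).astype(int)


class TestMCPPenalty:
    def test_closed_form_value(self):
        # lam|t| - t^2/(2 gamma) inside the concave region
        assert mcp_penalty(0.5, 1.0, 3.0) == pytest.approx(0.45833333, abs=1e-6)

    def test_flat_beyond_gamma_lambda(self):
        assert mcp_penalty(3.0, 1.0, 3.0) == pytest.approx(1.5)
        assert mcp_penalty(17.0, 1.0, 3.0) == pytest.approx(1.5)

    def test_continuous_at_knot(self):
        assert mcp_penalty(2.9999999, 1.0, 3.0) == pytest.approx(1.5, abs=1e-5)


class TestCoordinateUpdate:
    @pytest.mark.parametrize("z", [-2.0, -0.3, 0.0, 0.4, 1.7])
    @pytest.mark.parametrize("lam", [0.0, 0.25, 1.0])
    def test_lasso_is_soft_threshold(self, z, lam):
        expected = np.sign(z) * max(abs(z) - lam, 0.0)
        assert _coord_update(z, 1.0, lam, LASSO, 3.0, 0.5, 1.0) == pytest.approx(expected)

    @pytest.mark.parametrize("v", [0.25, 0.5, 1.0])  # v < 1/gamma is nonconvex
    @pytest.mark.parametrize("z", [-1.4, -0.6, 0.1, 0.45, 0.9, 2.5])
    def test_mcp_update_minimizes_objective(self, v, z):
        lam, gam = 0.4, 3.0
        b = _coord_update(z, v, lam, MCP, gam, 0.5, 1.0)
        grid = np.linspace(-6, 6, 24001)
        q = 0.5 * v * grid**2 - z * grid + mcp_penalty(grid, lam, gam)
        q_b = 0.5 * v * b**2 - z * b + mcp_penalty(b, lam, gam)
        assert q_b <= q.min() + 1e-8


class TestLogisticPath:
    def test_null_model_at_lambda_max(self, rng):
        X, y = _logistic_problem(rng)
        fit = fit_penalized_logistic(X, y, PenaltySpec(family="mcp"))
        assert np.all(fit.coef_path_std[0] == 0.0)

    def test_lambda_zero_matches_reference_mle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X, y = _logistic_problem(rng)
        spec = PenaltySpec(family="lasso", lambda_path=np.array([0.05, 0.0]))
        fit = fit_penalized_logistic(X, y, spec, **TIGHT)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        # compare at the lambda=0 end of the path, mapped to the original scale
        full = np.r_[
            fit.intercept_path[-1] - np.sum(
                fit.coef_path_std[-1] / np.where(fit.scale > 0, fit.scale, 1) * fit.center
            ),
            fit.coef_path_std[-1] / np.where(fit.scale > 0, fit.scale, 1),
        ]
        np.testing.assert_allclose(full, ref.params, atol=1e-5)

    @pytest.mark.parametrize("family", ["lasso", "alasso", "enet", "mcp"])
    def test_kkt_residuals_along_path(self, rng, family):
        X, y = _logistic_problem(rng, n=150, p=10,
                                 beta=(1.0, -0.8, 0.6, 0, 0, 0, 0, 0, 0, 0))
        spec = PenaltySpec(family=family, n_lambda=30)
        fit = fit_penalized_logistic(X, y, spec, **TIGHT)
        assert np.nanmax(fit.kkt_path) <= 1e-6

    def test_mcp_converges_to_lasso_for_huge_gamma(self, rng):
        X, y = _logistic_problem(rng, n=150, p=5, beta=(1.0, -0.8, 0.5, 0, 0))
        lams = np.geomspace(0.3, 0.003, 25)
        f_l = fit_penalized_logistic(
            X, y, PenaltySpec(family="lasso", lambda_path=lams), **TIGHT)
        f_m = fit_penalized_logistic(
            X, y, PenaltySpec(family="mcp", gamma_mcp=1e6, lambda_path=lams), **TIGHT)
        np.testing.assert_allclose(f_m.coef_path_std, f_l.coef_path_std, atol=1e-4)

    def test_support_invariant_to_column_scaling(self, rng):
        X, y = _logistic_problem(rng, n=250, p=6, beta=(1.2, -0.9, 0.7, 0, 0, 0))
        scales = np.array([1e-3, 5.0, 0.02, 1.0, 300.0, 1.0])
        f1 = fit_penalized_logistic(X, y, PenaltySpec(family="mcp"))
        f2 = fit_penalized_logistic(X * scales, y, PenaltySpec(family="mcp"))
        assert list(f1.support) == list(f2.support)
        # coefficients reported on the original (unscaled) axis
        np.testing.assert_allclose(
            f1.coefficients, f2.coefficients * scales, rtol=1e-4, atol=1e-7
        )

    def test_constant_response_rejected(self, rng):
        X, _ = _logistic_problem(rng)
        with pytest.raises(ValueError, match="constant"):
            fit_penalized_logistic(X, np.ones(X.shape[0]))


class TestCoxPath:
    def test_lambda_zero_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        X, t, e = _cox_problem(rng)
        spec = PenaltySpec(family="lasso", lambda_path=np.array([0.02, 0.0]))
        fit = fit_penalized_cox(X, t, e, spec, **TIGHT)
        df = pd.DataFrame(X, columns=["a", "b"])
        df["T"], df["E"] = t, e
        ref = lifelines.CoxPHFitter().fit(df, "T", "E").params_.values
        np.testing.assert_allclose(fit.coefficients, ref, atol=1e-4)

    def test_kkt_residuals_along_path(self, rng):
        X, t, e = _cox_problem(rng, n=150, p=6, beta=(0.9, -0.6, 0.4, 0, 0, 0))
        fit = fit_penalized_cox(X, t, e, PenaltySpec(family="mcp", n_lambda=30), **TIGHT)
        assert np.nanmax(fit.kkt_path) <= 1e-6

    def test_constant_columns_give_empty_support(self, rng):
        _, t, e = _cox_problem(rng)
        X = np.ones((t.shape[0], 3))
        fit = fit_penalized_cox(X, t, e, PenaltySpec(family="mcp"))
        assert fit.support.size == 0

    def test_zero_events_rejected(self, rng):
        X, t, _ = _cox_problem(rng)
        with pytest.raises(ValueError, match="event"):
            fit_penalized_cox(X, t, np.zeros(t.shape[0], dtype=int))


class TestSelectionSteps:
    def test_selected_sets_nested_in_screened_sets(self, sparse500):
        scr = sis_screen(sparse500)
        I1 = select_ivs(sparse500, scr)
        M1 = select_mediators(sparse500, scr)
        assert set(I1) <= set(scr.I0.tolist())
        assert set(M1) <= set(scr.M0.tolist())

    def test_true_signals_selected_on_fixed_cohort(self, sparse500):
        scr = sis_screen(sparse500)
        I1 = select_ivs(sparse500, scr)
        M1 = select_mediators(sparse500, scr)
        assert set(sparse500.truth["true_ivs"]) <= set(I1.tolist())
        assert set(sparse500.truth["true_mediators"]) <= set(M1.tolist())

    def test_cv10_tuning_runs(self, rng):
        X, y = _logistic_problem(rng, n=120, p=4, beta=(1.0, -0.8, 0, 0))
        fit = fit_penalized_logistic(
            X, y, PenaltySpec(family="lasso", tuning="cv10", n_lambda=20))
        assert fit.coefficients.shape == (4,)
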