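import numpy as np
import pandas as pd
import pytest

from ivmedsurv import (
    MediationDataset,
    NoValidInstrumentsError,
    fit_exposure_model,
    fit_iv_two_stage,
    fit_mediator_models,
    fit_outcome_model_iv,
    generate_dataset,
    partition_candidates,
    scenario_sparse,
)
from ivmedsurv._fitters import SeparationError, cox_newton, logistic_newton


class TestPartition:
    def test_set_difference(self):
        assert list(partition_candidates([3, 7], [7, 12])) == [3]

    def test_identical_sets_raise(self):
        with pytest.raises(NoValidInstrumentsError, match="no valid instruments"):
            partition_candidates([3, 7], [3, 7])

    def test_disjoint_sets_passthrough(self):
        assert list(partition_candidates([1, 5, 9], [2, 4])) == [1, 5, 9]


class TestNewtonSolvers:
    def test_logistic_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(300, 3))
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.3 + X @ [1.0, -0.7, 0.2])))).astype(float)
        coef, cov = logistic_newton(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(coef, ref.params, atol=1e-8)
        np.testing.assert_allclose(np.sqrt(np.diag(cov)), ref.bse, rtol=1e-6)

    def test_cox_matches_lifelines_with_ties(self, rng):
        lifelines = pytest.importorskip("lifelines")
        X = rng.normal(size=(150, 2))
        t = np.ceil(rng.exponential(1, 150) / np.exp(X @ [0.8, -0.5]) * 8)  # heavy ties
        t = np.maximum(t, 1.0)
        e = (rng.random(150) < 0.75).astype(int)
        coef, cov, _ = cox_newton(X, t, e)
        df = pd.DataFrame(X, columns=["a", "b"])
        df["T"], df["E"] = t, e
        ref = lifelines.CoxPHFitter().fit(df, "T", "E")  # Efron ties
        np.testing.assert_allclose(coef, ref.params_.values, atol=1e-4)
        np.testing.assert_allclose(
            np.sqrt(np.diag(cov)), ref.standard_errors_.values, rtol=1e-5
        )

    def test_logistic_separation_detected(self):
        x = np.r_[np.zeros(20), np.ones(20)].reshape(-1, 1)
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(SeparationError):
            logistic_newton(x, y)


class TestExposureModel:
    def test_eta_recovery_with_expected_attenuation(self):
        # At n=5,000, the stage-1 MLE converges to the confounder-marginalized
        # slopes: generating eta=(1.5, 2.0) shrinks by a factor ~0.89-0.91
        # because the withheld confounders add unexplained logit variance.
        # Frozen from a Monte-Carlo oracle run of the generator.
        ds = generate_dataset(scenario_sparse(5000, 0.2, seed=11))
        order = ds.truth["iv_order"]
        d, eta, se, index = fit_exposure_model(
            ds.covariate_matrix()[:, order], ds.exposure
        )
        np.testing.assert_allclose(eta, [1.3675, 1.7686], atol=0.02)
        assert np.all(se > 0)
        assert index.shape == (5000,)

    def test_perfect_instrument_raises_separation(self):
        x = np.r_[np.zeros(30), np.ones(30)]
        with pytest.raises(SeparationError):
            fit_exposure_model(x.reshape(-1, 1), x)

    def test_constant_exposure_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_exposure_model(rng.normal(size=(50, 1)), np.ones(50))


class TestMediatorModels:
    def test_two_point_exact_fit(self):
        c, lam, se = fit_mediator_models(np.array([0.0, 1.0]),
                                         np.array([[0.1], [0.9]]))
        assert lam[0] == pytest.approx(0.8)
        assert c[0] == pytest.approx(0.1)

    def test_null_slope_large_sample(self, rng):
        x = (rng.random(10000) < 0.5).astype(float)
        M = rng.normal(size=(10000, 2))
        _, lam, _ = fit_mediator_models(x, M)
        assert np.all(np.abs(lam) < 0.05)

    def test_slope_recovery(self, rng):
        x = (rng.random(800) < 0.5).astype(float)
        M = (0.8 * x + rng.normal(size=800)).reshape(-1, 1)
        _, lam, se = fit_mediator_models(x, M)
        assert lam[0] == pytest.approx(0.8, abs=0.1)
        # OLS sampling sd: sigma/sqrt(sum (x-xbar)^2)
        assert se[0] == pytest.approx(1 / np.sqrt((x - x.mean()) ** 2 @ np.ones(800)),
                                      rel=0.1)


class TestTwoStage:
    def test_indirect_effect_invariant_to_mediator_rescaling(self, small_data):
        from ivmedsurv import sis_screen, select_ivs, select_mediators

        ds = small_data
        scr = sis_screen(ds)
        I1 = select_ivs(ds, scr)
        M1 = select_mediators(ds, scr)
        I2 = partition_candidates(I1, M1)
        fit = fit_iv_two_stage(ds, I2, M1)

        scaled_cov = ds.covariates.copy()
        col = int(fit.M1[0])
        scaled_cov.iloc[:, col] = scaled_cov.iloc[:, col] * 37.0
        scaled = MediationDataset(time=ds.time, event=ds.event,
                                  exposure=ds.exposure, covariates=scaled_cov)
        fit2 = fit_iv_two_stage(scaled, I2, M1)
        np.testing.assert_allclose(
            fit.indirect_effects, fit2.indirect_effects, rtol=1e-6
        )
        assert fit2.lambda_hat[0] == pytest.approx(37.0 * fit.lambda_hat[0], rel=1e-6)

    def test_zero_variance_mediator_dropped_with_warning(self, small_data):
        ds = small_data
        cov = ds.covariates.copy()
        cov.iloc[:, 60] = 2.5
        data = MediationDataset(time=ds.time, event=ds.event,
                                exposure=ds.exposure, covariates=cov)
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_iv_two_stage(data, [0, 1], [60, 61])
        assert 60 not in fit.M1

    def test_overlapping_sets_rejected(self, small_data):
        with pytest.raises(ValueError, match="overlap"):
            fit_iv_two_stage(small_data, [4, 5], [5, 6])

    def test_summary_frame_reports_hazard_ratios(self, small_data):
        from ivmedsurv import sis_screen, select_ivs, select_mediators

        ds = small_data
        scr = sis_screen(ds)
        I2 = partition_candidates(select_ivs(ds, scr), select_mediators(ds, scr))
        fit = fit_iv_two_stage(ds, I2, select_mediators(ds, scr))
        table = fit.summary_frame()
        assert (np.sign(np.log(table["hr"])) == np.sign(table["estimate"])).all()
        assert (table["hr_low"] <= table["hr"]).all()


def test_outcome_model_requires_events(rng):
    idx = rng.normal(size=50)
    M = rng.normal(size=(50, 1))
    with pytest.raises(ValueError, match="event"):
        fit_outcome_model_iv(idx, M, np.abs(idx) + 1, np.zeros(50, dtype=int))
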