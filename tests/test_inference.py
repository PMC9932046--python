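import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ivmedsurv import (
    MediationDataset,
    bonferroni_adjust,
    bootstrap_test,
    decide_mediators,
    joint_test,
    sobel_test,
)
from ivmedsurv.mediation_inference import MediationTestResult
from ivmedsurv._fitters import cox_newton
from scipy import stats


class TestSobel:
    def test_closed_form_example(self):
        # se = sqrt(0.8^2*0.2^2 + 1.2^2*0.1^2) = 0.2, z = 0.96/0.2 = 4.8
        p = sobel_test(0.8, 0.1, 1.2, 0.2)
        assert p == pytest.approx(1.5867e-6, rel=1e-3)

    def test_null_point_gives_p_one(self):
        assert sobel_test(0.0, 0.1, 1.2, 0.2) == pytest.approx(1.0)

    def test_symmetric_in_the_two_paths(self):
        assert sobel_test(0.8, 0.1, 1.2, 0.2) == sobel_test(1.2, 0.2, 0.8, 0.1)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            sobel_test(0.8, 0.0, 1.2, 0.2)

    def test_vectorized(self):
        p = sobel_test([0.8, 0.0], [0.1, 0.1], [1.2, 1.2], [0.2, 0.2])
        assert p.shape == (2,)
        assert p[1] == pytest.approx(1.0)


class TestJointAndBonferroni:
    @pytest.mark.parametrize("pl, pg, expected", [(0.01, 0.04, 0.04), (1.0, 0.0, 1.0)])
    def test_joint_is_max(self, pl, pg, expected):
        assert joint_test(pl, pg) == expected

    def test_joint_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            joint_test(-0.1, 0.5)

    @pytest.mark.parametrize("p, q, expected", [(0.04, 10, 0.4), (0.9, 5, 1.0)])
    def test_bonferroni_values(self, p, q, expected):
        assert bonferroni_adjust(p, q) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20),
           st.integers(1, 50))
    def test_bonferroni_never_decreases_and_preserves_order(self, ps, q):
        raw = np.array(ps)
        adj = bonferroni_adjust(raw, q)
        assert np.all(adj >= raw)
        assert np.all(adj <= 1.0)
        order = np.argsort(raw, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_joint_type_one_error_conservative_under_composite_null(self, rng):
        # both paths null: lambda = 0 and gamma = 0
        n, reps, alpha = 150, 400, 0.05
        rejections = 0
        for _ in range(reps):
            x = (rng.random(n) < 0.5).astype(float)
            m = rng.normal(size=n)
            t = rng.exponential(1.0, n)
            e = np.ones(n, dtype=int)
            xc = x - x.mean()
            lam = (xc @ m) / (xc @ xc)
            se_l = np.sqrt(((m - m.mean() - lam * xc) ** 2).sum() / (n - 2) / (xc @ xc))
            p_l = 2 * stats.norm.sf(abs(lam / se_l))
            g, cov, _ = cox_newton(m.reshape(-1, 1), t, e)
            p_g = 2 * stats.norm.sf(abs(g[0] / np.sqrt(cov[0, 0])))
            if joint_test(p_l, p_g) < alpha:
                rejections += 1
        # conservative composite null: rate well below alpha + MC noise
        assert rejections / reps <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / reps)


def _tiny_iv_dataset(rng, n=200, lam=0.8, gam=0.0, beta=1.0):
    z = rng.normal(0, 1, size=(n, 2))
    x = (rng.random(n) < 1 / (1 + np.exp(-(z @ [1.0, 1.2])))).astype(int)
    m = lam * x + rng.normal(size=n)
    t = rng.exponential(1.0, n) / np.exp(beta * x + gam * m)
    c = rng.exponential(np.quantile(t, 0.8) * 4, size=n)
    cov = pd.DataFrame({"z1": z[:, 0], "z2": z[:, 1], "m": m})
    return MediationDataset(time=np.minimum(t, c), event=(t <= c).astype(int),
                            exposure=x, covariates=cov)


class TestBootstrap:
    def test_point_estimate_inside_percentile_interval(self, rng):
        data = _tiny_iv_dataset(rng, gam=0.9)
        est, ci, sig, B_ok = bootstrap_test(data, [0, 1], [2], B=300, seed=7)
        assert ci[0, 0] <= est[0] <= ci[0, 1]
        assert B_ok > 270
        assert bool(sig[0]) is True  # strong true mediation

    def test_deterministic_under_seed(self, rng):
        data = _tiny_iv_dataset(rng, gam=0.9)
        a = bootstrap_test(data, [0, 1], [2], B=150, seed=3)
        b = bootstrap_test(data, [0, 1], [2], B=150, seed=3)
        np.testing.assert_array_equal(a[1], b[1])

    def test_minimum_replicates_enforced(self, rng):
        data = _tiny_iv_dataset(rng)
        with pytest.raises(ValueError, match="B >= 100"):
            bootstrap_test(data, [0, 1], [2], B=50)

    def test_null_indirect_not_declared(self, rng):
        data = _tiny_iv_dataset(rng, lam=0.0, gam=0.0)
        _, ci, sig, _ = bootstrap_test(data, [0, 1], [2], B=200, seed=5)
        assert ci[0, 0] < 0 < ci[0, 1]
        assert not bool(sig[0])


class TestDecision:
    def _result(self, mediator, p):
        return MediationTestResult(
            mediator=mediator, indirect_effect=0.5, p_sobel_raw=p, p_joint_raw=p,
            p_sobel_adj=p, p_joint_adj=p,
        )

    def test_threshold_is_strict(self):
        results = [self._result(1, 0.049), self._result(2, 0.05)]
        assert decide_mediators(results, 0.05, "sobel") == [1]

    def test_empty_input_gives_empty_set(self):
        assert decide_mediators([], 0.05, "joint") == []

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            decide_mediators([self._result(1, 0.01)], 0.05, "waldo")
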