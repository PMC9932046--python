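"""Significance tests for per-mediator indirect effects.

Three tests of ``H0: lambda_i * gamma_i = 0``:

* **Sobel** — normal test of the product with delta-method standard error
  ``sqrt(lambda^2 S_gamma^2 + gamma^2 S_lambda^2)``;
* **joint significance** — ``p = max(p_lambda, p_gamma)`` of the two path
  tests (OLS normal approximation and Cox Wald respectively);
* **percentile bootstrap** — rows resampled with replacement, the two-stage
  fit re-estimated on the frozen candidate sets, and the indirect effect
  declared significant when the percentile interval excludes zero.

Sobel and joint p-values are Bonferroni-multiplied by the number of
candidate mediators actually tested; the bootstrap decision follows the
unadjusted interval (an adjusted ``1 - alpha/q`` interval is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._fitters import ConvergenceError
from .iv_estimation import IVFit, fit_iv_two_stage
from .simulate import MediationDataset

__all__ = [
    "MediationTestResult",
    "sobel_test",
    "joint_test",
    "bonferroni_adjust",
    "bootstrap_test",
    "decide_mediators",
    "test_mediation",
]


@dataclass
class MediationTestResult:
    mediator: int
    indirect_effect: float
    p_sobel_raw: float
    p_joint_raw: float
    p_sobel_adj: float
    p_joint_adj: float
    boot_ci: tuple[float, float] | None = None
    boot_B: int = 0
    significant_sobel: bool = False
    significant_joint: bool = False
    significant_boot: bool | None = None


def sobel_test(lambda_hat, s_lambda, gamma_hat, s_gamma):
    """Two-sided normal p-value for the product of coefficients."""
    lam = np.asarray(lambda_hat, dtype=np.float64)
    sl = np.asarray(s_lambda, dtype=np.float64)
    gam = np.asarray(gamma_hat, dtype=np.float64)
    sg = np.asarray(s_gamma, dtype=np.float64)
    if np.any(sl <= 0) or np.any(sg <= 0):
        raise ValueError("standard errors must be positive")
    se = np.sqrt(lam**2 * sg**2 + gam**2 * sl**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, np.abs(lam * gam) / se, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return p if p.ndim else float(p)


def joint_test(p_lambda, p_gamma):
    """max of the two path p-values (conservative under the composite null)."""
    pl = np.asarray(p_lambda, dtype=np.float64)
    pg = np.asarray(p_gamma, dtype=np.float64)
    if np.any((pl < 0) | (pl > 1) | (pg < 0) | (pg > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.maximum(pl, pg)
    return out if out.ndim else float(out)


def bonferroni_adjust(p_raw, q: int):
    """min(p * q, 1) elementwise."""
    if q < 1:
        raise ValueError("q must be >= 1")
    p = np.asarray(p_raw, dtype=np.float64)
    out = np.minimum(p * q, 1.0)
    return out if out.ndim else float(out)


class BootstrapFailureError(RuntimeError):
    pass


def _indirect_on_arrays(time, event, exposure, Z, M, method):
    """One indirect-effect estimate on raw arrays (bootstrap fast path)."""
    from ._fitters import cox_newton, logistic_newton
    from .iv_estimation import fit_mediator_models

    if event.sum() == 0 or len(np.unique(exposure)) < 2:
        raise ConvergenceError("degenerate resample")
    if method == "iv":
        coef, _ = logistic_newton(Z, exposure)
        proxy = coef[0] + Z @ coef[1:]
    else:
        proxy = exposure
    design = np.column_stack([proxy, M])
    coefs, _, _ = cox_newton(design, time, event)
    gamma = coefs[1:]
    _, lam, _ = fit_mediator_models(exposure, M)
    return lam * gamma


def bootstrap_test(
    data: MediationDataset,
    I2,
    M1,
    *,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "iv",
    adjust_level: bool = False,
    max_failure_fraction: float = 0.10,
):
    """Percentile-bootstrap CIs for the indirect effects on frozen sets.

    Rows are resampled with replacement; stage-1, stage-2 and the mediator
    models are re-estimated each replicate (the candidate sets ``I2``/``M1``
    are *not* re-selected). Returns ``(estimates, ci, significant, B_ok)``
    where ``ci`` has shape (len(M1), 2).
    """
    if B < 100:
        raise ValueError("need B >= 100 bootstrap replicates")
    M1 = np.asarray(M1, dtype=np.int64)
    if M1.size == 0:
        raise ValueError("no candidate mediators")
    rng = np.random.default_rng(seed)
    n = data.n
    point = fit_iv_two_stage(data, I2, M1, method=method).indirect_effects
    # work on the small candidate blocks only; refits are Newton solves
    Xmat = data.covariate_matrix()
    Z_all = Xmat[:, np.asarray(I2, dtype=np.int64)] if method == "iv" else None
    M_all = Xmat[:, M1]
    time_all = data.time.astype(np.float64)
    event_all = data.event.astype(np.int64)
    expo_all = data.exposure.astype(np.float64)
    draws = np.full((B, M1.size), np.nan)
    failures = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            draws[b] = _indirect_on_arrays(
                time_all[idx], event_all[idx], expo_all[idx],
                None if Z_all is None else Z_all[idx], M_all[idx], method,
            )
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            failures += 1
    if failures > max_failure_fraction * B:
        raise BootstrapFailureError(
            f"{failures}/{B} bootstrap replicates failed to converge"
        )
    ok = ~np.isnan(draws[:, 0])
    level = alpha / M1.size if adjust_level else alpha
    lo = np.nanquantile(draws[ok], level / 2.0, axis=0)
    hi = np.nanquantile(draws[ok], 1.0 - level / 2.0, axis=0)
    significant = (lo > 0) | (hi < 0)
    return point, np.column_stack([lo, hi]), significant, int(ok.sum())


def decide_mediators(results, alpha: float = 0.05, test: str = "sobel"):
    """Columns declared mediators by the chosen test at level alpha."""
    out = []
    for r in results:
        if test == "sobel":
            hit = r.p_sobel_adj < alpha
        elif test == "joint":
            hit = r.p_joint_adj < alpha
        elif test == "boot":
            hit = bool(r.significant_boot) if r.significant_boot is not None else False
        else:
            raise ValueError("test must be one of 'sobel', 'joint', 'boot'")
        if hit:
            out.append(int(r.mediator))
    return sorted(out)


def test_mediation(
    data: MediationDataset,
    fit: IVFit,
    *,
    alpha: float = 0.05,
    run_bootstrap: bool = False,
    B: int = 1000,
    seed: int = 0,
    q: int | None = None,
) -> list[MediationTestResult]:
    """Assemble per-mediator test results from a two-stage fit.

    ``q`` defaults to the number of candidate mediators actually tested
    (|M1|); pass the full mediator dimension for a global Bonferroni.
    """
    m = fit.M1.size
    if m == 0:
        return []
    q = m if q is None else int(q)
    p_sobel = np.atleast_1d(
        sobel_test(fit.lambda_hat, fit.lambda_se, fit.gamma_hat, fit.gamma_se)
    )
    p_lam = 2.0 * stats.norm.sf(np.abs(fit.lambda_hat / fit.lambda_se))
    p_gam = 2.0 * stats.norm.sf(np.abs(fit.gamma_hat / fit.gamma_se))
    p_joint = np.atleast_1d(joint_test(p_lam, p_gam))
    adj_sobel = bonferroni_adjust(p_sobel, q)
    adj_joint = bonferroni_adjust(p_joint, q)

    ci = sig_boot = None
    n_ok = 0
    if run_bootstrap:
        _, ci, sig_boot, n_ok = bootstrap_test(
            data, fit.I2, fit.M1, B=B, alpha=alpha, seed=seed, method=fit.method
        )
    results = []
    for k, col in enumerate(fit.M1):
        results.append(
            MediationTestResult(
                mediator=int(col),
                indirect_effect=float(fit.indirect_effects[k]),
                p_sobel_raw=float(p_sobel[k]),
                p_joint_raw=float(p_joint[k]),
                p_sobel_adj=float(adj_sobel[k]),
                p_joint_adj=float(adj_joint[k]),
                boot_ci=None if ci is None else (float(ci[k, 0]), float(ci[k, 1])),
                boot_B=n_ok,
                significant_sobel=bool(adj_sobel[k] < alpha),
                significant_joint=bool(adj_joint[k] < alpha),
                significant_boot=None if sig_boot is None else bool(sig_boot[k]),
            )
        )
    return results
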