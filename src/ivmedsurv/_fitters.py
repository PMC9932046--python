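"""Compact Newton solvers for unpenalized logistic and Cox regression.

These back the two-stage IV estimation and the percentile bootstrap, which
needs thousands of low-dimensional refits per dataset; the Cox partial
likelihood (Efron ties) is numba-compiled. Both solvers are validated in the
test suite against statsmodels and lifelines.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "ConvergenceError",
    "SeparationError",
    "logistic_newton",
    "cox_newton",
]


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge."""


class SeparationError(ConvergenceError):
    """Logistic likelihood is monotone (complete/quasi-complete separation)."""


def logistic_newton(X, y, *, tol=1e-10, max_iter=60):
    """Logistic MLE with intercept.

    Returns ``(coef, cov)`` where ``coef[0]`` is the intercept and ``cov`` is
    the inverse observed information (Wald covariance).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    Xd = np.column_stack([np.ones(n), X])
    p = Xd.shape[1]
    beta = np.zeros(p)
    beta[0] = _logit_mean(y)
    for _ in range(max_iter):
        eta = Xd @ beta
        if np.max(np.abs(eta)) > 30.0:
            raise SeparationError(
                "logistic fit diverged (|linear predictor| > 30); data are "
                "separated or nearly so"
            )
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = Xd.T @ (y - mu)
        info = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate
            raise ConvergenceError("singular information matrix") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            cov = np.linalg.inv(info)
            return beta, cov
    raise ConvergenceError("logistic Newton did not converge")


def _logit_mean(y):
    m = float(np.clip(np.mean(y), 1e-10, 1 - 1e-10))
    return float(np.log(m / (1.0 - m)))


@njit(cache=False)
def _cox_efron_ngh(order_eta, order_x, event, tie_first, tie_last):
    """Negative loglik, gradient, Hessian of the Efron partial likelihood.

    Rows are sorted by ascending time; ``tie_first``/``tie_last`` delimit
    groups of identical event times (inclusive indices into the sorted rows).
    """
    n, p = order_x.shape
    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    g = tie_first.shape[0] - 1
    i = n - 1
    while g >= 0:
        lo = tie_first[g]
        hi = tie_last[g]
        while i >= lo:
            e = np.exp(order_eta[i])
            s0 += e
            for a in range(p):
                xa = order_x[i, a]
                s1[a] += e * xa
                for b in range(p):
                    s2[a, b] += e * xa * order_x[i, b]
            i -= 1
        # tied events in [lo, hi]
        d = 0
        t0 = 0.0
        t1 = np.zeros(p)
        t2 = np.zeros((p, p))
        for k in range(lo, hi + 1):
            if event[k] == 1:
                d += 1
                e = np.exp(order_eta[k])
                loglik += order_eta[k]
                t0 += e
                for a in range(p):
                    xa = order_x[k, a]
                    grad[a] += xa
                    t1[a] += e * xa
                    for b in range(p):
                        t2[a, b] += e * xa * order_x[k, b]
        for l in range(d):
            frac = l / d
            den = s0 - frac * t0
            loglik -= np.log(den)
            for a in range(p):
                na = (s1[a] - frac * t1[a]) / den
                grad[a] -= na
                for b in range(p):
                    hess[a, b] += (s2[a, b] - frac * t2[a, b]) / den - na * (
                        s1[b] - frac * t1[b]
                    ) / den
        g -= 1
    return loglik, grad, hess


def _tie_groups(time_sorted):
    change = np.flatnonzero(np.diff(time_sorted) != 0)
    first = np.concatenate([[0], change + 1])
    last = np.concatenate([change, [time_sorted.shape[0] - 1]])
    return first.astype(np.int64), last.astype(np.int64)


def cox_newton(X, time, event, *, tol=1e-9, max_iter=60):
    """Cox proportional-hazards MLE (Efron tie handling).

    Returns ``(coef, cov, loglik)``; ``cov`` is the inverse observed
    information. Raises on zero events or non-convergence.
    """
    X = np.asarray(X, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    if event.sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    order = np.argsort(time, kind="stable")
    ox = np.ascontiguousarray(X[order])
    oe = event[order]
    first, last = _tie_groups(time[order])
    p = X.shape[1]
    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = ox @ beta
        if np.max(np.abs(eta)) > 250.0:
            raise ConvergenceError("Cox fit diverged (monotone likelihood?)")
        ll, grad, hess = _cox_efron_ngh(eta, ox, oe, first, last)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular Cox information matrix") from exc
        # step-halving on loglik decrease
        shrink = 1.0
        for _half in range(30):
            cand = beta + shrink * step
            ll_new = _cox_efron_ngh(ox @ cand, ox, oe, first, last)[0]
            if ll_new >= ll - 1e-12:
                break
            shrink *= 0.5
        beta = beta + shrink * step
        if np.max(np.abs(shrink * step)) < tol or abs(ll - ll_old) < 1e-12:
            eta = ox @ beta
            ll, grad, hess = _cox_efron_ngh(eta, ox, oe, first, last)
            cov = np.linalg.inv(hess)
            return beta, cov, ll
        ll_old = ll
    raise ConvergenceError("Cox Newton did not converge")
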