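"""Sure independence screening (SIS) of an ultrahigh-dimensional covariate pool.

Two marginal rankings are produced: exposure association (univariate logistic
score z for ``X ~ column``) and outcome association (univariate Cox Wald z for
``(time, event) ~ column``). Each subset keeps the top ``t = floor(2n/log n)``
columns (natural log), the conventional SIS subset size. Ranking ties at the
cut are broken toward the lower column index so the result is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import MediationDataset

__all__ = ["ScreeningResult", "sis_subset_size", "sis_screen"]


@dataclass
class ScreeningResult:
    I0: np.ndarray  # column indices marginally associated with the exposure
    M0: np.ndarray  # column indices marginally associated with the outcome
    t: int
    scores_exposure: np.ndarray
    scores_outcome: np.ndarray


def sis_subset_size(n: int) -> int:
    """floor(2n / log n), natural logarithm."""
    if n < 3:
        raise ValueError("need n >= 3 for a positive subset size")
    return int(np.floor(2.0 * n / np.log(n)))


def _top_t(scores: np.ndarray, t: int) -> np.ndarray:
    # stable sort on (-|score|, index): lower index wins ties
    order = np.lexsort((np.arange(scores.shape[0]), -np.abs(scores)))
    return np.sort(order[:t])


def logistic_score_z(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column score-test z for a univariate logistic model of y on the column.

    Under the null (intercept-only), the score is ``x'(y - ybar)`` with
    variance ``ybar(1-ybar) * sum (x - xbar)^2``; constant columns score 0.
    """
    y = np.asarray(y, dtype=np.float64)
    ybar = y.mean()
    resid = y - ybar
    xc = X - X.mean(axis=0)
    num = xc.T @ resid
    den2 = ybar * (1.0 - ybar) * np.einsum("ij,ij->j", xc, xc)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(den2 > 0, num / np.sqrt(den2), 0.0)
    return z


def cox_wald_z(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    *,
    n_iter: int = 4,
    chunk: int = 1024,
) -> np.ndarray:
    """Per-column Wald z from univariate Cox fits, vectorized across columns.

    All columns are Newton-iterated simultaneously (Breslow risk-set sums via
    suffix cumulative sums over time-sorted rows). A handful of iterations is
    ample for Wald ranking; diverging columns are clipped. Constant columns
    score 0.
    """
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.float64)
    order = np.argsort(time, kind="stable")
    ev = event[order]
    zs = np.empty(X.shape[1])
    for start in range(0, X.shape[1], chunk):
        sub = np.asarray(X[:, start : start + chunk], dtype=np.float64)[order]
        zs[start : start + sub.shape[1]] = _cox_wald_chunk(sub, ev, n_iter)
    return zs


def _cox_wald_chunk(xs: np.ndarray, ev: np.ndarray, n_iter: int) -> np.ndarray:
    n, p = xs.shape
    sd = xs.std(axis=0)
    keep = sd > 0
    xstd = np.where(keep, (xs - xs.mean(axis=0)) / np.where(keep, sd, 1.0), 0.0)
    beta = np.zeros(p)
    evmask = ev.astype(bool)
    info = np.full(p, np.nan)
    for _ in range(n_iter):
        eta = np.clip(xstd * beta, -30.0, 30.0)
        e = np.exp(eta)
        s0 = np.cumsum(e[::-1], axis=0)[::-1]
        s1 = np.cumsum((e * xstd)[::-1], axis=0)[::-1]
        s2 = np.cumsum((e * xstd * xstd)[::-1], axis=0)[::-1]
        m = s1 / s0
        grad = (xstd[evmask] - m[evmask]).sum(axis=0)
        info = (s2[evmask] / s0[evmask] - m[evmask] ** 2).sum(axis=0)
        info = np.maximum(info, 1e-10)
        beta = np.clip(beta + grad / info, -20.0, 20.0)
    z = beta * np.sqrt(info)
    return np.where(keep, z, 0.0)


def sis_screen(data: MediationDataset, *, t: int | None = None) -> ScreeningResult:
    """Rank all observed columns marginally and keep the top-t for each target."""
    n = data.n
    if n < 10:
        raise ValueError("SIS needs n >= 10")
    if t is None:
        t = sis_subset_size(n)
    if t < 1:
        raise ValueError("SIS subset size must be >= 1")
    Xmat = data.covariate_matrix()
    if Xmat.shape[1] < t:
        t = Xmat.shape[1]
    s_exp = logistic_score_z(Xmat, data.exposure)
    s_out = cox_wald_z(Xmat, data.time, data.event)
    if not (np.all(np.isfinite(s_exp)) and np.all(np.isfinite(s_out))):
        raise FloatingPointError("non-finite screening statistic")
    return ScreeningResult(
        I0=_top_t(s_exp, t),
        M0=_top_t(s_out, t),
        t=t,
        scores_exposure=s_exp,
        scores_outcome=s_out,
    )
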