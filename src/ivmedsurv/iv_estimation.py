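"""Two-stage instrumental-variable estimation under a Cox outcome model.

Stage 1 regresses the binary exposure on the candidate instruments
(unpenalized logistic MLE) and forms the per-subject instrument index
``D = d + eta'Z`` — the part of the exposure that, by the IV assumptions, is
free of confounding. Stage 2 fits an unpenalized Cox model on the instrument
index together with the candidate mediators, so the exposure coefficient is
estimated through the instruments rather than the confounded exposure.
Mediator models ``M_i = c + lambda_i X + eps`` are simple per-mediator OLS on
the observed exposure.

Stage-2 Wald standard errors are naive with respect to first-stage
uncertainty; the percentile bootstrap in :mod:`ivmedsurv.mediation_inference`
is the recommended inference route for indirect effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._fitters import SeparationError, cox_newton, logistic_newton
from .simulate import MediationDataset

__all__ = [
    "IVFit",
    "NoValidInstrumentsError",
    "partition_candidates",
    "fit_exposure_model",
    "fit_outcome_model_iv",
    "fit_mediator_models",
    "fit_iv_two_stage",
]


class NoValidInstrumentsError(RuntimeError):
    pass


@dataclass
class IVFit:
    """Estimates from the two-stage fit (or its classical analogue).

    ``beta_hat`` is the log-hazard coefficient on the exposure proxy: the
    stage-1 instrument index for the IV route, the observed exposure for the
    classical route. ``gamma_hat``/``lambda_hat`` align with ``M1``.
    """

    I2: np.ndarray
    M1: np.ndarray
    eta_hat: np.ndarray | None
    eta_se: np.ndarray | None
    d_hat: float | None
    instrument_index: np.ndarray | None
    beta_hat: float
    beta_se: float
    gamma_hat: np.ndarray
    gamma_se: np.ndarray
    lambda_hat: np.ndarray
    lambda_se: np.ndarray
    c_hat: np.ndarray
    dropped_instruments: np.ndarray
    dropped_mediators: np.ndarray
    method: str = "iv"

    @property
    def indirect_effects(self) -> np.ndarray:
        return self.lambda_hat * self.gamma_hat

    def summary_frame(self):
        import pandas as pd

        rows = [
            {
                "term": "exposure_index" if self.method == "iv" else "exposure",
                "estimate": self.beta_hat,
                "se": self.beta_se,
                "z": self.beta_hat / self.beta_se,
                "p": 2 * stats.norm.sf(abs(self.beta_hat / self.beta_se)),
                "hr": np.exp(self.beta_hat),
                "hr_low": np.exp(self.beta_hat - 1.959963984540054 * self.beta_se),
                "hr_high": np.exp(self.beta_hat + 1.959963984540054 * self.beta_se),
            }
        ]
        for k, col in enumerate(self.M1):
            z = self.gamma_hat[k] / self.gamma_se[k]
            rows.append(
                {
                    "term": f"mediator_{col}",
                    "estimate": self.gamma_hat[k],
                    "se": self.gamma_se[k],
                    "z": z,
                    "p": 2 * stats.norm.sf(abs(z)),
                    "hr": np.exp(self.gamma_hat[k]),
                    "hr_low": np.exp(self.gamma_hat[k] - 1.959963984540054 * self.gamma_se[k]),
                    "hr_high": np.exp(self.gamma_hat[k] + 1.959963984540054 * self.gamma_se[k]),
                }
            )
        return pd.DataFrame(rows)


def partition_candidates(I1, M1) -> np.ndarray:
    """Candidate instruments: selected exposure predictors that were not also
    selected as mediators (``I2 = I1 \\ M1``)."""
    I1 = np.asarray(I1, dtype=np.int64)
    M1 = np.asarray(M1, dtype=np.int64)
    I2 = np.setdiff1d(I1, M1)
    if I2.size == 0:
        raise NoValidInstrumentsError(
            "no valid instruments: every exposure-selected column was also "
            "selected as a mediator; consider relaxing the mediator penalty "
            "or supplying known instruments"
        )
    return I2


def _drop_degenerate(Xmat, cols):
    cols = np.asarray(cols, dtype=np.int64)
    sd = Xmat[:, cols].std(axis=0) if cols.size else np.empty(0)
    keep = sd > 0
    if not np.all(keep):
        import warnings

        warnings.warn(
            f"dropping zero-variance columns {list(cols[~keep])} before "
            "unpenalized fit",
            stacklevel=3,
        )
    return cols[keep], cols[~keep]


def fit_exposure_model(Z_cols: np.ndarray, exposure: np.ndarray):
    """Stage 1: unpenalized logistic MLE of exposure on candidate instruments.

    Returns ``(d_hat, eta_hat, eta_se, instrument_index)`` where the index is
    the fitted linear predictor ``d_hat + eta_hat' Z``.
    """
    exposure = np.asarray(exposure, dtype=np.float64)
    if len(np.unique(exposure)) < 2:
        raise ValueError("exposure is constant; stage-1 model undefined")
    try:
        coef, cov = logistic_newton(Z_cols, exposure)
    except SeparationError as exc:
        raise SeparationError(
            "stage-1 logistic separation; refit with a penalized model or "
            "different instruments"
        ) from exc
    d_hat = float(coef[0])
    eta_hat = coef[1:]
    eta_se = np.sqrt(np.diag(cov))[1:]
    index = d_hat + Z_cols @ eta_hat
    return d_hat, eta_hat, eta_se, index


def fit_outcome_model_iv(instrument_index, M1_cols, time, event):
    """Stage 2: unpenalized Cox MLE on [exposure proxy, candidate mediators].

    Works identically for the classical route by passing the observed
    exposure as ``instrument_index``. Returns
    ``(beta_hat, beta_se, gamma_hat, gamma_se)`` with Wald SEs from the
    observed information.
    """
    instrument_index = np.asarray(instrument_index, dtype=np.float64)
    if np.any(~np.isfinite(instrument_index)):
        raise ValueError("instrument index contains non-finite values")
    design = np.column_stack([instrument_index, M1_cols])
    coef, cov, _ = cox_newton(design, time, event)
    se = np.sqrt(np.diag(cov))
    return float(coef[0]), float(se[0]), coef[1:], se[1:]


def fit_mediator_models(exposure, M1_cols):
    """Per-mediator OLS of M_i on the observed exposure.

    Returns ``(c_hat, lambda_hat, lambda_se)``; the residual variance uses
    n - 2 degrees of freedom.
    """
    x = np.asarray(exposure, dtype=np.float64)
    M = np.atleast_2d(np.asarray(M1_cols, dtype=np.float64))
    if M.shape[0] != x.shape[0]:
        M = M.T
    n = x.shape[0]
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("exposure is constant; mediator slopes undefined")
    lam = (xc @ M) / sxx
    c = M.mean(axis=0) - lam * x.mean()
    resid = M - c - np.outer(x, lam)
    s2 = np.einsum("ij,ij->j", resid, resid) / max(n - 2, 1)
    lam_se = np.sqrt(s2 / sxx)
    return c, lam, lam_se


def fit_iv_two_stage(
    data: MediationDataset,
    I2,
    M1,
    *,
    method: str = "iv",
    exposure_proxy: str = "index",
) -> IVFit:
    """Run both stages plus the mediator models on fixed candidate sets.

    ``method='classical'`` skips stage 1 and puts the observed exposure in
    the Cox model. ``exposure_proxy='probability'`` substitutes the stage-1
    fitted probability for the linear index.
    """
    Xmat = data.covariate_matrix()
    M1 = np.asarray(M1, dtype=np.int64)
    M1, dropped_m = _drop_degenerate(Xmat, M1)
    if M1.size == 0:
        raise ValueError("no candidate mediators to estimate")
    if method == "iv":
        I2 = np.asarray(I2, dtype=np.int64)
        if np.intersect1d(I2, M1).size:
            raise ValueError("candidate instruments and mediators overlap")
        I2, dropped_i = _drop_degenerate(Xmat, I2)
        if I2.size == 0:
            raise NoValidInstrumentsError("all candidate instruments degenerate")
        d_hat, eta_hat, eta_se, index = fit_exposure_model(Xmat[:, I2], data.exposure)
        if exposure_proxy == "probability":
            proxy = 1.0 / (1.0 + np.exp(-index))
        else:
            proxy = index
    elif method == "classical":
        I2 = np.asarray(I2, dtype=np.int64) if I2 is not None else np.empty(0, np.int64)
        dropped_i = np.empty(0, np.int64)
        d_hat = eta_hat = eta_se = index = None
        proxy = data.exposure.astype(np.float64)
    else:
        raise ValueError("method must be 'iv' or 'classical'")

    beta_hat, beta_se, gamma_hat, gamma_se = fit_outcome_model_iv(
        proxy, Xmat[:, M1], data.time, data.event
    )
    c_hat, lambda_hat, lambda_se = fit_mediator_models(data.exposure, Xmat[:, M1])
    return IVFit(
        I2=I2,
        M1=M1,
        eta_hat=eta_hat,
        eta_se=eta_se,
        d_hat=d_hat,
        instrument_index=index,
        beta_hat=beta_hat,
        beta_se=beta_se,
        gamma_hat=gamma_hat,
        gamma_se=gamma_se,
        lambda_hat=lambda_hat,
        lambda_se=lambda_se,
        c_hat=c_hat,
        dropped_instruments=dropped_i,
        dropped_mediators=dropped_m,
        method=method,
    )
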