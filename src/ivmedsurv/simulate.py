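"""Synthetic data generator for IV-based mediation analysis with survival outcomes.

The generator emulates an observational epigenetic study: a binary exposure
(e.g. smoking) driven by a pair of instruments and by four *unmeasured*
confounders; a high-dimensional block of normally distributed candidate
mediators (methylation-style), a handful of which truly transmit the exposure
effect; and a right-censored survival outcome following a proportional-hazards
model. The confounder block is generated, used, and then withheld from the
observed covariates, so the analysis faces genuine unmeasured confounding
while oracle tests can still see the truth.

Structural model
----------------
* instruments  ``Z1, Z2 ~ N(0, sigma^2)`` with sd (0.9, 1.1), independent;
* confounders  ``L1, L2 ~ N(0, sigma^2)`` with sd (0.8, 1.2);
  ``L3 ~ Bern(0.4)``, ``L4 ~ Bern(0.6)``;
* exposure     ``X ~ Bern(expit(d + eta'Z + zeta2'L))``;
* mediators    ``M_i = c + lambda_i X + eps``, ``eps ~ N(0, sd^2)``;
* outcome      hazard ``h0 * exp(a + beta X + gamma'M + zeta1'L)`` with an
  exponential baseline, survival times drawn by inverse transform
  ``T = -log(U) / (h0 exp(lp))``;
* censoring    independent exponential, rate calibrated numerically so the
  expected censored fraction equals the requested target.

Columns whose ``lambda`` and ``gamma`` are both zero are pure noise fillers
``N(0, 1)``. The observed covariate block is column-shuffled before delivery
so that downstream selection cannot exploit column position; the index map is
kept in ``MediationDataset.truth``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "SimulationConfig",
    "MediationDataset",
    "CensoringCalibrationError",
    "scenario_sparse",
    "scenario_dense",
    "calibrate_censoring",
    "generate_dataset",
]


class CensoringCalibrationError(RuntimeError):
    """Could not match the requested censoring fraction."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the data-generating process.

    ``gamma_vec``/``lambda_vec`` give the leading mediator coefficients; all
    further mediator columns have both coefficients zero. A column is a true
    mediator iff ``lambda_i * gamma_i != 0``.
    """

    n: int
    p_total: int = 1000
    gamma_vec: tuple[float, ...] = (1.2, 0.8, 1.5, 0.0)
    lambda_vec: tuple[float, ...] = (0.8, 1.2, 0.0, 1.5)
    beta: float = 1.5
    zeta1: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7)
    zeta2: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7)
    eta: tuple[float, ...] = (1.5, 2.0)
    a: float = 0.0
    c: float = 0.0
    d: float = 0.0
    sd_iv: tuple[float, float] = (0.9, 1.1)
    sd_conf: tuple[float, float] = (0.8, 1.2)
    p_bern: tuple[float, float] = (0.4, 0.6)
    mediator_noise_sd: float = 1.0
    baseline_hazard: float = 1.0
    censor_rate_target: float = 0.2
    frailty_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.gamma_vec) != len(self.lambda_vec):
            raise ValueError("gamma_vec and lambda_vec must have equal length")
        if not 0.0 < self.censor_rate_target < 1.0:
            raise ValueError("censor_rate_target must lie in (0, 1)")
        if self.n < 2:
            raise ValueError("need n >= 2")
        n_cov = self.p_obs
        if n_cov < len(self.eta) + len(self.gamma_vec):
            raise ValueError("p_total too small for the requested coefficients")

    @property
    def p_obs(self) -> int:
        """Observed covariate columns: the total pool minus the 4 withheld confounders."""
        return self.p_total - len(self.zeta1)

    @property
    def true_mediator_positions(self) -> tuple[int, ...]:
        """Pre-shuffle mediator indices (0-based within the mediator block)."""
        g = np.asarray(self.gamma_vec)
        l = np.asarray(self.lambda_vec)
        return tuple(int(i) for i in np.flatnonzero(g * l != 0.0))

    @property
    def true_indirect_effects(self) -> dict[int, float]:
        g = np.asarray(self.gamma_vec)
        l = np.asarray(self.lambda_vec)
        return {int(i): float(g[i] * l[i]) for i in self.true_mediator_positions}


def scenario_sparse(n: int, censor_rate: float = 0.2, seed: int = 0) -> SimulationConfig:
    """1,000-covariate setting: two true mediators (effects 0.96 each)."""
    return SimulationConfig(n=n, p_total=1000, censor_rate_target=censor_rate, seed=seed)


def scenario_dense(n: int, censor_rate: float = 0.2, seed: int = 0) -> SimulationConfig:
    """3,000-covariate setting: four true mediators, two with negative effects."""
    return SimulationConfig(
        n=n,
        p_total=3000,
        gamma_vec=(1.2, 0.8, -1.2, 1.2, 1.5, 0.0),
        lambda_vec=(0.8, 1.2, 0.8, -0.8, 0.0, 1.5),
        censor_rate_target=censor_rate,
        seed=seed,
    )


@dataclass
class MediationDataset:
    """One simulated (or imported) cohort.

    ``covariates`` carries the shuffled observed block with labels
    ``V0001..Vpppp``; ``truth`` records, in shuffled coordinates, the true IV
    columns, the true mediator columns, and the generating ``lambda``/``gamma``
    per column (zeros for instruments, noise, and real data).
    """

    time: np.ndarray
    event: np.ndarray
    exposure: np.ndarray
    covariates: pd.DataFrame
    hidden_confounders: np.ndarray | None = None
    truth: dict = field(default_factory=dict)
    config: SimulationConfig | None = None

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    def covariate_matrix(self) -> np.ndarray:
        return self.covariates.to_numpy(dtype=np.float64, copy=False)

    def validate(self) -> None:
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("survival times must be finite and positive")
        if not set(np.unique(self.event)).issubset({0, 1}):
            raise ValueError("event indicator must be 0/1")
        if not set(np.unique(self.exposure)).issubset({0, 1}):
            raise ValueError("exposure must be binary 0/1")
        if self.covariates.isna().any().any():
            raise ValueError("missing values in covariates")

    def to_csv(self, path: str | Path, truth_path: str | Path | None = None) -> None:
        path = Path(path)
        df = pd.DataFrame(
            {
                "id": np.arange(1, self.n + 1),
                "time": self.time,
                "event": self.event,
                "exposure": self.exposure,
            }
        )
        out = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)
        if truth_path is None:
            truth_path = path.with_suffix(".truth.json")
        payload = {
            "true_ivs": [int(i) for i in self.truth.get("true_ivs", [])],
            "true_mediators": [int(i) for i in self.truth.get("true_mediators", [])],
            "config": asdict(self.config) if self.config is not None else None,
        }
        Path(truth_path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, *, time="time", event="event", exposure="exposure") -> "MediationDataset":
        df = pd.read_csv(path)
        from .pipeline import validate_input  # late import to avoid a cycle

        return validate_input(df, time=time, event=event, exposure=exposure)


def calibrate_censoring(linear_predictors, h0: float, target: float) -> float:
    """Exponential censoring rate matching an expected censored fraction.

    With event times that are exponential given the linear predictor
    (rate ``r_i = h0 * exp(lp_i)``) and censoring ``C ~ Exp(theta)``
    independent, ``P(T_i > C) = theta / (theta + r_i)``; the returned theta
    solves ``mean_i theta/(theta+r_i) = target`` by bracketed root finding
    and is monotone increasing in the target.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target censoring rate must lie in (0, 1)")
    rates = h0 * np.exp(np.asarray(linear_predictors, dtype=np.float64))
    if np.any(~np.isfinite(rates)):
        raise CensoringCalibrationError("non-finite hazard in calibration")

    def frac(theta):
        return float(np.mean(theta / (theta + rates))) - target

    lo = 1e-12
    hi = float(np.max(rates))
    for _ in range(200):
        if frac(hi) > 0:
            break
        hi *= 4.0
    else:
        raise CensoringCalibrationError(
            f"no censoring rate reaches target {target:.3f}; achieved at most "
            f"{frac(hi) + target:.3f}"
        )
    return float(brentq(frac, lo, hi, xtol=1e-12, rtol=1e-12))


def generate_dataset(config: SimulationConfig) -> MediationDataset:
    """Draw one cohort from the structural model. Bit-reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    k = len(config.eta)
    q_named = len(config.gamma_vec)
    p_obs = config.p_obs
    n_med = p_obs - k

    Z = rng.normal(0.0, config.sd_iv, size=(n, k))
    L_norm = rng.normal(0.0, config.sd_conf, size=(n, 2))
    L_bern = (rng.random((n, 2)) < np.asarray(config.p_bern)).astype(np.float64)
    L = np.column_stack([L_norm, L_bern])

    logit_x = config.d + Z @ np.asarray(config.eta) + L @ np.asarray(config.zeta2)
    X = (rng.random(n) < expit(logit_x)).astype(np.int64)

    lam = np.zeros(n_med)
    gam = np.zeros(n_med)
    lam[:q_named] = config.lambda_vec
    gam[:q_named] = config.gamma_vec
    M = config.c + np.outer(X, lam) + rng.normal(0.0, config.mediator_noise_sd, size=(n, n_med))

    lp = (
        config.a
        + config.beta * X
        + M @ gam
        + L @ np.asarray(config.zeta1)
    )
    if config.frailty_sd > 0:
        lp = lp + rng.normal(0.0, config.frailty_sd, size=n)
    h0 = config.baseline_hazard
    U = rng.random(n)
    T = -np.log(U) / (h0 * np.exp(lp))

    theta = calibrate_censoring(lp, h0, config.censor_rate_target)
    C = rng.exponential(1.0 / theta, size=n)
    time = np.minimum(T, C)
    event = (T <= C).astype(np.int64)

    raw = np.column_stack([Z, M])  # pre-shuffle order: [Z1, Z2, mediators...]
    perm = rng.permutation(p_obs)
    shuffled = raw[:, perm]
    # column j of `shuffled` is raw column perm[j]
    pos_of_raw = np.empty(p_obs, dtype=np.int64)
    pos_of_raw[perm] = np.arange(p_obs)

    lam_col = np.zeros(p_obs)
    gam_col = np.zeros(p_obs)
    lam_col[pos_of_raw[k:]] = lam
    gam_col[pos_of_raw[k:]] = gam

    labels = [f"V{j + 1:04d}" for j in range(p_obs)]
    covariates = pd.DataFrame(shuffled, columns=labels)
    truth = {
        "true_ivs": sorted(int(pos_of_raw[j]) for j in range(k)),
        "iv_order": [int(pos_of_raw[j]) for j in range(k)],  # Z1, Z2, ... identity
        "true_mediators": sorted(
            int(pos_of_raw[k + j]) for j in config.true_mediator_positions
        ),
        "lambda_by_column": lam_col,
        "gamma_by_column": gam_col,
        "permutation": perm,
        "censoring_rate_param": theta,
    }
    ds = MediationDataset(
        time=time,
        event=event,
        exposure=X,
        covariates=covariates,
        hidden_confounders=L,
        truth=truth,
        config=config,
    )
    ds.validate()
    return ds
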