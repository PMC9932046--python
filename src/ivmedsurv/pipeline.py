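"""End-to-end orchestration: screening, selection, two-stage estimation, tests.

``run_proposed`` executes the full IV route:

1. SIS screening of all observed columns (exposure subset I0, outcome
   subset M0, each of size ``floor(2n/log n)``);
2. penalized logistic selection of exposure predictors on I0 -> I1;
3. penalized Cox selection of outcome predictors on M0 -> M1 (candidate
   mediators);
4. candidate instruments I2 = I1 \\ M1;
5. two-stage IV estimation (stage-1 logistic on I2, stage-2 Cox on the
   instrument index plus M1, per-mediator OLS);
6. Sobel / joint / bootstrap tests of each indirect effect;
7. Bonferroni adjustment and the significance decision at level alpha.

``run_classical`` is the unadjusted comparator: the same screening and
selection, but the stage-2 Cox model uses the observed exposure instead of
the instrument index (no instruments required).
"""

from __future__ import annotations

import platform
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .iv_estimation import IVFit, fit_iv_two_stage, partition_candidates
from .mediation_inference import MediationTestResult, decide_mediators, test_mediation
from .penalized_models import PenaltySpec, select_ivs, select_mediators
from .screening import ScreeningResult, sis_screen
from .simulate import MediationDataset

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_proposed",
    "run_classical",
    "validate_input",
]


@dataclass
class PipelineConfig:
    iv_penalty: PenaltySpec = field(
        default_factory=lambda: PenaltySpec(family="mcp", refine=False)
    )
    mediator_penalty: PenaltySpec = field(default_factory=lambda: PenaltySpec(family="mcp"))
    alpha: float = 0.05
    run_bootstrap: bool = False
    B: int = 1000
    seed: int = 0
    decision_test: str = "sobel"
    bonferroni_q: int | None = None  # None -> |M1|
    exposure_proxy: str = "index"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.decision_test not in {"sobel", "joint", "boot"}:
            raise ValueError("decision_test must be 'sobel', 'joint' or 'boot'")


@dataclass
class PipelineResult:
    screening: ScreeningResult
    I1: np.ndarray
    M1: np.ndarray
    I2: np.ndarray
    fit: IVFit | None
    tests: list[MediationTestResult]
    selected_mediators: list[int]
    method: str
    provenance: dict

    @property
    def empty(self) -> bool:
        return self.fit is None

    def results_table(self) -> pd.DataFrame:
        cols = [
            "mediator", "lambda", "gamma", "indirect", "ci_low", "ci_high",
            "p_sobel", "p_joint", "p_boot_flag", "adj_p_sobel", "adj_p_joint",
        ]
        if self.fit is None:
            return pd.DataFrame(columns=cols)
        rows = []
        for k, r in enumerate(self.tests):
            rows.append(
                {
                    "mediator": r.mediator,
                    "lambda": self.fit.lambda_hat[k],
                    "gamma": self.fit.gamma_hat[k],
                    "indirect": r.indirect_effect,
                    "ci_low": None if r.boot_ci is None else r.boot_ci[0],
                    "ci_high": None if r.boot_ci is None else r.boot_ci[1],
                    "p_sobel": r.p_sobel_raw,
                    "p_joint": r.p_joint_raw,
                    "p_boot_flag": r.significant_boot,
                    "adj_p_sobel": r.p_sobel_adj,
                    "adj_p_joint": r.p_joint_adj,
                }
            )
        return pd.DataFrame(rows, columns=cols)


def _run(data: MediationDataset, config: PipelineConfig, method: str) -> PipelineResult:
    t0 = _time.perf_counter()
    data.validate()
    screening = sis_screen(data)
    I1 = select_ivs(data, screening, config.iv_penalty)
    M1 = select_mediators(data, screening, config.mediator_penalty)

    fit = None
    tests: list[MediationTestResult] = []
    selected: list[int] = []
    I2 = np.empty(0, dtype=np.int64)
    if M1.size == 0:
        # nothing to test: an informative empty result, not an error
        pass
    else:
        if method == "iv":
            I2 = partition_candidates(I1, M1)  # raises if empty
        fit = fit_iv_two_stage(
            data, I2 if method == "iv" else None, M1,
            method=method, exposure_proxy=config.exposure_proxy,
        )
        tests = test_mediation(
            data,
            fit,
            alpha=config.alpha,
            run_bootstrap=config.run_bootstrap or config.decision_test == "boot",
            B=config.B,
            seed=config.seed,
            q=config.bonferroni_q,
        )
        selected = decide_mediators(tests, config.alpha, config.decision_test)

    provenance = {
        "config": {
            "alpha": config.alpha,
            "B": config.B,
            "seed": config.seed,
            "decision_test": config.decision_test,
            "iv_penalty": config.iv_penalty.family,
            "mediator_penalty": config.mediator_penalty.family,
            "exposure_proxy": config.exposure_proxy,
            "method": method,
        },
        "versions": {
            "ivmedsurv": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
        "n": int(data.n),
        "p": int(data.p),
        "elapsed_s": None,
    }
    provenance["elapsed_s"] = round(_time.perf_counter() - t0, 3)
    return PipelineResult(
        screening=screening,
        I1=I1,
        M1=M1,
        I2=I2,
        fit=fit,
        tests=tests,
        selected_mediators=selected,
        method=method,
        provenance=provenance,
    )


def run_proposed(data: MediationDataset, config: PipelineConfig | None = None) -> PipelineResult:
    """IV-based mediation pipeline (steps 1-7)."""
    return _run(data, config or PipelineConfig(), "iv")


def run_classical(data: MediationDataset, config: PipelineConfig | None = None) -> PipelineResult:
    """Unadjusted comparator: observed exposure in the stage-2 Cox model."""
    return _run(data, config or PipelineConfig(), "classical")


def validate_input(
    table: pd.DataFrame,
    *,
    time: str = "time",
    event: str = "event",
    exposure: str = "exposure",
    id_column: str = "id",
) -> MediationDataset:
    """Typed dataset from a user table, with itemized validation errors.

    All columns other than the declared time/event/exposure (and an optional
    id column) form the covariate pool. Zero-variance covariates are
    reported but retained (selection scores them zero).
    """
    problems = []
    for name in (time, event, exposure):
        if name not in table.columns:
            problems.append(f"missing required column {name!r}")
    if problems:
        raise ValueError("; ".join(problems))

    t = pd.to_numeric(table[time], errors="coerce")
    e = pd.to_numeric(table[event], errors="coerce")
    x = pd.to_numeric(table[exposure], errors="coerce")
    if t.isna().any():
        problems.append(f"column {time!r} has missing/non-numeric values")
    elif (t <= 0).any():
        problems.append(f"column {time!r} has non-positive times (first at row "
                        f"{int(np.argmax(t.to_numpy() <= 0))})")
    if e.isna().any() or not set(e.dropna().unique()).issubset({0, 1}):
        problems.append(f"column {event!r} must be binary 0/1")
    if x.isna().any() or not set(x.dropna().unique()).issubset({0, 1}):
        problems.append(f"column {exposure!r} must be binary 0/1")

    drop = [c for c in (time, event, exposure, id_column) if c in table.columns]
    cov = table.drop(columns=drop)
    non_numeric = [c for c in cov.columns if not np.issubdtype(
        pd.to_numeric(cov[c], errors="coerce").dtype, np.number)]
    cov = cov.apply(pd.to_numeric, errors="coerce")
    na_cols = [c for c in cov.columns if cov[c].isna().any()]
    if na_cols:
        problems.append(f"covariates with missing values: {na_cols[:10]}")
    if problems:
        raise ValueError("; ".join(problems))

    constant = [c for c in cov.columns if cov[c].nunique() <= 1]
    if constant:
        import warnings

        warnings.warn(f"zero-variance covariates retained but unselectable: "
                      f"{constant[:10]}", stacklevel=2)
    ds = MediationDataset(
        time=t.to_numpy(dtype=np.float64),
        event=e.to_numpy(dtype=np.int64),
        exposure=x.to_numpy(dtype=np.int64),
        covariates=cov.astype(np.float64),
    )
    ds.validate()
    return ds
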