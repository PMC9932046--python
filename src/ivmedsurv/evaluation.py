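"""Selection/estimation metrics and replicated simulation benchmarks.

FDR and PSR follow the usual selection conventions: with TP/FP/FN counted
against the known truth, ``FDR = FP/(FP+TP)`` (defined as 0 when nothing is
selected) and ``PSR = TP/(TP+FN)``. Indirect-effect recovery is summarized
by the Monte-Carlo mean and mean squared error against the generating
``lambda*gamma``, collected per true mediator over the replicates in which
that mediator was estimable (i.e. entered the candidate set).

The two benchmark drivers mirror the structure of the published simulation
grids: a selector comparison (lasso / adaptive lasso / elastic net / MCP for
the instrument-selection step, scored on the candidate-instrument set after
the mediator partition) and a mediation benchmark over method x test x
sample size x censoring rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .iv_estimation import NoValidInstrumentsError, partition_candidates
from .mediation_inference import decide_mediators
from .penalized_models import PenaltySpec, select_ivs, select_mediators
from .pipeline import PipelineConfig, run_classical, run_proposed
from .screening import sis_screen
from .simulate import SimulationConfig, generate_dataset, scenario_sparse

__all__ = [
    "CellMetrics",
    "compute_fdr_psr",
    "compute_mse",
    "replicate_seed",
    "run_selector_benchmark",
    "run_mediation_benchmark",
]


@dataclass
class CellMetrics:
    method: str
    test: str
    selector: str
    n: int
    censor_rate: float
    fdr: float
    psr: float
    replicates: int
    failures: int = 0
    effect_estimates: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "method": self.method,
            "test": self.test,
            "selector": self.selector,
            "n": self.n,
            "censor_rate": self.censor_rate,
            "fdr": self.fdr,
            "psr": self.psr,
            "replicates": self.replicates,
            "failures": self.failures,
        }
        for key, stats in self.effect_estimates.items():
            row[f"mean[{key}]"] = stats["mean"]
            row[f"mse[{key}]"] = stats["mse"]
            row[f"reps[{key}]"] = stats["n"]
        return row


def compute_fdr_psr(selected: Iterable[int], truth: Iterable[int]) -> tuple[float, float]:
    """False discovery rate (0 when nothing selected) and positive selection rate."""
    sel = set(int(i) for i in selected)
    tru = set(int(i) for i in truth)
    if not tru:
        raise ValueError("truth set must be non-empty for PSR")
    tp = len(sel & tru)
    fp = len(sel - tru)
    fn = len(tru - sel)
    fdr = fp / (fp + tp) if (fp + tp) > 0 else 0.0
    psr = tp / (tp + fn)
    return fdr, psr


def compute_mse(estimates: Sequence[float], true_value: float) -> tuple[float, float]:
    """Monte-Carlo mean and mean squared error against the generating value."""
    est = np.asarray(estimates, dtype=np.float64)
    if est.size < 2:
        raise ValueError("need at least two replicate estimates")
    return float(est.mean()), float(np.mean((est - true_value) ** 2))


def replicate_seed(seed: int, *keys: int) -> int:
    """Deterministic per-replicate seed below 2^31."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


def iv_selection_replicate(config: SimulationConfig, selector: str = "mcp"):
    """Steps 1-4 on one simulated dataset; returns (candidate IV set, true IV set).

    The logistic selector varies; the Cox mediator selector stays MCP (the
    method's default), and the scored set is I2 = I1 \\ M1.
    """
    data = generate_dataset(config)
    screening = sis_screen(data)
    I1 = select_ivs(data, screening, PenaltySpec(family=selector, refine=False))
    M1 = select_mediators(data, screening)  # MCP at the default operating point
    try:
        I2 = partition_candidates(I1, M1)
    except NoValidInstrumentsError:
        I2 = np.empty(0, dtype=np.int64)
    return set(int(i) for i in I2), set(data.truth["true_ivs"])


def run_selector_benchmark(
    *,
    selectors: Sequence[str] = ("lasso", "alasso", "enet", "mcp"),
    ns: Sequence[int] = (200, 500, 800),
    censor_rates: Sequence[float] = (0.2, 0.4, 0.6),
    reps: int = 100,
    seed: int = 0,
    scenario: Callable[[int, float, int], SimulationConfig] = scenario_sparse,
) -> pd.DataFrame:
    """Instrument-selection FDR/PSR grid over selector x n x censoring."""
    rows = []
    for si, selector in enumerate(selectors):
        for ni, n in enumerate(ns):
            for ci, cens in enumerate(censor_rates):
                fdrs, psrs, failures = [], [], 0
                for rep in range(reps):
                    rseed = replicate_seed(seed, 1, ni, ci, rep)
                    try:
                        sel, tru = iv_selection_replicate(
                            scenario(n, cens, rseed), selector
                        )
                        fdr, psr = compute_fdr_psr(sel, tru)
                        fdrs.append(fdr)
                        psrs.append(psr)
                    except (ValueError, RuntimeError):
                        failures += 1
                rows.append(
                    CellMetrics(
                        method="iv", test="-", selector=selector, n=n,
                        censor_rate=cens,
                        fdr=float(np.mean(fdrs)) if fdrs else np.nan,
                        psr=float(np.mean(psrs)) if psrs else np.nan,
                        replicates=len(fdrs), failures=failures,
                    ).as_row()
                )
    return pd.DataFrame(rows)


def _effect_key(lam: float, gam: float) -> str:
    return f"gamma={gam:g},lambda={lam:g}"


def run_mediation_benchmark(
    *,
    methods: Sequence[str] = ("iv", "classical"),
    tests: Sequence[str] = ("sobel", "joint", "boot"),
    ns: Sequence[int] = (200, 500, 800),
    censor_rates: Sequence[float] = (0.2, 0.4, 0.6),
    reps: int = 100,
    seed: int = 0,
    B: int = 200,
    scenario: Callable[[int, float, int], SimulationConfig] = scenario_sparse,
) -> pd.DataFrame:
    """Mediator detection and effect recovery over method x test x n x censoring.

    One pipeline run per (method, n, censoring, replicate) feeds all the
    requested tests; the bootstrap is executed only when requested. Failed
    replicates are excluded and counted.
    """
    run_boot = "boot" in tests
    rows = []
    for mi, method in enumerate(methods):
        runner = run_proposed if method == "iv" else run_classical
        for ni, n in enumerate(ns):
            for ci, cens in enumerate(censor_rates):
                per_test = {t: {"fdr": [], "psr": []} for t in tests}
                estimates: dict[str, list[float]] = {}
                true_values: dict[str, float] = {}
                failures = 0
                done = 0
                for rep in range(reps):
                    rseed = replicate_seed(seed, 2, mi, ni, ci, rep)
                    config = scenario(n, cens, rseed)
                    try:
                        data = generate_dataset(config)
                        result = runner(
                            data,
                            PipelineConfig(run_bootstrap=run_boot, B=B, seed=rseed),
                        )
                    except (ValueError, RuntimeError):
                        failures += 1
                        continue
                    done += 1
                    truth = set(data.truth["true_mediators"])
                    for t in tests:
                        sel = decide_mediators(result.tests, 0.05, t)
                        fdr, psr = compute_fdr_psr(sel, truth)
                        per_test[t]["fdr"].append(fdr)
                        per_test[t]["psr"].append(psr)
                    lam_col = data.truth["lambda_by_column"]
                    gam_col = data.truth["gamma_by_column"]
                    if result.fit is not None:
                        in_m1 = {int(c): k for k, c in enumerate(result.fit.M1)}
                        for col in sorted(truth):
                            key = _effect_key(lam_col[col], gam_col[col])
                            true_values[key] = float(lam_col[col] * gam_col[col])
                            if col in in_m1:
                                estimates.setdefault(key, []).append(
                                    float(result.fit.indirect_effects[in_m1[col]])
                                )
                for t in tests:
                    eff = {}
                    for key, vals in estimates.items():
                        if len(vals) >= 2:
                            mean, mse = compute_mse(vals, true_values[key])
                            eff[key] = {"mean": mean, "mse": mse, "n": len(vals)}
                    rows.append(
                        CellMetrics(
                            method=method, test=t, selector="mcp", n=n,
                            censor_rate=cens,
                            fdr=float(np.mean(per_test[t]["fdr"])) if done else np.nan,
                            psr=float(np.mean(per_test[t]["psr"])) if done else np.nan,
                            replicates=done, failures=failures,
                            effect_estimates=eff,
                        ).as_row()
                    )
    return pd.DataFrame(rows)
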