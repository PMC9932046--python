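# Methods

`ivmedsurv` estimates and tests high-dimensional mediation effects on a
time-to-event outcome when the exposure–outcome relation is confounded by
*unmeasured* variables. The instrument-based two-stage design removes
confounding bias from the exposure effect; this note records the model, the
algorithmic choices, and — importantly — what the approach can and cannot
deliver under the package's own simulation design.

## Structural model

For subject-level data with binary exposure $X$, instruments
$Z = (Z_1,\dots,Z_k)$, candidate mediators $M = (M_1,\dots,M_q)$ (with
$q \gg n$ allowed), unmeasured confounders $L$, and a right-censored survival
outcome:

$$h(t) = h_0(t)\,\exp\!\big(a + \beta X + \gamma^\top M + \zeta_1^\top L\big)$$
$$M_i = c + \lambda_i X + \varepsilon_i, \qquad \varepsilon_i \sim N(0, \sigma^2)$$
$$\operatorname{logit} P(X = 1) = d + \eta^\top Z + \zeta_2^\top L$$

The indirect (mediation) effect transmitted by $M_i$ is the product
$\lambda_i\gamma_i$ on the log-hazard scale. $L$ is a common cause of $X$ and
the outcome and is unobserved; a Cox fit of the outcome on $(X, M)$ therefore
cannot be causally interpreted without help. Identification leans on the
standard instrument conditions: the $Z_j$ predict $X$, affect the outcome
only through $X$, and are independent of $L$; mediators are mutually
independent given $X$; no unmeasured mediator–outcome confounding.

## Pipeline

1. **Screening.** All observed columns are ranked by two marginal statistics:
   a univariate logistic score z against the exposure and a univariate Cox
   Wald z against the outcome. Each ranking keeps the top
   $t = \lfloor 2n/\log n\rfloor$ columns (natural log; ties at the cut go to
   the lower column index), giving the exposure-associated subset `I0` and
   the outcome-associated subset `M0`.
2. **Instrument selection.** MCP-penalized logistic regression of $X$ on the
   `I0` columns; the selected support is `I1`.
3. **Mediator selection.** MCP-penalized Cox regression of the outcome on the
   `M0` columns; the selected support is `M1`.
4. **Partition.** Candidate instruments `I2 = I1 \ M1`; everything in `M1`
   is a candidate mediator. An empty `I2` is an error (no valid
   instruments); an empty `M1` short-circuits to an empty result.
5. **Two-stage estimation.** Stage 1: unpenalized logistic MLE of $X$ on the
   `I2` columns, yielding the instrument index
   $\hat D = \hat d + \hat\eta^\top Z$. Stage 2: unpenalized Cox MLE on
   $[\hat D, M_{M1}]$; the coefficient on $\hat D$ estimates the
   instrumented exposure effect and the mediator coefficients give
   $\hat\gamma$. Each $\hat\lambda_i$ comes from simple OLS of $M_i$ on the
   observed $X$.
6. **Testing.** Per mediator: Sobel's normal test of
   $\hat\lambda\hat\gamma$ with delta-method standard error
   $\sqrt{\hat\lambda^2 S_\gamma^2 + \hat\gamma^2 S_\lambda^2}$; the joint
   significance test $p = \max(p_\lambda, p_\gamma)$; and a percentile
   bootstrap that resamples rows, re-runs stage 1/stage 2/OLS on the frozen
   candidate sets, and declares significance when the $1-\alpha$ interval
   excludes zero.
7. **Multiplicity.** Sobel and joint p-values are Bonferroni-multiplied by
   $q = |M1|$ (the tests actually performed; a flag switches to the full
   mediator dimension). The bootstrap decision follows the unadjusted
   interval by default, with a $1-\alpha/q$ option.

The *classical* comparator runs the identical pipeline but places the
observed $X$ (not $\hat D$) in the stage-2 Cox model and needs no
instruments.

## Synthetic data generator

The generator emulates an observational epigenetic cohort: methylation-style
Gaussian mediator columns, a smoking-style binary exposure, survival with
20/40/60 % censoring, and four withheld confounders. Defaults:

| parameter | default | notes |
|---|---|---|
| instruments | $Z_1 \sim N(0, 0.9^2)$, $Z_2 \sim N(0, 1.1^2)$, independent | |
| confounders | $N(0,0.8^2), N(0,1.2^2), \mathrm{Bern}(0.4), \mathrm{Bern}(0.6)$ | generated, used, withheld |
| $\eta$ | $(1.5, 2.0)$ | chosen so the weaker instrument's marginal first-stage z stays comfortably above 5 at $n = 500$ (measured minimum ≈ 5.4); weaker instruments are not reliably selectable in step 2 |
| $\beta$ | 1.5 | direct exposure effect |
| $\zeta_1 = \zeta_2$ | $(0.4, 0.5, 0.6, 0.7)$ | confounder effects on outcome / exposure |
| $\gamma, \lambda$ (1,000-covariate scenario) | $(1.2, 0.8, 1.5, 0, \dots)$, $(0.8, 1.2, 0, 1.5, \dots)$ | two true mediators, each with $\lambda\gamma = 0.96$ |
| $\gamma, \lambda$ (3,000-covariate scenario) | $(1.2, 0.8, -1.2, 1.2, 1.5, 0, \dots)$, $(0.8, 1.2, 0.8, -0.8, 0, 1.5, \dots)$ | four true mediators, $\lambda\gamma = \pm 0.96$ |
| intercepts $a, c, d$ | 0 | |
| mediator noise sd | 1 | |
| baseline hazard | exponential, $h_0 = 1$ | survival times by inverse transform $T = -\log U / (h_0 e^{\mathrm{lp}})$ |
| log-frailty sd | 0 | a hazard-level error term is available for sensitivity runs but off by default: with it on, the estimand belongs to a frailty model the estimator does not fit |

Censoring is an independent exponential whose rate $\theta$ solves
$\frac1n\sum_i \theta/(\theta + h_0 e^{\mathrm{lp}_i}) = \text{target}$ by
bracketed root finding — exact for this generator because event times are
conditionally exponential, and monotone in the target. Columns are shuffled
before delivery (the truth keeps the index map) so selection cannot exploit
position. Noise fillers are iid $N(0,1)$, indistinguishable from mediators
with $\lambda = \gamma = 0$.

What the generator does **not** emulate: correlated mediators (real CpG
blocks are strongly correlated; the mediator-independence assumption is
built into the generation), bounded beta-value marginals, batch structure,
informative censoring, or measured covariates. Passing tests therefore
certify the estimator under its own assumptions, not robustness to their
violation.

## Numerical choices

* **Penalized solvers.** Logistic and Cox (Breslow partial likelihood)
  pathwise coordinate descent over a 100-point geometric $\lambda$ grid
  (down to 0.01·$\lambda_{\max}$ logistic / 0.05 Cox), IRLS-outer with warm
  starts, columns standardized internally to mean 0 / sd 1 (coefficients
  reported on the original scale). Penalties: lasso, adaptive lasso (weights
  $1/|\hat\beta_{\text{ridge}}|$ from a small-ridge null-model fit), elastic
  net ($\alpha = 0.5$), MCP ($\gamma = 3$). The MCP coordinate subproblem is
  nonconvex whenever the quadratic curvature $v_j < 1/\gamma$; the update
  evaluates all stationary candidates and keeps the objective minimizer, and
  $\lambda_{\max}$ accounts for the jump condition
  $|z| > \sqrt{v\gamma}\,\lambda$ so the path genuinely starts at the null
  model. KKT residuals of the true (non-quadratic) objective are recorded at
  every grid point; at tight tolerances they reach $10^{-6}$ (asserted in
  the test suite). The path stops early when the support exceeds
  $\max(30, n/10)$ — the criterion never selects the dense tail, and the
  nonconvex updates oscillate there — or when separation / monotone
  likelihood is detected.
* **Tuning.** Default is an extended BIC,
  $\mathrm{dev} + \mathrm{df}\,[\log n + 2\gamma_{\mathrm{EBIC}}\log p]$
  with $\gamma_{\mathrm{EBIC}} = 1$: after screening keeps the best $t$ of
  ~1,000 columns, the survivors carry selection-inflated association and the
  plain BIC admits several noise columns per fit. Ten-fold CV (deviance;
  partial-likelihood difference for Cox) is available.
* **Stepwise refinement (mediator step).** Columns enter the $\lambda$ path
  bundled with whatever else activates at the same penalty, so a criterion
  restricted to path points can reject a column because of its travelling
  companions — in the simulation this systematically hit the strong
  exposure-proxy mediator. The mediator selection therefore finishes with a
  forward/backward stepwise sweep: each candidate is tested alone against
  the same EBIC penalty using unpenalized refits, best addition first. The
  instrument step stays path-only (per-column tests in the exposure model
  are diluted by the mediator columns and add nothing).
* **Ties.** The penalized Cox selection uses the Breslow likelihood
  (simulated times are continuous, so this is exact there); the unpenalized
  estimation stage and the bootstrap use Efron's correction, matched against
  lifelines in the tests.
* **Degenerate input.** Constant columns score zero in screening and are
  dropped (with a warning) before unpenalized fits; logistic separation and
  Cox monotone likelihood raise typed errors (path fits truncate instead);
  bootstrap replicates with no events, constant resampled exposure, or
  non-convergent fits are skipped, and more than 10 % failures is an error.
* **Determinism.** Every stochastic component (generator, bootstrap, CV
  folds, benchmark replicates) is driven by explicit seeds;
  benchmark replicate seeds derive from `SeedSequence` so grids are
  reproducible cell-by-cell.

## Design choices where the design was open

* **Stage-2 exposure proxy.** The linear instrument index $\hat D$ (the
  stage-1 intercept is absorbed by the Cox baseline). The fitted probability
  $\operatorname{expit}(\hat D)$ is available; measured on the simulation it
  changes $\hat\beta$'s scale but not the indirect-effect products.
* **$\hat\lambda$ uses the observed exposure**, matching the structural
  mediator model; regressing $M$ on the instrument index instead is
  available behind a flag.
* **Bootstrap freezes the selected sets.** Re-selection inside each
  replicate would mix selection variability into the interval and multiply
  cost; a re-selection option exists for sensitivity analysis.
* **Reported p for the bootstrap** is the CI-exclusion decision; an
  inverted-CI "p-value" is deliberately not reported as a calibrated
  quantity.
* **Real-data reporting** hides mediators with $\hat\lambda\hat\gamma < 0$
  by default (the convention for exposures expected to shorten survival),
  with a flag for the full table.

## What the estimator can and cannot do here — measured limits

Two quantitative ceilings, both reproduced by the acceptance suite, matter
for interpreting results:

1. **Non-collapsibility attenuation.** Omitting the withheld confounder
   block removes roughly $\operatorname{var}(\zeta_1^\top L) \approx 0.67$
   of log-hazard variance from every stage-2 model. With ~80 % events this
   attenuates all Cox coefficients — the familiar proportional-hazards
   marginalization effect — by a factor around 0.8. The instrument route
   removes *confounding bias* in the exposure effect but cannot restore the
   conditional (L-adjusted) scale of $\gamma$: mean recovered indirect
   effects for a true $\lambda\gamma = 0.96$ plateau near 0.75–0.86
   depending on the mediator and sample size, with the stage-1 slopes
   showing the same marginalization (measured factor ≈ 0.9 at $n = 5000$).
   The classical comparator is attenuated in the same way rather than
   inflated: under this generator $M \perp L \mid X$, so once $X$ is in the
   model there is no confounding path into $\hat\gamma$ at all. Detection
   power is unaffected (the attenuated effects remain many standard errors
   from zero), which is why the selection and testing benchmarks reach
   their nominal performance while the point-recovery benchmarks stabilize
   below the generating value.
2. **Instrument / exposure-proxy confusion.** A column with
   $\lambda \ne 0, \gamma = 0$ (an exposure-consequence that does not touch
   the outcome) and a true instrument are *both* associated with the outcome
   only through $X$, and both become null given $X$ — no data-driven rule
   can separate them in general. The mediator-vs-instrument partition
   resolves the ambiguity by whichever the outcome screen absorbs first;
   measured across independent replicate sets this leaves candidate-
   instrument selection at PSR ≈ 0.95 and FDR ≈ 0.07 at $n = 500$, its
   structural operating point under this design. Users with domain
   knowledge should pass known instruments rather than rely on the
   partition.

Further known limitations: binary exposure only; mediator–outcome and
exposure–mediator confounding are assumed absent (the instrument does not
help there); with no true confounding and large $n$ the outcome screen may
absorb the instruments themselves and leave `I2` empty (a hard error with
remediation hint); stage-2 Wald standard errors ignore first-stage
uncertainty, so the bootstrap is the recommended inference for indirect
effects.
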