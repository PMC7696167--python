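# Methods

## The model

`roscopk` implements a population pharmacokinetic model for orally
administered roscovitine (seliciclib) and its carboxylate metabolite M3 in
adult cystic-fibrosis patients. All computation is done in molar units
(doses in µmol with molar masses 354.45 g/mol for the parent and
368.43 g/mol for M3, concentrations in nmol/L); exposures are reported in
ng·h/mL.

### Structural model

A single oral dose D (µmol) splits pre-systemically:

* a fraction `F_dose = D/(D + D50)` reaches the circulation as parent drug
  (`D50` = 1190 µmol typical: the dose at which half escapes first pass);
* the complement `1 − F_dose` enters directly as metabolite M3.

Absorption-input rates are inverse-Gaussian (IG) densities parameterised
by the time of their maximum `Tmax` and a coefficient of variation `CV`:

    IG(t) = sqrt(MAT / (2π CV² t³)) · exp(−(t − MAT)² / (2 CV² MAT t))
    MAT   = Tmax / (sqrt(1 + (9/4)CV⁴) − (3/2)CV²)

The MAT expression is the unique mean making `Tmax` the mode of the
density (an IG with mean m and shape λ has mode
m·(sqrt(1+9m²/4λ²) − 3m/2λ) and CV² = m/λ); its correctness is verified in
the tests by numerically locating the density's argmax. The parent input
is a two-phase mixture with weights `pi1` and `1 − pi1` and phase modes
`T1max` and `T2max = T1max + dT2max` (the increment parameterisation keeps
the phases ordered); the metabolite input is a single IG sharing `T1max`
and `CV1` — an identifiability constraint of the final model.

Disposition is linear: central + peripheral compartments for the parent
(`k12`, `k21`), irreversible conversion to M3 (`kmet`, the parent's only
elimination route — direct parent elimination was not identifiable), and
first-order elimination of M3 (`ke`). One apparent central volume `V`
(i.e. V/F) is shared by both analytes because M3 was never dosed directly.
Consequences used as test oracles: AUC∞(parent) = F·D/(kmet·V) and
AUC∞(M3) = D/(ke·V) (all dose mass exits through M3).

### Stochastic model

Seven parameters carry log-normal inter-individual variability — D50,
T1max, dT2max, CV1, CV2, V, ke, in that fixed order — with two estimated
correlations, (T1max, CV2) and (dT2max, CV1); `pi1`, `k12`, `k21`, `kmet`
are population constants. Covariates: proton-pump-inhibitor use multiplies
T1max by `exp(0.680)` (the published table attaches the PPI coefficient to
T1max; the accompanying text mentions dT2max — a `ppi_target` switch moves
the effect there without re-estimating), and the apparent volume scales as
`(height/170 cm)^6.47`. Residual error is proportional for the parent
(b1 = 0.297) and combined additive + proportional for M3 (a2 = 9.20 nmol/L,
b2 = 0.271). Observations below the 5.00 ng/mL LLOQ (14.11 / 13.57 nmol/L
after conversion) are left-censored.

## Numerics

* Reference single-profile solver: LSODA, rtol 1e-8 / atol 1e-10, output
  grid 0.02 h on [0, 12] h. The IG density is evaluated as 0 for
  t ≤ 1e-12 h.
* Batch solver (simulation, estimation, diagnostics): classical RK4 with
  input rates precomputed on a half-step grid, vectorized across subjects.
  At 0.02 h it agrees with the adaptive reference to better than 2e-4
  relative (tested); estimation uses 0.05 h, ample for observation-time
  predictions. Parameter draws extreme enough to overflow the explicit
  integrator (tail proposals inside samplers) are detected and treated as
  zero-likelihood.
* AUC(0–12h): trapezoid on the noise-free model curve (residual error is
  never added before integrating — adding it would only inject noise into
  a deterministic quantity).
* Quantiles/medians use linear interpolation (numpy default, type 7).

## Synthetic-trial generator

The generator emulates the ROSCO-CF first-dose design: 23 subjects in
three arms (9 × 200 mg, 7 × 400 mg, 7 × 800 mg), sampling pre-dose and at
0.5, 1, 2, 4, 6, 8, 12 h, both analytes with the 5 ng/mL LLOQ, heights
uniform on 158–182 cm (the published table gives only median and range)
and PPI prevalence 15/23. Pre-dose rows are always censored. Negative
simulated values (possible under M3's additive error) are censored, never
truncated to zero. The full 7-point post-dose grid is kept by default (the
real study averaged ~6 points/subject; an optional `missing_rate`
reproduces that on average — determinism first, realism optional). Each
subject consumes a counter-derived RNG substream, so results are
independent of subject order. The generator does not emulate dropout,
dosing non-compliance, assay batch effects, or the repeat-dose schedule —
so passing recovery tests demonstrate correctness of the estimator under
the model, not robustness to real-data misspecification.

## Estimation (SAEM)

Individual parameters are sampled on a transformed scale (log; logit for
`pi1`) by Metropolis-Hastings, three kernel types per iteration: an
independence proposal from the current population law, joint random walks
(per-subject adaptive scale targeting ~30% acceptance), and
single-coordinate random walks (each subject perturbs one randomly chosen
coordinate; per-coordinate adaptive scale targeting ~44%) — the
coordinate kernel is what gives weakly-informed coordinates such as D50
usable mixing. Censored observations are Gibbs-imputed each iteration from
the truncated (below-LLOQ) Gaussian predictive, which is equivalent in
expectation to the censored-data likelihood; the direct `log Φ` form is
used in individual likelihoods, EBEs and the observed-data likelihood.
Pre-dose rows are excluded from fitting: the single-dose model predicts
exactly zero there, making them uninformative and numerically degenerate
under a proportional error model.

Population updates per iteration: typical values and covariate
coefficients by generalized least squares on the (stochastic-approximation
averaged) individual log-parameters under the current Ω; Ω from its
sufficient statistics, projected onto the model's sparsity pattern
(diagonal plus the two estimated correlation pairs, correlations clipped
to |r| ≤ 0.95, variances floored at 0.02²); the parent's proportional
error from its exact sufficient statistic; M3's combined error by a damped
Nelder-Mead solution of the complete-data likelihood (no closed form
exists). Two stabilizers that matter in practice: simulated annealing
(during the exploratory phase, variance parameters may shrink by at most
5% per iteration — without it the variability collapses onto the residual
error before the chains mix), and a decreasing artificial variance for the
no-IIV parameters (start 0.5, ×0.995 per iteration, floored at 0.08 during
exploration and 0.01 afterwards — a faster decay freezes `pi1` short of
its optimum).

Defaults: 400 exploratory iterations (step 1) + 200 smoothing iterations
(step `1/k^0.7`). At the study scale a fit takes ~0.5 min on one core; the
100-subject recovery runs use 600 + 300.

The observed-data −2LL is estimated per subject by importance sampling
(default 1000 draws) from a multivariate-t (df 4) proposal centred at the
posterior-mode η with scale from a finite-difference Hessian; the mode
search runs L-BFGS with batched finite-difference gradients after a
64-draw prior scan that picks the starting basin (the posterior can be
multimodal). BICc penalizes the 18 parameters describing the individual-
parameter distribution (7 typical values with IIV, 7 ω, 2 correlations,
2 covariate coefficients) by ln N and the 7 others (4 no-IIV structural +
3 error) by ln n_obs. η-shrinkage is `1 − SD(η̂)/ω`; ε-shrinkage is
`1 − SD(IWRES)` over uncensored rows.

First-order and lagged first-order absorption comparison models share the
disposition and the saturable split, apply the same `ka` (and lag) to both
dose fractions, carry IIV on (D50, ka, V, ke) and no covariates, and are
compared by BICc.

## Diagnostics

NPDE: `n_sim` (default 1000) replicates of the design are simulated with
residual error; per subject, observed and simulated vectors are
decorrelated by the inverse Cholesky factor of the empirical simulated
covariance on an `asinh(x/7 nmol/L)` scale — log-like where concentrations
are high (the predictive is near log-normal, so the linear decorrelation
is adequate there) and smooth through zero where M3's additive error puts
simulated values. Below-LLOQ data are handled symmetrically: the censored
observation is imputed at a uniform quantile of the sub-LLOQ predictive
and simulated BLQ values are shuffled within their column (a marginal
redraw), keeping observed and simulated vectors exchangeable so that every
component can be ranked after decorrelation; censored rows stay flagged
for plotting. Summaries report mean, variance, Shapiro-Wilk (shape) and
Kolmogorov-Smirnov vs N(0,1) (location/scale-sensitive; the one with power
against e.g. a misspecified volume, whose mean shift partly hides inside
the decorrelation). Null calibration at the study design: mean within
±0.1, variance within [0.85, 1.15] and normality not rejected, each in
≈19/20 replicate trials.

pcVPC: per Bergstrand's prediction correction — every observed and
simulated value is scaled by bin-median population prediction over its own
population prediction (typical parameters with the subject's covariates,
η = 0); bins default to the nominal sampling times; empirical 10/50/90
percentiles are overlaid on 95% bands from replicate-level percentiles;
censored observations are excluded from percentiles and reported as a
per-bin BLQ fraction.

## Monte Carlo dose simulations

Scenario engine: n subjects (default 1000) per dose, reference covariates
(height 170 cm, no PPI) by default — the covariate distribution used for
the published simulations is not stated, and reference covariates
reproduce the printed medians because the median of `exp(η)` is 1; a
sampled-covariates policy exists for sensitivity analysis. AUC ratios are
computed per subject and then summarized (median of ratios). PPI
comparisons share the random-effect draws between arms (common random
numbers).

## Known limitations

* No standard errors / %RSE (no Fisher-information machinery); a bootstrap
  would be the natural extension.
* SAEM end-game precision: in the noiseless limit the residual variance
  collapse outpaces the population-mean updates, so exact recovery is
  asymptotic in iterations; the tests assert convergence toward truth, and
  parameter-recovery quality is quantified at realistic noise on 100
  synthetic subjects (fixed effects within ±20%, ω within ±30%).
* β for height on V is intrinsically noisy at these sample sizes (the
  height range spans only ±7% around the reference).
* Single-dose only: no accumulation, no inter-occasion variability.
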