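# Methods

## The measurement model

Each region of interest (ROI) is modeled independently. At occasion
t ∈ {1, 2, 3} the latent integrity factor η_t is measured by three
modality indicators:

    y_{m,t} = τ_m + λ_m η_t + u_m + ε_{m,t}

* **τ_m** — indicator intercept, held equal across occasions within an
  indicator at *every* invariance level, so the latent change means remain
  interpretable as occasion-mean differences on the indicator scale.
* **λ_m** — factor loading. VBM is the reference indicator, fixed to 1 at
  every occasion (it loads positively in this literature across all ROIs,
  which makes the MD loading come out negative, as it should: higher mean
  diffusivity means lower tissue integrity). Factor variances are free.
* **u_m** — a participant-level method effect per modality, constant over
  occasions. Its variance appears as an equality-constrained residual
  covariance between the three occasions of a modality — one parameter per
  modality. This is the minimal mechanism producing equal within-modality
  cross-occasion covariances.
* **ε_{m,t}** — occasion-specific residual.

The latent trajectory is a change score structure with unit paths:
η₂ = η₁ + Δ₂₁ and η₃ = η₂ + Δ₃₂. Free latent parameters per group: the
baseline variance ψ₁, change means μ₂₁/μ₃₂, change variances, and the three
covariances among (η₁, Δ₂₁, Δ₃₂). The baseline latent mean is fixed to 0
per group; group baseline differences live in the intercepts.

**Invariance levels.** `configural` frees loadings and residual variances
per occasion and group; `metric` equates loadings across occasions and
groups; `strict` additionally equates residual variances. "Strict" is
operationalized as residual-variance (not intercept) equality because the
invariance-test degrees of freedom then follow the 2/3 (group) and 4/6
(occasion) pattern of the ladder below; intercepts are instead equal
across occasions at all levels. This is a deliberate reconstruction of an
under-determined design choice and is the main caveat when comparing df
accounting with other implementations.

**Fitness and the bivariate model.** VO₂peak is observed at occasions 1
and 3 only; a pseudo-latent difference factor gives the exactly identified
two-occasion model (5 parameters, 5 moments, df = 0 per group). The
bivariate model is the union of the two structures plus six free
covariances: (ΔFit, Δ₂₁), (ΔFit, Δ₃₂), (fit₁, η₁), (fit₁, Δ₂₁),
(fit₁, Δ₃₂), (ΔFit, η₁). The change–change covariance φ, standardized by
the implied change SDs, is the coupling of interest; standardized values
may exceed |1| when a latent block is not positive definite and are then
reported with a diagnostic, never clipped.

**Covariates.** Age, sex (female = 1) and education enter, on request, as
exogenous manifests with free means, variances and pairwise covariances,
plus directed paths to η₁, Δ₂₁ and Δ₃₂ per group. Covariances among
covariates are free because age/sex/education correlate; fixing them to 0
would distort the FIML likelihood of incomplete cases.

## Estimation

The kernel is RAM algebra: Σ = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ, μ = F(I−A)⁻¹M per
group. The objective is the full-information −2 log-likelihood; cases are
grouped by missingness pattern (contractually identical to case-by-case
evaluation, which the tests verify). Numerical choices:

* optimizer L-BFGS-B, finite-difference (3-point) gradients, objective
  tolerance 1e-10, up to 5 restarts with seeded 10% jitter; variance
  parameters (labels appearing only on the S diagonal) bounded below at
  1e-6 unless a model fixes them (boundary tests fix, not bound);
* a non-positive-definite implied covariance maps to a large finite
  ceiling (1e12) rather than +∞ so finite-difference gradients stay
  defined near the boundary; an optimum at the ceiling is reported as
  non-convergence;
* nested fits are warm-started from their parent's solution (equality-
  merged labels take the average of the parent estimates); if a child
  still undercuts its parent's −2lnL, the parent is refitted warm-started
  from the child — the child's solution is feasible for the parent, so
  this only improves. Negative χ² differences beyond 1e-4 after that are
  hard errors, signalling an optimization failure rather than noise;
* standard errors from the inverse of one-half the numerical (central-
  difference) Hessian of −2lnL; a non-PD Hessian yields missing SEs with a
  diagnostic (Heywood-adjacent), never silent numbers;
* the saturated model per group is closed-form for complete data
  (n(k ln 2π + ln|S_ML| + k)) and otherwise optimized by the same FIML
  machinery with the covariance parameterized through its Cholesky factor;
  the independence model separates per variable and is closed-form even
  under missingness;
* RMSEA uses √(max(0, χ²−df)/(df·(N−1))) with N the total across groups
  and no multigroup inflation factor — one convention, stated rather than
  assumed, since fit-index formula variants differ across SEM software;
  the 95% CI inverts the noncentral-χ² CDF in the noncentrality parameter
  (coverage 0.975/0.025) by bracketed root finding;
* CFI = 1 − max(0, χ²−df)/max(χ²−df, χ²_b−df_b, 0). Because the model
  carries a constrained mean structure while the conventional independence
  baseline saturates the means, the model df can exceed the baseline df;
  the max(·, 0) denominator keeps CFI in [0, 1] and the usual
  baseline-df ≥ model-df precondition is deliberately not enforced;
* exactly identified models (df = 0) report RMSEA as undefined and
  CFI = 1 — fit is perfect by definition, and saying so is more honest
  than printing a 0/0.

## Inference

The likelihood-ratio test compares a parent (parameter free) with a nested
child (parameter fixed to 0 or merged across groups); nesting is verified
structurally by free-location inclusion, so equality-merged labels count
as nested. Δχ² = child(−2lnL) − parent(−2lnL), p from the central χ²
upper tail. For df = 1 with a directional hypothesis, p_one = p_two/2 when
the free estimate's sign matches the hypothesis and 1 − p_two/2 otherwise;
the standing directions are positive change in the exercise group,
negative in the control group, and positive for the EG-minus-ACG
difference and for change–change couplings. Directional tests are defined
for df = 1 only; multi-df comparisons report two-sided p-values.

The factorial-invariance ladder runs, per ROI, in fixed order: group
invariance on the occasion-1 factor (configural→metric df 2,
metric→strict df 3), then occasion invariance on the pooled three-occasion
model with groups collapsed into one sample (configural→metric df 4,
metric→strict df 6), stopping at the first step significant two-sided at
α = 0.05. No multiplicity correction is applied across ROIs (a documented,
liberal choice; the pipeline's `--fdr` flag offers Benjamini–Hochberg as a
clearly-marked extension). "Groups collapsed" means a single-group fit on
pooled raw data — the plainer of the two readings; an equality-constrained
two-group alternative would test the same hypothesis against a different
baseline.

The reliable-variance-in-change gate fixes a change factor's variance and
its covariances to zero and halves the two-sided p (a 50:50 χ² mixture
heuristic for the boundary null, flagged as heuristic in the output).
Change–change models are fitted only for ROI × interval cells that pass
both the group-difference gate and the variance gate; the pipeline asserts
this invariant on every run.

## The synthetic generator

`SimConfig` defaults encode the study conditions the package emulates:
35 controls and 40 exercisers aged 63–77, three occasions, MD the
strongest indicator (standardized loading ≈ −0.86, VBM ≈ 0.53, MT ≈ 0.46
via the residual-SD defaults — these observed reliabilities are generator
knobs, not claims), control-group latent decline of 0.15/0.20 SD per
three-month interval against near-zero exerciser change, change SDs of
0.3, fitness baseline 23 ± 5.5 mL/kg/min with mean gains of 2.9 (EG)
vs 0.8 (ACG), fitness–integrity change coupling of 0.7 (EG) / 0.3 (ACG),
5% per-occasion dropout and 2% sporadic missingness. Where the emulated
study reports no value (coupling in controls, change SDs, missingness
rates), the defaults are one-time choices of plausible magnitudes for an
aging-intervention cohort and are not revisited.

Latents are drawn jointly multivariate-normal per participant — the
integrity trio (η₁, Δ₂₁, Δ₃₂) conditioned on the fitness pair
(fit₁, ΔFit) in the designated coupled ROI — rather than by post-hoc
residual mixing, so the generator's estimand matches the bivariate model's.
Coupling is restricted to one designated ROI because coupling one ΔFit to
many independent ROI changes at a fixed correlation quickly violates
positive semi-definiteness; all covariance blocks are PSD-checked at
construction with the offending block named. Method effects are
participant-level random intercepts per modality; outliers are injected by
adding ±k·SD (default k = 6) to randomly chosen cells so the 4-SD screen
provably catches them; dropout is monotone (all variables from the dropout
occasion onward) with MCAR holes on top. ROI latents are independent
across ROIs, occasions share no autoregressive residual structure, and
indicators are conditionally Gaussian — real multimodal MRI data are none
of these, so passing recovery tests demonstrates correctness of the
estimator under its own assumptions, not robustness to real-data
violations.

## Data hygiene

Fixed order: univariate 4-SD screen on raw values per (variable,
occasion) → multivariate Mahalanobis screen per variable across occasions
(classical product-moment covariance of complete cases, χ² cutoff at
1 − 0.001 with df = occasions; a flagged case loses all its occasions) →
ICV adjustment of VBM only (adjusted = raw − b·(ICV − mean ICV), b the
least-squares slope) → stack-then-rescale standardization (one shared
location/scale across occasions, preserving occasion-mean gaps). Whether
the univariate screen preceded ICV adjustment in the emulated workflow is
not documented; detection on raw values is this package's fixed choice.
All SDs use the n−1 denominator. Compliance: non-compliant iff total
minutes < 21 × 90 = 1890, any zero-activity pause > 2 consecutive weeks
(gaps in week numbering count), or — for exercisers — a negative
least-squares wattage trend over active weeks ("steady or slightly
increasing" operationalized as slope ≥ 0, with a −1e-8 numerical floor).
Non-compliant participants lose occasions 2–3 but keep baseline rows
(`t1-retained`, the default) or are dropped entirely (`fully-excluded`).

## Design sensitivity

For the within-between interaction: noncentrality λ = f²·N·m·ε/(1−ρ),
numerator df (g−1)(m−1)ε, denominator df (N−g)(m−1)ε; power is the
noncentral-F mass beyond the central-F critical value; the minimal f roots
power(f) = target by bisection to 1e-6. For the correlation: the critical
r comes from the exact t-transform of the null distribution; power under
ρ > 0 integrates the exact (Gaussian-hypergeometric) density of the sample
correlation, split at its mode for quadrature stability, with a Fisher-z
closed form (r = tanh((z_{1−α}+z_{power})/√(N−3))) as the approximate
mode. ρ = 0.5, ε = 1 and one-tailed testing are the conventional defaults
of repeated-measures power tools, stated explicitly in `PowerConfig` —
never silent.

## Problem sizes used in the test suite

Simulation-backed checks are sized to keep the whole suite in single-digit
minutes while leaving the statistical bounds meaningful: parameter-recovery
coverage uses 30 replications of the bivariate model at n = 400 (per-
parameter 3-SE coverage must be ≥ 93%, i.e. ≥ 28/30 against a ≈ 99.7%
population coverage); type-I calibration uses 150 null replications of the
df = 1 group-difference test and 100 of the group-metric invariance step,
each checked against exact 99% binomial bounds around the nominal 5%;
screen calibration uses n = 5000. Population-moment checks for the
generator use n = 5000 with 3-Monte-Carlo-SE bounds. The end-to-end
pipeline tests use one ROI with n = 150 per group (planted signal) and
n = 40 per group (determinism).

## Known limitations

* No analytic gradients; large models pay a finite-difference cost.
* The saturated model under heavy missingness is optimized, not solved by
  EM, and is the slowest step of fit-index computation.
* No robust (MCD) multivariate screen — the classical product-moment
  screen is the specified behavior.
* No ordinal/robust estimators, bootstrap SEs, definition variables,
  combined-hemisphere models, or second-order (dual) change score models.
* The boundary p-value for variance gates is a 50:50 mixture heuristic;
  the exact mixture weights for composite boundary hypotheses are not
  computed.
* One-sided logic applies to single parameters only.
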