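# Methods

## Setting and estimands

Two samples are observed under a non-nested design: a randomized trial
(S = 1, n₁ rows) and an observational study (S = 0, n₀ rows), drawn
separately from their super-populations with unknown sampling fractions.
Each row carries an outcome Y, a binary treatment A, covariates X, and a
designated subset X\* ⊆ X consumed by the prediction model g(X\*) under
evaluation.  The package targets two quantities in the population
underlying the observational study (the target population):

* the counterfactual risk ψ(a) = E[L(Y^a, g(X\*)) | S = 0], the expected
  loss of g had everyone received treatment a;
* the tailored conditional mean μ_a(x\*) = E[Y^a | X\* = x\*, S = 0].

Both depend on the potential outcome Y^a and so are not functions of the
observed data without identifying assumptions.

## Identification

The *observational analysis* assumes consistency, treatment
exchangeability within S = 0 (no unmeasured confounding), and treatment
positivity there; it rewrites the inner expectation as a regression in
the (S = 0, A = a) cell.  The *transportability analysis* instead relies
on trial randomization plus exchangeability of the two populations given
X (Y^a ⫫ S | X) and positivity of trial participation; its inner
regression uses the (S = 1, A = a) cell.  If all assumptions hold
simultaneously, the conditional expected losses agree across sources and
may be pooled — the *joint analysis* — buying efficiency at the price of
assuming everything at once.  The treatment- and participation-positivity
conditions are checkable in data (`positivity_diagnostics`); the
exchangeability conditions are not, which is why the benchmarking
comparison below reports rather than decides.

## Estimators

Let L_i = L(Y_i, g(X\*_i)) and let ĥ_{a,s}(X) (or pooled ĥ_a) denote a
regression of L on X in the analysis-specific cell.  For each analysis
three estimator families are provided.

**Outcome model.** ψ̂ = n₀⁻¹ Σ_{S_i=0} ĥ(X_i), with ĥ = ĥ_{a,0}, ĥ_{a,1},
or ĥ_a by analysis.

**Inverse probability weighting.** Row weights are

* observational: I(S=0, A=a) / ê_a(X; S=0);
* transportability: I(S=1, A=a) · ŵ(X) / ê_a(X; S=1), with the
  participation odds ŵ(X) = P̂(S=0|X) / P̂(S=1|X) fitted on the pooled
  sample — under the non-nested design these odds estimate the transport
  weight only up to the unknown sampling-fraction constant, which Hájek
  normalization absorbs;
* joint: I(A=a) · [I(S=0) + I(S=1) ŵ(X)] / ê_a(X, S).

Hájek normalization (weighted sum of losses divided by the weight sum) is
the default: it bounds the estimate by the observed loss range and makes
a constant loss reproduce itself exactly.  Horvitz–Thompson scaling by
1/n₀ is retained as an option because the plain sample-analog estimators
are written that way; the transportability hand example in the test
suite shows the two intentionally disagreeing on small samples.  Note
that for the joint analysis the weight sum approaches 2n₀, so the HT
variant is not recommended there.

**Doubly robust.** The augmented form adds a weighted residual
correction to the outcome-model term, e.g. for the observational
analysis n₀⁻¹ Σ_{S=0}[ĥ_{a,0}(X) + I(A=a)/ê_a(X) · (L − ĥ_{a,0}(X))],
and analogously with the transport weights (trial residuals) and the
joint weights (residuals from both sources by default;
`joint_residual_sources="trial"` restricts the correction to trial
rows).  The estimator is consistent when either the loss regression or
the weight models are correctly specified; the test suite verifies both
the robustness direction (intercept-only ĥ, correct weights) and the
failure mode (both misspecified).  The exact finite-sample algebra of
these augmented forms is a design choice of this package, validated
against simulation truths.

## Nuisance functions

Defaults mirror a parametric main-effects implementation: OLS for loss
regressions (a fast lstsq path, since the bootstrap refits it tens of
thousands of times) and unpenalized logistic regression for treatment
propensities and the participation model.  A `quadratic` OLS learner
(degree-2 polynomial basis) is provided because the squared-error loss of
a linear predictor is exactly quadratic in X — the correct specification
whenever g and the outcome means are linear.  Saturated (cell-mean) and
random-forest learners, and any user object with fit/predict, plug in
anywhere.  All probability outputs are clipped to [0.001, 0.999]
(configurable); estimators warn when more than 10% of weighted rows sit
at a clip bound.  When the trial randomization probability is known it
can be supplied and is then used instead of an estimated trial
propensity (the default in the simulation studies).  Optional K-fold
cross-fitting is available for flexible learners and off by default, as
the parametric defaults do not need it.  A diagnostic refit of the
pooled loss regression with S as a predictor
(`source_homogeneity_diagnostic`) probes the cross-source equality that
justifies pooling; it is advisory, like all diagnostics here.

Tailored models use the same machinery in two steps: regress Y on X in
the analysis cell, then regress those predictions, evaluated on *all*
target rows regardless of their observed treatment, on X\* among target
rows by squared-error regression (one code path for any X\* dimension;
saturated learners recover the nonparametric version on discrete X\*).

## Inference and benchmarking

The nonparametric bootstrap is stratified by S — n₀ and n₁ are fixed by
the non-nested design, so each replicate resamples within source — and
refits every nuisance inside each replicate.  Wald intervals from the
replicate standard deviation are the default (B = 500), percentile
intervals the alternative for skewed losses.  Degenerate resamples are
redrawn up to 10 times, then counted; more than 5% failures warns.

Benchmarking bootstraps the paired difference ψ̂_obs − ψ̂_tr, both arms
seeing the identical resample per replicate so the interval reflects
estimator disagreement only.  Concordance is reported as
"CI contains 0" together with the magnitude of the difference; it
supports but cannot verify the assumptions, since both analyses could be
biased alike.

## The simulator

Per row in source s: X ~ N(μ_X0·I(s=0), 1) with μ_X0 = 0.5 so transport
weighting is non-trivial (0 gives the identical-population sanity case);
U ~ N(0,1) unmeasured, independent of X; A ~ Bern(0.5) in the trial and
A ~ Bern(expit(α₀ + α_X X + β_AU U)) in the observational source
(α₀ = 0, α_X = 0.3); potential outcomes

    Y¹ = γ₀ + γ_X X + μ_YU U + e₁,  e₁ ~ N(0, √(σ_eps² + σ_YU² U² I(s=0)))
    Y⁰ = δ₀ + δ_X X + μ_YU U + e₀,  e₀ ~ N(0, σ_eps)

with γ = (1, 1), δ = (0, 1), σ_eps = 1, and Y = A·Y¹ + (1−A)·Y⁰, so
consistency holds by construction.  Oracle columns (U, Y⁰, Y¹) live in a
separate frame the estimators never receive.  The knobs isolate
violations: β_AU > 0 together with μ_YU > 0 breaks treatment
exchangeability in S = 0 only; σ_YU > 0 inflates the Y¹ noise by U in
S = 0 only, breaking population exchangeability for squared-error
performance while leaving conditional means intact.  σ_YU enters through
the standard deviation √(σ_eps² + σ_YU² U²) and applies to Y¹ only,
giving the clean closed form ψ(1) = μ_YU² + σ_eps² + σ_YU² for squared
error when g is the true conditional mean — the oracle used throughout
calibration, alongside a Monte-Carlo `true_risk` that draws fresh target
rows and evaluates the loss against the potential outcome directly.

**Violation-case strengths.** A design-time calculation fixed the case
grid at σ_YU = 1 (case 2) and β_AU = μ_YU = 2 (cases 3–4).  For a
standard normal U tilted by logistic selection, E[U² | A=1, X] stays
within ≈3% of 1 for any β_AU up to 3 (the mean shift almost exactly
offsets the variance shrinkage), so with g equal to the true mean the
confounding bias of the observational risk estimator is second-order:
about −2.2% relative at β_AU = μ_YU = 2, negative because the selection
slightly *reduces* the conditional second moment.  The chosen strengths
make that bias an order of magnitude larger than the Monte-Carlo
standard error at the study scale (500 replicates of n₀ = n₁ = 2000)
while case 2's transport bias is −σ_YU²/(σ_eps² + σ_YU²) = −0.5.
Relative bias is defined as (mean estimate − truth)/truth.

**Benchmarking power study.** Against an evaluated model equal to the
true conditional mean, the same second-order arithmetic makes the
observational-vs-transport difference undetectable at realistic sample
sizes.  The benchmarking studies therefore evaluate a deliberately
imperfect model (the constant-zero predictor), for which residual
structure in X remains and confounded treatment selection shifts the
observational loss regression at first order (delta ≈ 3 at
β_AU = μ_YU = 2, ≈6 bootstrap standard errors at n₀ = n₁ = 2000) — the
realistic scenario, since models under evaluation are never the truth.
Those studies pair the zero model with the `quadratic` loss-regression
learner, which is then correctly specified; with a merely linear ĥ the
two analyses acquire different projection biases under covariate shift
and the no-violation concordance rate drops well below nominal — a
model-misspecification artifact, not an assumption violation.

**Cohort-style demo.** `run_cass_style_demo` dichotomizes outcomes at
threshold 1.0 (the midpoint of the two arms' intercepts at the target
covariate mean, giving event rates near one half), splits the target
sample 50/50, fits a random-forest event-probability model on the
training half, and estimates its Brier risk on the evaluation half plus
the full trial with the complete 2 × 3 × 3 grid and B = 500 bootstrap
Wald intervals.

## Problem sizes used in the checks

The statistical acceptance tests run 500 replicates at n₀ = n₁ = 2000
for consistency and bias-signature checks, 200 replicates at
n₀ = n₁ = 4000 for double robustness, 500 replicates across a
(n₀, n₁) grid for the efficiency comparison, 200 outer × B = 200 for
bootstrap coverage, and 200 outer × B = 200 per scenario for
benchmarking; `scripts/acceptance.py` uses the same designs at 100–300
replicates.  These sizes put Monte-Carlo standard errors well below the
effect sizes being asserted (e.g. coverage SE ≈ 1.5% against a
[0.92, 0.98] band).

## What the simulator does and does not emulate

It reproduces the structural features the estimators care about — two
sources with shifted covariate distributions, confounding confined to
the observational source, selective violation of each exchangeability
assumption, known randomization probability — with a one-dimensional X
and U and linear outcome means.  It does not emulate high-dimensional or
categorical covariates, non-linear outcome surfaces, missing data,
censoring, non-adherence, or measurement error; passing tests certify
estimator correctness under the stated mechanisms, not robustness to
those complications (missingness is in fact rejected by contract:
complete cases only).  Other known limitations: a single shared
covariate set for all analyses (no per-analysis X), deterministic
treatment strategies only, no uniform confidence bands over X\*, and no
sandwich-variance alternative to the bootstrap.
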