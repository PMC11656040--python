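# Methods

## The structural model

All estimators address the linear interaction model for a continuous
outcome `Y` (grams), binary exposure `S`, binary moderator variant `G`,
instrument `G2`, measured covariates `Z` and an unmeasured confounder `U`:

```
E[Y | S, G, Z, U] = γ0 + β1·S·G + β0·S·(1−G) + γYG·G + γYZ·Z + γYU·U
                  = γ0 + β0·S + (β1−β0)·S* + γYG·G + γYZ·Z + γYU·U,
```

where `S* = G·S`.  `β1` and `β0` are the causal exposure effects in
carriers and non-carriers of the moderator allele; `β1 − β0` is the
genetically moderated exposure effect (GMEE).  The classical instrumental
assumptions for a variant are relevance (IV1), independence from
confounders (IV2), exclusion / no pleiotropy (IV3) and homogeneity (IV4).
The moderator `G` violates IV4 by construction; `G2` is assumed to satisfy
IV1–IV4.

## Estimators

**GMEE family.**  `GMEE(1) = Ê[Y|S=1,G=1] − Ê[Y|S=1,G=0]` and `GMEE(0)`
likewise among the unexposed; `RGMEE = GMEE(1) − GMEE(0)`.  Cell-mean
standard errors use within-cell variances.  GMEE(1) is consistent for
`β1−β0` when `G` is independent of `S` and of `U` and has no direct outcome
effect; GMEE(0) estimates exactly the direct-effect contamination, so the
RGMEE additionally tolerates pleiotropy (IV3 violation).  It remains biased
when `G` is associated with `U` (IV2 violation) or with `S`: both create
differential confounder selection across the `(S, G)` cells.  Those biases
are small in absolute terms under realistic parameter values (order 1 g
here, versus a 100 g moderated effect) but strictly nonzero — the test
suite demonstrates them on replicated million-record cohorts.  Because the
assumptions imply `G ⫫ S`, a `G`–`S` association test is a prerequisite for
the RGMEE; the package reports it as a warning with an F statistic, never
as a hard failure.

**Method 1** (joint instrumentation).  Stage 1 fits
`Ê[S | G, G2, covariates]`; stage 2 regresses `Y` on `Ŝ·G` and `Ŝ·(1−G)`
plus outcome covariates.  Both group effects come from one model, and
`SE(β1−β0)` uses the stage-2 coefficient covariance.  Valid when `G`
satisfies IV2 and IV3; `G` may affect `S`.  The default first stage is a
main-effects logistic regression (the applied-analysis convention); a
linear-probability backend exists because the ratio estimands are
link-free, and the two are cross-checked in tests.  With two binary
instruments the main-effects logistic model is not saturated over the four
genotype cells; the induced approximation error was checked by simulation
(30 replicates of n = 10⁶) and is statistically undetectable at Monte-Carlo
SE ≈ 1 g, so no interaction term is added.

**Method 2** (moderation removal).  Step 1 estimates `β1−β0` by RGMEE;
step 2 fits `Ê[S | G2, covariates]`; step 3 regresses the adjusted outcome
`Y − (β1−β0)·S*` on `Ŝ` to recover `β0`, and `β1 = β0 + (β1−β0)`.  The two
components are treated as independent, giving
`SE(β1) = sqrt(Var(β1−β0) + Var(β0))` exactly; in coverage studies this
independence approximation makes the `β1` interval mildly conservative
(empirically ≈ 0.976 at n = 20,000 versus the nominal 0.95) while `β0` and
the difference are nominal.

**Standard errors and tests.**  All two-stage procedures report stage-2
model-based standard errors with no first-stage variance correction — the
procedures are defined that way, and the coverage results above validate
the choice at the sample sizes of interest.  Confidence intervals are
`value ± 1.96·SE`; p-values are two-sided normal.  A nonparametric
bootstrap is deliberately not the default anywhere.

**Wald decomposition.**  For a known configuration,
`plim Cov(G,Y)/Cov(G,S)` splits into a ratio term
`(β1·E[S|G=1] − β0·E[S|G=0]) / (E[S|G=1] − E[S|G=0])` plus the bias
`B = (γYG + γYU·γUG) / (E[S|G=1] − E[S|G=0])`, using
`E[U|G=1] − E[U|G=0] = γUG` analytically.  Conditional exposure moments are
integrated over the confounder and linear-predictor noise either by
Monte-Carlo with 10⁶ draws under a fixed internal seed (default — the
result is then a deterministic function of the configuration) or by 80-node
Gauss–Hermite quadrature; the backends agree to well under a gram.  Under
monotonicity the ratio term equals
`β1 + (β1−β0)·P(always-taker)/P(complier)` (verified against the latent
principal strata), so it coincides with a complier average causal effect
only when effect heterogeneity among the always-exposed vanishes — e.g.
under homogeneity, or with no always-takers in a population of carriers.
In general it is *not* the factual-genotype complier mixture
`β1·P(G=1|complier) + β0·P(G=0|complier)`; the package exposes both
quantities (`wald_estimand` and `true_cace`) so the gap is explicit rather
than hidden.

## The synthetic-cohort generator

```
G  ~ Bern(0.55),  G2 ~ Bern(0.4)
U  = γUG·G + N(0, 1)
η  = −2 + γSG·G + γSG2·G2 + γSU·U + N(0, 0.5)
S  ~ Bern(expit(η))
Y  = 3500 + β1·S·G + β0·S·(1−G) + γYG·G + γYU·U + N(0, 470)
```

with defaults `β1 = −200`, `β0 = −100` g.  The `N(0, 0.5)` exposure noise
is parameterised by its SD, in parallel with the `N(0, 470)` outcome noise
whose 470 g matches a plausible birth-weight residual SD.  Violation
coefficients default to zero; named scenario constructors switch them on:

* `method1_scenario`: `γSG = 0.5` (moderator affects exposure), no
  pleiotropy, no confounder path — Method 1's assumption set;
* `method2_scenario`: `γSG = 0`, `γYG = 150` g pleiotropy — Method 2's
  assumption set;
* `shared_scenario`: all violations off — both methods valid, used for
  head-to-head power and precision comparisons.

**Calibrated coefficients.**  Three structural coefficients have no single
canonical value and were fixed once, by calibration against the study
design the package emulates: `γSG2 = 1.5` and `γSU = 0.5` give an exposure
prevalence of ≈ 0.24 (plausible for pre-pregnancy smoking) and a strong
but not deterministic instrument, and `γYU = 100` g per confounder SD gives
moderate unmeasured confounding with total outcome SD ≈ 481 g.  Under this
calibration the large-sample power properties line up with the published
sample-size guidance for this class of design: detecting a −15 g moderated
effect at 80% power needs ≈ 200,000 individuals with Method 2 and
≈ 500,000 with Method 1.  These values are a plausible rendering of the emulated study design,
not a claim about any specific cohort.

**Latent ground truth.**  Potential exposures `s_if_g1`/`s_if_g0`
re-evaluate `η` (including `G`'s contribution to `U`) with the moderator
forced, reusing every noise draw — the "same person, different allele"
counterfactual; potential outcomes share the outcome noise and keep `G`
factual.  This yields exact complier classification; monotonicity is
checked per cohort (strongly negative `γSG` genuinely creates defiers) and
never assumed.  Optional independent Gaussian covariates `z1..zk` exist
purely to exercise covariate-adjustment code paths; they are not part of
the structural model.

**What the generator does not emulate.**  Real cohorts have allele-count
genotypes (the moderator here is carrier-coded 0/1; the CSV reader's
`dichotomize_g` flag collapses counts), continuous polygenic scores with
measurement structure, missing data, relatedness and population
stratification, and covariates that actually confound.  Passing tests
therefore demonstrate correctness of the estimators under the stated
structural model, not robustness to those real-data features.

## The study engine

Replicates derive child seeds from `(master_seed, n, replicate)` through a
counter-based splittable scheme, so any grid subset is independently
reproducible and identical scenarios are bit-identical.  Summaries report,
per (method, parameter, sample size): mean estimate, bias, empirical SD,
power of the two-sided 5% Wald test, and 95% CI coverage, each with its
Monte-Carlo standard error (`SD/sqrt(R)` for means, `sqrt(p(1−p)/R)` for
proportions).  Failed fits are excluded and counted; a cell with more than
1% failures is flagged invalid rather than silently summarised.  Default
replicate counts are desk-scale (hundreds to 1,000 rather than 20,000);
all conclusions are stated relative to the accompanying MCSEs.

## Numerical choices and degenerate inputs

* Empty `(S, G)` cells raise estimability errors naming the cell; constant
  or linearly dependent design columns raise collinearity errors naming the
  column (rank is checked on the k×k Gram matrix, stable for tall designs).
* Perfect separation or non-convergence of the logistic first stage raises
  a fit-failure error rather than returning degenerate coefficients.
* A first-stage F below 10 (configurable) triggers a weak-instrument
  warning, not an error; the Method-2 `G`–`S` gate warns at 5% by default.
* The exposure and outcome models take independent covariate lists,
  mirroring applied analyses that adjust the two models differently.
* Cohort CSVs serialise floats at 17 significant digits so write-then-read
  round-trips are exact; binary columns are validated as {0, 1}; missing
  values in required columns are rejected (complete-case framing).

## Known limitations

* Only a linear, Gaussian-error outcome model; no non-linear effects and
  no multi-allelic moderator.
* Single-sample, individual-level data only — no summary-statistic MR and
  no multi-variant pleiotropy-robust estimators.
* Stage-2 model-based SEs understate uncertainty slightly for Method 2's
  `β0` at small n (the estimated RGMEE adjustment adds noise); empirically
  coverage stays within 0.94–0.95 at n ≥ 20,000.
* The RGMEE biases under IV2 violation or `G`–`S` dependence are real but
  of order 1 g at realistic parameter values; detecting them requires
  hundreds of million-record replicates, which the test suite does, and
  applied users should treat the corresponding assumption checks as
  first-class.
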