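# Methods

## Model and likelihood

The package models K mutually exclusive causes of death with independent
cause-specific Weibull hazards. For cause j and covariate row
x = (1, bmi, age, sex_woman, stage_II, stage_III, stage_IV):

- hazard: h_j(t|x) = λ_j(x) p_j t^{p_j−1}, with λ_j(x) = exp(x·β_j);
- cause-specific survival: S_j(t|x) = exp(−λ_j(x) t^{p_j});
- overall survival: S(t|x) = exp(−Σ_j λ_j(x) t^{p_j});
- cumulative incidence: F_j(t|x) = ∫₀ᵗ h_j(u|x) S(u|x) du.

The log link on the scale is the only covariate link consistent with
reporting exp(coefficient) as a hazard ratio, and it guarantees λ > 0;
the shape p_j is cause-specific but covariate-free. Times are in months;
age and BMI enter untransformed, so coefficients are per-year and
per-kg/m²; reference categories are man and stage I.

The log-likelihood with right-censoring is additively separable across
causes: the cause-j term is exactly the single-event Weibull likelihood
with all other causes recoded as censored. Fitting therefore proceeds
cause by cause; the identity itself is kept as a test invariant (it
holds to floating-point exactness) and as an acceptance check.

The "naive" comparator deliberately ignores the competing-risks
structure. Its default event definition is cause-1-only (competing
deaths censored), the standard way such analyses are done in practice;
an any-death pooled definition is also available since published
single-event analyses do not always state which was used.

## Estimation and inference

Each cause is maximised over the working parameter (β_j, log p_j) — the
log transform enforces p_j > 0. The optimiser is BFGS with analytic
gradients, started from the exponential closed-form MLE for the
intercept (events / person-time) and zeros elsewhere, followed by Newton
polishing (analytic gradient, central-difference Hessian, step-halving)
which brings the gradient to near machine precision; up to four jittered
restarts are attempted otherwise. Convergence is declared when the
scale-invariant gradient norm max_i |g_i|·max(1,|θ_i|)/max(1,|ℓ|) falls
below 1e-5 (the raw gradient sup-norm is not invariant to covariate
scale: the age column, ≈50, inflates it by orders of magnitude at a
perfectly converged optimum).

The covariance of (β̂_j, log p̂_j) is the inverse of the
central-difference observed information at the optimum (relative step
1e-5). 95% CIs for hazard ratios exponentiate β̂ ± 1.959964·SE
directly, avoiding the delta method on the HR scale; p-values are
two-sided Wald.

A cause with zero observed events is flagged non-estimable rather than
fitted. A fit whose information matrix is singular or not positive
definite is flagged non-converged and downstream curve evaluation
refuses it. This situation is real, not hypothetical: with ~4% rare-cause
mortality at n = 372, a cohort can contain no rare-cause deaths in the
reference stage, leaving the baseline hazard unidentified (a monotone
likelihood — the same pathology that produces published table rows with
coefficients like −14 and SEs like 99).

## Synthetic cohorts

`generate_cohort` uses the latent-failure-times construction: per
subject, one latent Weibull time per cause via inverse-transform
sampling t = (−ln u / λ)^{1/p}, an independent censoring time, and the
observed record is the minimum with its cause label. This is the
canonical data-generating process consistent with cause-specific
hazards; latent ties (measure zero) break toward the lowest cause index.

Defaults emulate the motivating registry cohort: n = 372; P(man) =
0.567; age ~ N(52.69, 14.39²); BMI ~ N(24.61, 3.98²) redrawn until
positive (age is left unbounded — negative draws are astronomically
unlikely and harmless to the model); stage probabilities are the exact
count fractions 117/110/116/29 over 372 (the published percentages sum
to 100.1 and are not used directly). Non-intercept true coefficients
follow the published fitted pattern (protective BMI, weak sex and age
effects, risk increasing with stage). Censoring is Uniform(0, 132)
months, emulating staggered entry over an ~11-year window with a common
closing date; the two intercepts (−5.396, −7.890 with shapes 1.2 and
1.0) were calibrated once by bisection at n = 60000 so the default
configuration yields 29.8% cancer deaths, 3.8% other-cause deaths and
≈66% censoring, matching the cohort margins.

What the generator does **not** emulate: covariate correlations (stage,
age, BMI and sex are drawn independently), dependent or informative
censoring, time-varying covariates, frailty, measurement error, or
non-Weibull hazards. Passing recovery tests on these cohorts shows the
estimator is correct *under the model*, not that the model fits any
particular real registry.

## Numerical choices

- **CIF quadrature**: `scipy.integrate.quad` after the substitution
  v = u^{p_j}, which removes the integrable hazard singularity at 0 when
  p_j < 1 and makes the cause-j factor of the integrand constant;
  relative tolerance 1e-9, with an error-estimate check that raises on
  non-convergence. Probability conservation S + ΣF_j = 1 holds to
  ~1e-12 in practice.
- **Kaplan–Meier**: standard product-limit with deaths processed before
  censorings at tied times; subjects censored at an event time count as
  at risk. Verified against lifelines to 1e-10.
- **Cloglog diagnostic**: points (log t, log(−log S)) at event times
  with 0 < S < 1 (endpoints excluded — the transform is undefined
  there); ordinary least squares gives (slope, intercept, R²), slope
  estimating the shape p and intercept log λ. The stored ordinate is
  log(−log S); renderers may negate for display.
- **Likelihood overflow guards**: the log cumulative hazard is clamped
  at 500 and log p at 30 inside the objective so that wild line-search
  iterates stay finite; both caps are far outside any region a real
  optimum occupies.

## Validation studies (shared by the test suite and acceptance script)

- *Worked examples*: published (coefficient, SE) pairs from the
  motivating study's regression tables are run through the Wald
  machinery; computed HR and CI endpoints agree with the published
  values to table rounding (±0.01). Rows whose printed CI is internally
  inconsistent with the printed SE are excluded as typographical.
- *Separability*: joint vs summed per-cause log-likelihoods on 100
  random cohorts; exact identity.
- *Recovery*: 200 cohorts of n = 1000 at a fixed truth (stage-IV log-HR
  1.5, shapes 1.2 and 0.9, intercepts −5.246/−4.323 giving ≈35%/30%/35%
  cause-1/cause-2/censored). Effect sizes are chosen so that 5% of each
  true value exceeds ≈4 Monte-Carlo standard errors of the
  200-replicate mean — i.e. the bias check is resolvable at the study's
  resolution. Mean bias per parameter stays below 5% of truth; pooled
  empirical coverage of the 95% Wald intervals (16 parameters) lands
  near 94–95%. Per-parameter coverages are also reported; at 200
  replicates a single parameter's empirical coverage has MC standard
  error ≈1.5%, so individual values a couple of points either side of
  95% carry no signal.
- *Exponential oracles*: with shapes fixed at 1, the intercept-only MLE
  equals events/person-time (closed form), and CIF quadrature matches
  the analytic two-cause exponential formula, both to ≤1e-8.
- *Diagnostic*: cloglog slope on KM of an n = 5000 Weibull cohort
  recovers the true shape within 0.1; the transform of the exact model
  curve is a perfect line (R² = 1 to 1e-10).

Problem sizes (200×1000 fits, n = 5000 diagnostics, 100-dataset
identity checks) were chosen as the smallest that make each check
statistically decisive; the full validation run completes in well under
a minute on one CPU.

## Known limitations

- No Fine–Gray subdistribution regression, left truncation, shape
  covariates, or Bayesian estimation.
- Wald inference is first-order; with very few events per cause
  (rare-cause fits at registry scale) profile-likelihood intervals
  would behave better than ±z·SE, and the package's answer there is to
  flag rather than to fix.
- The five-year stage-specific survival table depends on the covariate
  profile chosen (cohort-mean age/BMI, reference sex by default);
  population-averaged curves are not implemented.
- Model-based curves come without confidence bands, and nonparametric
  (Aalen–Johansen) cumulative incidence is out of scope.
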