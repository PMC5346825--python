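# weibullcr

Parametric competing-risks survival analysis with cause-specific Weibull
hazards, written for prognostic-factor studies in which patients can die
from the disease under study *or* from unrelated causes — the motivating
setting is a colorectal-cancer registry cohort with two competing causes
of death (cancer vs. everything else) and heavy right-censoring.

Ignoring competing deaths (treating them as plain censoring in a
single-event model) is a classic source of over-estimated covariate
effects; this package fits both analyses side by side so the difference
is visible.

## Model

Each cause of death *j* = 1..K has a Weibull cause-specific hazard with a
log-linear covariate link on the scale parameter:

```
h_j(t | x) = λ_j(x) · p_j · t^(p_j − 1),      λ_j(x) = exp(x·β_j)
S_j(t | x) = exp(−λ_j(x) · t^(p_j))
```

so each cause is a proportional-hazards model and `exp(β)` is a
time-constant hazard ratio (HR). The full likelihood over subjects with
observed time `t_i` and event code `d_i` (0 = censored, j = death from
cause j)

```
ℓ = Σ_i [ Σ_j 1{d_i=j}·log h_j(t_i, x_i) − Σ_j λ_j(x_i)·t_i^{p_j} ]
```

separates into independent per-cause terms, each equivalent to a
single-event Weibull fit with all other causes recoded as censored. The
package provides:

- **`data_model`** — subject records (time in months, event code, sex,
  age, BMI, AJCC stage I–IV), CSV I/O, design encoding (reference: man,
  stage I), descriptive cohort summaries;
- **`synthetic`** — a latent-failure-times cohort generator whose
  defaults emulate the registry cohort (n = 372, 56.7% men, stage mix
  117/110/116/29, ≈30% cancer deaths, ≈4% other-cause deaths, ≈66%
  censored);
- **`fitting`** — per-cause maximum likelihood over (β_j, log p_j) with
  analytic gradients, Newton polishing, observed-information covariance,
  plus the naive single-event comparator and Wald HR/CI/p inference;
- **`diagnostics`** — Kaplan–Meier estimation and the
  log(−log S) vs log t linearity diagnostic for the Weibull form;
- **`incidence`** — cause-specific survival, overall survival, and
  cumulative incidence functions F_j(t) = ∫₀ᵗ h_j(u)S(u)du by adaptive
  quadrature, with horizon summaries (default: 60-month survival by
  stage);
- **`cli`** — a `weibullcr` command with `simulate`, `fit`, `diagnose`,
  `curves` and `report` subcommands.

## Worked example

Simulate a 1500-subject cohort from the default configuration and fit
both competing-risks models:

```sh
weibullcr simulate --n 1500 --seed 42 --out-dir demo
weibullcr fit demo/cohort.csv --out-dir demo
weibullcr diagnose demo/cohort.csv --out-dir demo
weibullcr curves demo/cohort.csv --out-dir demo
```

`demo/table_competing.tsv` then contains (excerpt, cancer-death block):

```
Event                         Covariate   Coefficient (SE)  HR     95% CI         P value
Death from colorectal cancer  BMI (kg/m2) -0.030(0.012)     0.971  (0.948-0.994)  0.014
                              Stage II    -0.513(0.150)     0.599  (0.446-0.803)  <0.001
                              Stage III   0.411(0.118)      1.509  (1.197-1.902)  <0.001
                              Stage IV    1.424(0.156)      4.152  (3.055-5.642)  <0.001
```

Each row is a per-unit hazard ratio for cancer-specific death: here a
stage IV diagnosis multiplies the cancer-death hazard by 4.15 (95% CI
3.06–5.64) relative to stage I, and each extra BMI unit lowers it by
about 3%. The diagnostic reports the cloglog line

```
{"slope": 1.053, "intercept": -5.369, "r2": 0.996, ...}
```

— slope ≈ shape p, r² near 1 supports the Weibull form. The 60-month
horizon table (`demo/horizon.tsv`) gives, per stage at cohort-mean age
and BMI:

```
  profile  overall_survival  survival_cause_1  cif_cause_1
  stage I             0.728             0.744        0.254
 stage II             0.781             0.837        0.157
stage III             0.625             0.640        0.357
 stage IV             0.241             0.292        0.653
```

`survival_cause_1` is the net (cause-specific) survival
exp(−λ₁t^{p₁}); `cif_cause_1` is the crude probability of having died
of the cancer by 60 months given the competing cause; they answer
different questions and both are reported.

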