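# Methods

## The design

The package implements a sharp regression-discontinuity (RDD) analysis of
an abrupt, exogenous shock on a bounded depression scale, together with the
gene–environment extension in which polygenic scores moderate the shock
effect. The running variable is the interview day `r`, centred at the
cutoff; treatment is deterministic, `T = 1{r ≥ 0}` (subjects interviewed on
the cutoff day itself are treated, because the shock occurred that
morning). The treatment model is the local linear specification

    Y = α + β₁T + β₂r + β₃(T·r) + β₄'χ + ε,

fitted by weighted least squares with triangular kernel weights
`w = max(0, 1 − |r|/h)` inside bandwidth `h`; β₁ is the local average
treatment effect at the cutoff. The moderated model adds a polygenic score
`G` with its full interaction set:

    Y = α + β₁T + β₂r + β₃G + β₄(T·r) + β₅(T·G) + β₆(r·G) + β₇(T·r·G)
        + β₈'PC + β₉'χ + ε,

where `G` is either a median-split indicator (ties at the median are
"low", per the ≤50th-percentile rule) or the standardized continuous
score; the ten genotype principal components and the *other* standardized
polygenic score enter as covariates. β₅ is the gene–environment contrast:
with a binary `G`, the difference in the shock effect between high- and
low-score groups; with a continuous `G`, the change per SD of the score.

A note on slope contrasts: the post-cutoff slope of the outcome in days is
β₂ + β₃ (the `r` plus `T:r` coefficients). Some write-ups of this design
label the post-shock slope "β₁ + β₃", which conflicts with the term
definitions above; `post_cutoff_slope` implements β₂ + β₃ and the
discrepancy is flagged here rather than silently resolved.

## Inference

Robust (sandwich) covariance on the kernel-weighted normal equations:

    cov(β̂) = (X'WX)⁻¹ (Σᵢ wᵢ² eᵢ² xᵢxᵢ') (X'WX)⁻¹ · n/(n − p)   [HC1]

with HC0 available by omitting the small-sample factor. With uniform
weights and HC0 this reduces exactly to OLS with White covariance (checked
against statsmodels to machine precision in the tests). Critical values
are normal (z) for single fits, consistent with large-sample RDD practice;
pooling over multiple imputations switches to a t reference with
Barnard–Rubin degrees of freedom. The full-sample model (bandwidth ∞) uses
uniform weights, since an infinite kernel scale is undefined.

Degenerate designs raise informative errors: no rows on one side of the
cutoff, a moderator constant within the bandwidth, fewer usable rows than
parameters. Indicator covariate levels that are absent or constant inside
the estimation window are dropped from the design rather than allowed to
make it singular; core terms are never dropped.

## The synthetic cohort generator

There is no public accession for the underlying cohort, so every analysis
stage is exercised on a generator whose ground truth is known. One row per
subject carries: integer interview day on `[-50, 200]` (drawn uniformly
within each side of the cutoff, with a configurable pre/post split
defaulting to the observed 1,098/3,628 imbalance); nine screener items in
0–3; baseline covariates at realistic scales (baseline depression score,
age, sex, maternal education in four ordered levels, family income,
vocabulary test score, three personality scales, state of residence with
two deliberately rare states to exercise the balance-test floor); ten
genetic PCs; and two polygenic scores drawn independently of treatment
(no gene–environment correlation, which the balance tests verify).

**Ground truth equals the estimand.** The scored outcome is an integer in
[0, 27]. A naive construction — Gaussian latent with mean equal to the
linear predictor, then round-and-clamp — attenuates every coefficient,
because clamping at the floor of the scale shifts conditional means upward
by an amount that depends on the predictor (with mean ≈4.2 and SD 3.87 the
implied attenuation of the discontinuity is ≈14%). A generator whose
nominal τ is not the true jump in observed means would make every recovery
test meaningless. The generator therefore inverts the exact
discretization-mean function

    g(m) = Σ_{k=1..27} Φ((m − (k − ½))/σ)  =  E[round(clamp(N(m, σ), 0, 27))]

(a strictly increasing function, inverted on a fine grid) and places the
latent location at `g⁻¹(target)`, so the conditional mean of the *scored*
outcome equals the specified regression function essentially exactly while
scores remain properly bounded, integer, and right-skewed with mass at
zero. Conditional-mean targets are floored just inside (0, 27) — a
negative mean is meaningless on this scale; the floor binds for well under
1% of subjects at the default effect sizes.

Items are recovered from the score by even allocation (contribution
`s ÷ 9` each, remainder spread over the first items, the two
positive-affect items stored reverse-coded), so the standard scoring rule
reproduces the total exactly. Consequence: inter-item correlation is far
higher than in real screener data (Cronbach's alpha ≈0.95 on synthetic
items versus ≈0.81 in the emulated study). The items exist to exercise the
scoring and reliability code; only the sum is consumed downstream, so no
conclusion in this package depends on item-level realism.

Randomness is one global seed feeding a CRC-keyed stream per column, so
individual columns regenerate reproducibly.

### Default parameters (the emulated study conditions)

| parameter | default | meaning / why |
|---|---|---|
| `n_subjects` | 4,726 | analytical sample after exclusions |
| `date_range` | (−50, 200) | days relative to cutoff |
| `pre_fraction` | 1,098/4,726 | observed pre-cutoff share |
| `alpha` | 4.19 points | pre-cutoff outcome mean |
| `tau` | 0.89 points | discontinuity at the cutoff (h=50 model) |
| `slope_pre`, `slope_post` | 0, −0.006 points/day | flat seasonal trend, post-shock recovery |
| `beta_meanG` | 0.20 | level effect per SD of the mean PGS |
| `delta_varG` | 1.40 | T × variance-PGS (plasticity) interaction per SD |
| `noise_sd` | 3.87 points | residual SD (pre-cutoff outcome SD) |
| `missing_rates` | 0.2%–31.5% | per-covariate, from the published imputed-value counts |

Covariate effects are unspecified by the emulated design; they were chosen
once at plausible magnitudes (baseline depression +0.20/point,
neuroticism +0.15/point, male −0.50, small negative effects of cognition,
income, education, extraversion, conscientiousness; age and state null)
and are applied to mean-centred covariates so `alpha` remains the
pre-cutoff outcome mean. Missingness is MCAR by default; the MAR mode
makes the missingness log-odds depend on sex and baseline depression with
the intercept calibrated (by root finding) so the marginal rate still
equals the requested rate.

## Multiple imputation

Chained equations, visiting variables in ascending order of missingness.
Continuous covariates use type-1 predictive mean matching: an approximate
Bayesian draw of the linear-model parameters (σ² from a scaled inverse-χ²,
β from its normal approximation), observed predictions under β̂, missing
predictions under β*, and a uniform draw among the k = 5 nearest donors'
observed values. Ordered categories use a proportional-odds cumulative
logit fitted by maximum likelihood, sampling a category from the fitted
probabilities; if the likelihood fit fails (separation, non-convergence)
the variable falls back to PMM on its numeric codes with a warning. Every
conditional model includes all other imputed variables plus the declared
predictors — the analysis outcome and design variables (Y, T, r, the
standardized scores), since congenial imputation must see what the
analysis model sees. Outcome and design variables are never imputed.
Defaults: m = 20 completed datasets, 5 burn-in cycles (10 in the module
default; the drivers use 5, which the chain's mixing at these missingness
rates comfortably supports).

Rubin's rules pool per-coefficient: estimate = mean, total variance =
within + (1 + 1/m)·between, Barnard–Rubin degrees of freedom using the
complete-data residual df, two-sided t p-values. m = 1 or zero
between-imputation variance degrades to the normal reference.

## Falsification suite

*Placebo scan*: for each counterfactual cutoff day d in −20..+20 the
pseudo-treatment `1{r ≥ d}` is re-fitted at cutoff d with a 20-day
bandwidth and no covariates; the true cutoff is included for
comparability, and non-estimable days are flagged rather than fatal.
Because every placebo window inside ±20 days contains the true cutoff,
placebo expectations near day 0 are contaminated by the real jump: under
the default conditions the expected placebo estimate decays from τ at
day 0 to ≈0.7τ one day away and ≈0.2τ three days away. Day 0 is therefore
the maximum of the *expected* scan, but with per-day standard errors of
roughly half τ the *realized* maximum lands on a contaminated neighbour in
most replicates — the acceptance script reports the observed day-0-maximum
fraction (≈25–30% at these effect sizes) rather than asserting it away.
Under a null τ = 0 the scan's significant fraction is checked against a
binomial envelope; placebo estimates at overlapping cutoffs are positively
correlated within a replicate, so that envelope is somewhat
anti-conservative, a known approximation kept for simplicity.

*Balance tests*: each predetermined covariate (categoricals expanded to
indicators; state indicators restricted to states with ≥40 residents in
the 50-day window) becomes the outcome of a covariate-free discontinuity
fit. Raw p-values are reported next to the expected false-positive count
α·(number of tests); no multiplicity correction is applied, matching the
informal calibration this diagnostic is meant for.

*Power*: the two-sided normal expression
`1 − Φ(z_{1−α/2} − τ/se) + Φ(−z_{1−α/2} − τ/se)` with the plug-in robust
SE of β₁ from the realized design. This equals α exactly at τ = 0 and is
strictly increasing in |τ|. It is a plug-in approximation, not the
local-polynomial variance formula of dedicated RDD power calculators.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks use: 500 replicates of n = 2,318 subjects inside the
±50-day window (with the observed pre/post split) for recovery bias and
interval coverage; 200 replicates × 41 placebo days for scan calibration;
200 replicates of n = 800 with 10–32% MCAR, m = 5 and 5 cycles for pooled
interval coverage. These sizes give Monte-Carlo standard errors small
relative to the tolerances being checked while keeping the whole suite in
a few minutes; the MI settings are the package's own choice (coverage is
insensitive to m beyond small values once the Barnard–Rubin reference is
used).

## Known limitations

- The generator does not simulate genotype LD structure, GWAS summary
  statistics, or the construction of variance-PGS weights; polygenic
  scores are treated as supplied inputs (the scoring module builds them
  from dosage matrices and weight files when those exist).
- Item-level synthetic data are over-correlated (see above); longitudinal
  multi-wave trajectories are out of scope.
- Passing recovery tests show the estimator is correct *under the
  generator's assumptions* (correctly specified linear conditional means,
  independent noise, MCAR/MAR missingness); they cannot certify behaviour
  under sorting at the cutoff, non-ignorable missingness, or outcome
  dynamics the generator does not emulate.
- Sandwich-z inference is mildly anti-conservative at small effective
  sample sizes (measured ≈6% size at n ≈ 700 with a 50-day triangular
  window); calibration checks are run at the study's own sample size.
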