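# rdd-gxe

Sharp regression-discontinuity analysis of an exogenous shock on a
depression scale, with polygenic-score moderation — the statistical
machinery for asking whether the *immediate* mental-health response to a
sudden population-level trauma differs by genotype, in a quasi-experimental
design where interview timing assigns exposure.

The package is written for social-science genomics / biostatistics
researchers. The motivating design: a survey wave happens to straddle an
abrupt shock (interviews run from ~50 days before to ~200 days after), so
subjects interviewed on or after the shock day form the treated group and
the interview day is the running variable. The outcome is a 9-item CES-D
depression screener (0–27, two reverse-coded items). Two polygenic scores
moderate the effect: a conventional **mean** PGS predicting the level of
depressive symptoms, and a **variance** PGS interpreted as genetic
plasticity — under the diathesis-stress hypothesis, high-plasticity
subjects should react more strongly to the shock.

## The model

The treatment model is local linear on each side of the cutoff,

$$Y_i = \alpha + \beta_1 T_i + \beta_2 r_i + \beta_3 (T_i r_i) + \beta_4'\chi_i + \varepsilon_i,$$

with $T_i = \mathbf{1}\{r_i \ge 0\}$, triangular kernel weights inside
bandwidths of 10–50 days (plus a full-sample fit), and
heteroskedasticity-robust (HC1) standard errors; $\beta_1$ is the local
average treatment effect at the cutoff. The gene–environment model adds a
polygenic score $G_i$ (median-split or standardized continuous) with its
full interaction set,

$$Y_i = \alpha + \beta_1 T_i + \beta_2 r_i + \beta_3 G_i + \beta_4 (T_i r_i)
+ \beta_5 (T_i G_i) + \beta_6 (r_i G_i) + \beta_7 (T_i r_i G_i)
+ \beta_8' PC_i + \beta_9'\chi_i + \varepsilon_i,$$

where $\beta_5$ is the gene–environment contrast. Missing covariates are
multiply imputed by chained equations (predictive mean matching /
ordered logit), and coefficients are pooled with Rubin's rules. A
falsification suite — placebo cutoffs, covariate balance discontinuities,
analytic power — probes the design assumptions. Because the underlying
cohort is restricted-access, a synthetic cohort generator with known
ground truth (including an exact mean-preserving discretization onto the
bounded 0–27 scale) stands in for the data and makes every stage testable.
See `docs/methods.md` for the full account.

## Layout

- `src/rdd_gxe/` — the library: `synthetic` (cohort generator),
  `phenotype` (screener scoring, reliability, sample exclusions), `pgs`
  (score construction, standardization, median split, PCs, validity
  regression), `impute` (MICE + Rubin pooling), `rdd` (the estimator),
  `validity` (placebo/balance/power), `sensitivity` (transforms,
  quadratic fits, binned scatter), `pipeline` (YAML-driven end-to-end
  run), `cli` (`rdd-gxe` command).
- `analysis/01_…07_….py` — the numbered study drivers: simulate, score &
  filter, impute, bandwidth sweep, G×E models, validity checks,
  sensitivity. Each writes its tables under `results/`.

## Worked example

```python
import rdd_gxe as rg

# a cohort at the emulated study conditions, with known ground truth
cfg = rg.SyntheticConfig(seed=2)          # tau=0.89, delta_varG=1.40, ...
cohort = rg.generate_cohort(cfg)

fit = rg.fit_sharp_rdd(cohort, rg.RDDSpec(bandwidth=50))
print(f"LATE at h=50: {fit.late:.3f} (se {float(fit.se['T']):.3f})")

gxe = rg.fit_gxe_rdd(cohort, rg.RDDSpec(
    bandwidth=50, moderator="varPGS_z", moderator_coding="continuous",
    other_pgs="meanPGS_z"))
print(f"T x varPGS: {gxe.params['T:G']:.3f} (se {float(gxe.se['T:G']):.3f})")
```

prints

```
LATE at h=50: 0.836 (se 0.384)
T x varPGS: 1.758 (se 0.350)
```

— one realization's estimate of the 0.89-point jump in the depression
score at the cutoff, and of the 1.40-point-per-SD plasticity interaction;
each sits about one standard error from its generating value (a single
cohort carries SEs of ~0.4 at this bandwidth, so individual draws scatter
accordingly; the replicated recovery numbers come from the script below).

Running the numbered drivers in order reproduces the full study shape —
exclusion log (15,170 → 4,726 via the three sequential filters),
Table-1-style descriptives, bandwidth-sweep coefficient tables for the
treatment and both moderation models pooled over 20 imputations, the
placebo scan, balance report, power, sensitivity specifications and the
binned discontinuity plot data.

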