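# ivbalance

Diagnostics for deciding **which of two designs is less biased by
confounding** in an observational treatment study: a conventional (OLS)
regression of outcome on treatment, or an instrumental-variable (IV)
analysis using a proxy for prescriber preference (e.g. the prescription the
physician issued to their previous patient).

The toolkit is aimed at pharmacoepidemiologists and applied biostatisticians
who have a patient-level cohort with a binary treatment `X`, a binary
instrument `Z`, outcomes `Y`, baseline covariates `C_j`, and a physician or
practice identifier for clustering.

## The statistics at the core

If a covariate `C` with unit effect on the outcome is omitted, the
confounding bias of each design is a **bias component**:

```
bias_OLS(C) = E[C | X=1] − E[C | X=0]
bias_IV(C)  = ( E[C | Z=1] − E[C | Z=0] ) / ( E[X | Z=1] − E[X | Z=0] )
```

The IV component divides the covariate imbalance across instrument arms by
the first-stage risk difference — an instrument that only weakly moves
treatment amplifies whatever imbalance it carries. Because IV estimates are
much less precise, raw bias-component plots are uninterpretable: `ivbalance`
attaches cluster-robust confidence intervals to both components and tests
their difference with a **modified Hausman test**,

```
( β̂_iv − β̂_ols ) / sqrt( var(β̂_iv − β̂_ols) )  ~  N(0, 1),
```

estimated by one-step GMM on stacked estimating equations so that the
variance of the difference includes the covariance of the two components on
the same sample. The effect itself is estimated by the Wald ratio
`ψ̂ = (ȳ₁ − ȳ₀)/(x̄₁ − x̄₀)` (equivalently 2SLS for a single binary
instrument). Two further diagnostics are included: **negative-control
outcome** tests (conventional vs IV estimates for an outcome the treatment
cannot plausibly affect) and **negative-control population** tests
(instrument–outcome associations among patients of the same physicians who
were never exposed).

Simulation generators reproduce the settings in which these diagnostics were
studied: a fully specified validity design (valid instrument, confounded
OLS), a collider/selection design in which restricting to treated patients
breaks the instrument, and a clustered physician-preference cohort with
negative controls.

## Worked example

```python
from ivbalance import (SimulationConfig, simulate_validity_dgp,
                       balance_table, wald_estimate, write_report)
from ivbalance.plots import bias_plot

cohort = simulate_validity_dgp(SimulationConfig(n=10_000, seed=1))
print(wald_estimate(cohort, "y"))
report = balance_table(cohort)
fs = report.first_stage
print(f"first stage RD {fs.risk_difference.estimate:.3f}, partial F {fs.partial_F:.1f}")
for pair in report.pairs[:3]:
    print(f"{pair.covariate}: OLS {pair.ols.estimate:+.4f}  "
          f"IV {pair.iv.estimate:+.4f}  p={pair.test.p_value:.3f}")
write_report(report, "balance_table.csv")
bias_plot(report, "bias_plot.svg", show_ci=True)
```

prints (exactly, for this seed):

```
EstimateWithCI(estimate=1.1648943114259485, se=0.27544799631027544, ci_low=0.6250261590440869, ci_high=1.70476246380781, level=0.95, n_used=10000, n_clusters=10000, degenerate=False)
first stage RD 0.120, partial F 116.3
c1: OLS -0.0078  IV +0.0929  p=0.228
c2: OLS +0.0018  IV -0.0428  p=0.589
c3: OLS -0.0083  IV +0.0480  p=0.498
```

Reading it: in this single draw the Wald estimate (1.16, CI 0.63–1.70) is
noisy around the generating effect 0.5 — a single replicate of a
just-identified IV analysis is imprecise even at N=10,000 (averaged over 200
replicates it recovers 0.50, see below). The pseudo-confounders c1–c10 are
independent of everything, and the diagnostics say so: the IV bias
components look larger than the OLS ones in absolute value, but every
difference test is consistent with chance (all p ≥ 0.2), which is exactly
why bias-component plots need confidence intervals.

The same analyses are available from the shell:

```sh
ivbalance simulate --scenario validity --n 10000 --seed 1 --outdir run
ivbalance balance run/validity_cohort.csv --exposure-col x --instrument-col z \
    --cluster-col cluster --covariate-cols c1 --covariate-cols c2 --outdir run
```

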