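# Methods

This note documents the models, estimators, numerical choices and
limitations behind `ivbalance`.

## Setting and notation

A patient-level cohort holds a binary treatment `X`, a binary instrument
`Z` (a proxy for prescriber preference, such as the previous patient's
prescription), outcomes `Y`, covariates `C_j` (binary or continuous), and a
cluster identifier (physician). A valid instrument is associated with `X`,
independent of confounders, and has no direct effect on `Y`. Everything is
estimated on the linear (risk-difference) scale; there are no link
functions, no multi-instrument systems, and no survival models.

## Estimators

**Wald/2SLS.** For a single binary instrument the IV estimand is the Wald
ratio ψ = (E[Y|Z=1] − E[Y|Z=0]) / (E[X|Z=1] − E[X|Z=0]). We estimate it —
and every other quantity in the package — as a just-identified linear
moment system `E[z_i (y_i − x_i'θ)] = 0`, so the point estimate is exactly
the ratio of sub-sample mean differences while the standard error comes
from one shared sandwich formula.

**Bias components.** Omitting a covariate `C` with unit outcome effect
(the components are reported on the covariate's own scale, i.e. the
normalisation β_C = 1) biases OLS by `E[C|X=1] − E[C|X=0]` and the Wald
estimator by the Wald ratio with `C` as the outcome. Components are
univariate by design — one covariate at a time, no mutual adjustment —
matching how covariate-balance tables are read. In serialized reports,
binary covariates are shown ×100 (percentage-point risk differences);
continuous ones as raw mean differences.

**First stage.** The instrument-exposure risk difference with cluster-robust
CI; the partial F-statistic is the squared cluster-robust t-ratio of the
instrument coefficient (single-instrument case).

## Cluster-robust variance

All variances use the one-way clustered sandwich
`V = A⁻¹ B A⁻ᵀ / n` with `A = Z'X/n` and `B` the outer product of
per-cluster score sums scaled by `G/(G−1)` (G = number of clusters). No
additional `(n−1)/(n−k)` degrees-of-freedom factor is applied; the choice
is recorded in report metadata, and the test suite pins the exact algebraic
relation to statsmodels' convention. Confidence intervals use normal (not
t) quantiles, consistent with the N(0,1) reference of the difference test.
With every row its own cluster the estimator reduces to an HC-type robust
variance; a single cluster falls back to the unclustered outer product.

## The modified Hausman test

For each covariate the OLS and IV bias components are estimated **jointly**
from stacked moment conditions on the same sample — orthogonality of the
OLS residual `c_i − a₁ − b_ols x_i` with `(1, x_i)` and of the IV residual
`c_i − a₂ − b_iv x_i` with `(1, z_i)`. Four moments, four parameters: the
system is exactly identified, so one-step GMM with identity weighting is
exact and the joint point estimates equal the single-equation ones (asserted
to 1e-10 in tests). The payoff is the joint clustered covariance of
`(b_ols, b_iv)`, which yields `var(b_iv − b_ols)` including their
covariance. The statistic `(b_iv − b_ols)/se` is referred to N(0,1),
two-sided; the null is "no difference between the two bias components".
Intercepts are included in both blocks so each slope equals the
corresponding mean difference for binary `X`. P-values are raw — no
multiplicity adjustment, since the table is read as a profile, not a
screening procedure.

Known small-sample behaviour: the z-test is asymptotically calibrated but
conservative when the first stage is noisy, because the estimated standard
error co-moves with the estimation error of the IV component (the
familiar weak-instrument dampening of Wald-type t-ratios). In the validity
design below, the type-I error rate at α=0.05 is ≈0.045 at N=10,000 but
only ≈0.025 at N=2,000. Callers testing at small N should expect
conservative inference rather than inflated false positives.

## Negative controls

*Outcome test*: conventional (OLS slope of the negative-control outcome on
treatment) and IV (Wald) estimates side by side on the same complete-case
sample. The package reports estimates only; which analysis "passes" is an
interpretive judgement. *Population test*: per-outcome least-squares slope
on the instrument with physician-clustered CI in a cohort of unexposed
patients of the same physicians; membership of that cohort is supplied by
the caller (or by the preference-cohort generator), never inferred from
dates inside the package. Good negative controls should share the
confounding structure of the outcome of interest and have enough variation
for power; that guidance is documentation, not code.

## Simulation designs

**Validity DGP** (defaults of `SimulationConfig`): latent `v, w, u ~ N(0,1)`
with `u` the confounder; `z ~ Bernoulli(0.2)`; ten pseudo-confounders
`c_j ~ Bernoulli(0.2)` independent of everything;
`x = 1(z·γ + u + w > d)` with γ = 0.5; `y = x·β + u + v` with β = 0.5;
N = 10,000. The threshold d is solved analytically: since `u + w` has
variance 2, `Pr[x=1] = p_z Φ((γ−d)/√2) + (1−p_z) Φ(−d/√2)`, and `d` is
found by bracketed Brent root-finding to |f(d)| < 1e-10 (verified against a
10⁶-draw empirical oracle). OLS of `y` on `x` is biased upward by ≈1.2
through `u`; the Wald estimate is consistent for β. Sampling order is fixed
(z, pseudo-confounders, u, w, v, then x, y) so a seed pins the table;
seeds are not portable across numpy versions.

**Collider/selection DGP.** The published account of this design specifies
two features — a measured proxy confounder with squared correlation
r² = 0.01 with the truth, and a treated-only restriction that makes the IV
bias component detectable and an order of magnitude larger than the OLS
one — but not the full generating process. `simulate_collider_dgp` is
therefore an explicitly documented stand-in preserving those two features
on top of the validity structure: `proxy = √r²·u + √(1−r²)·ε`, and a
treatment-receipt indicator `s = 1(α_z z + α_u u + e > d_s)` with defaults
α_z = α_u = 2 and receipt prevalence 0.5 (all exposed in config, not hidden
in code). Restricting to `s = 1` conditions on a collider: it induces a
negative z–u association (inflating the proxy imbalance across instrument
arms) and simultaneously shrinks the first stage, so the IV component of
the proxy inflates by well over 10× while the OLS component barely moves;
without the restriction the two components are the same order of magnitude.
The α values were chosen so both selection channels are strong enough for
the induced dependence to dominate at n = 10,000; they are design
constants of the stand-in, not estimates of the original process.

**Physician-preference cohort.** ~300 physicians with latent preference
`a_g ~ N(0,1)` see ~30 patients each (Poisson, min 2). Patient confounder
`q_i ~ N(0,1)`; prescription `x_i = 1(a_g + q_i + e_i > 0)` (≈50/50 between
two active drugs); the instrument is the physician's previous patient's
prescription, so the first patient per physician is dropped. Outcomes:
`y = 0.5·x + q + noise` (true effect) and a binary negative-control outcome
driven by `q` alone (prevalence 0.2). Twenty-six binary covariates load on
`q` with weight 0.5, mimicking a baseline-characteristics table. The
negative-control population draws fresh patients of the same physicians
(no exposure; instrument = the physician's last index prescription) with
24 confounder-driven binary outcomes, all null for the instrument by
construction. These sizes are chosen as a realistic primary-care-database
miniature with a strong first stage (partial F ≫ 10).

What the generators do **not** emulate: real EHR coding systems, dates and
lookback windows, covariate-specific prevalences of any particular drug
cohort, heterogeneous treatment effects, or instrument-confounder
pathways other than the collider mechanism. Passing tests on these designs
show the estimators and tests behave as advertised under their assumptions;
they do not certify any particular real-world instrument as valid.

## Validation studies (computed by the test suite and acceptance script)

* Parameter recovery: mean Wald estimate over 200 validity replicates of
  N=10,000 recovers β = 0.5 within twice the Monte Carlo standard error of
  the mean (≈ ±0.04).
* Threshold calibration: empirical exposure prevalence over 10⁶ draws
  within ±0.002 of the 0.2 target.
* Proxy construction: squared proxy-confounder correlation at n=10⁶ within
  ±0.002 of 0.01.
* Oracle equivalence: group-mean, Wald-ratio and stacked-moment estimates
  agree to 1e-10 on 100 random tables.
* Null calibration of the difference test at α=0.05 (see the small-sample
  caveat above: ≈0.045 at N=10,000, ≈0.025 at N=2,000).
* Under the validity design, all 10 IV component CIs are wider than their
  OLS counterparts and ≥9 of 10 cover zero on a single N=10,000 draw.
* Collider contrast: restricted |IV|/|OLS| mean-absolute-component ratio
  ≥ 10 over 100 seeds; unrestricted ratio is order 1.

## Numerical and degenerate-input choices

* Zero first stage (identical exposure means across instrument arms) raises
  a `DegenerateInstrumentError`; no estimate is fabricated.
* Constant covariates/outcomes yield flagged degenerate rows (estimate 0,
  se 0) so that report rows are preserved instead of silently vanishing;
  degenerate rows suppress the difference test.
* Missing covariate/outcome values are handled per-operation by
  complete-case analysis on the columns that operation uses; every result
  records the N actually used, and rejected rows at load time are counted,
  never silently dropped.
* `var(b_iv − b_ols)` is floored at 0 against round-off; the moment
  Jacobian is screened by SVD before solving (relative tolerance 1e-12).
* Binary columns are detected by value set {0,1} after optional recoding,
  never by dtype.
* Cluster labels are opaque; estimates are invariant to row order and
  relabeling (property-tested).

## Limitations

Constant-treatment-effect assumption throughout (the bias-component algebra
relies on it); no binary-outcome link functions; no multi-instrument or
overidentification machinery; no automated selection of negative controls;
no FDR layer on the balance table. The bias-ratio and prevalence-difference
ratio statistics from the earlier balance literature are out of scope.
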