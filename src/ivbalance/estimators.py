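"""Wald/2SLS effect estimator, OLS and IV bias components, and instrument strength.

The confounding bias that an omitted covariate C (with unit effect on the
outcome) induces is, for conventional regression, the covariate mean
difference across exposure arms,

    bias_OLS = E[C | X=1] - E[C | X=0],

and for the Wald/IV estimator, the covariate mean difference across
instrument arms scaled up by the first stage,

    bias_IV = (E[C | Z=1] - E[C | Z=0]) / (E[X | Z=1] - E[X | Z=0]).

Both are estimated here as just-identified linear moment systems so that the
point estimates equal the group-mean formulas exactly while standard errors
come from a cluster-robust sandwich (clustered on the physician identifier).
All intervals use normal quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from ._linmoments import DegenerateSystemError, fit_linear_moments
from .data_model import CohortTable


class DegenerateInstrumentError(ValueError):
    """Zero first stage: exposure means are identical across instrument arms."""


@dataclass(frozen=True)
class EstimateWithCI:
    """Point estimate with cluster-robust standard error and normal-quantile CI."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    n_used: int = 0
    n_clusters: int = 0
    degenerate: bool = False

    @classmethod
    def from_point(cls, estimate: float, se: float, level: float,
                   n_used: int, n_clusters: int, degenerate: bool = False) -> "EstimateWithCI":
        z = stats.norm.ppf(0.5 + level / 2.0)
        return cls(estimate=float(estimate), se=float(se),
                   ci_low=float(estimate - z * se), ci_high=float(estimate + z * se),
                   level=level, n_used=n_used, n_clusters=n_clusters, degenerate=degenerate)

    def scaled(self, k: float) -> "EstimateWithCI":
        """The estimate on a rescaled covariate/outcome scale (e.g. x100)."""
        lo, hi = sorted((self.ci_low * k, self.ci_high * k))
        return replace(self, estimate=self.estimate * k, se=abs(self.se * k),
                       ci_low=lo, ci_high=hi)


@dataclass(frozen=True)
class FirstStage:
    """Instrument-exposure association: risk difference and partial F-statistic."""

    risk_difference: EstimateWithCI
    partial_F: float


def _slope_fit(y: np.ndarray, regressor: np.ndarray, instrument: np.ndarray,
               clusters: np.ndarray, level: float):
    """Slope of y on [1, regressor] with instruments [1, instrument]."""
    n = len(y)
    X = np.column_stack([np.ones(n), regressor])
    Z = np.column_stack([np.ones(n), instrument])
    fit = fit_linear_moments(X, Z, y, clusters)
    return EstimateWithCI.from_point(fit.theta[1], fit.se(1), level, fit.n, fit.n_clusters)


def _check_first_stage(cohort: CohortTable) -> None:
    z, x = cohort.instrument, cohort.exposure
    if np.mean(x[z == 1]) == np.mean(x[z == 0]):
        raise DegenerateInstrumentError(
            "exposure mean identical across instrument arms (zero first stage)"
        )


def wald_estimate(cohort: CohortTable, outcome: str, level: float = 0.95) -> EstimateWithCI:
    """Wald/2SLS estimate of the exposure effect on ``outcome``.

    The point estimate is the ratio of instrument-arm mean differences,
    psi = (ybar1 - ybar0) / (xbar1 - xbar0); the standard error is the
    cluster-robust 2SLS sandwich, which for a single binary instrument
    estimates the same quantity.
    """
    cc = cohort.complete_case([outcome])
    _check_first_stage(cc)
    try:
        return _slope_fit(cc.column(outcome), cc.exposure, cc.instrument,
                          cc.cluster, level)
    except DegenerateSystemError as exc:  # pragma: no cover - guarded above
        raise DegenerateInstrumentError(str(exc)) from exc


def ols_bias_component(cohort: CohortTable, covariate: str, level: float = 0.95) -> EstimateWithCI:
    """Covariate mean difference across exposure arms (OLS slope of C on X).

    A constant covariate yields a flagged degenerate zero estimate rather
    than an error, so report rows for empty strata are preserved.
    """
    cc = cohort.complete_case([covariate])
    c = cc.column(covariate)
    if np.min(c) == np.max(c):
        return EstimateWithCI.from_point(0.0, 0.0, level, cc.n, cc.n_clusters, degenerate=True)
    x = cc.exposure
    if np.min(x) == np.max(x):
        return EstimateWithCI.from_point(0.0, 0.0, level, cc.n, cc.n_clusters, degenerate=True)
    return _slope_fit(c, x, x, cc.cluster, level)


def iv_bias_component(cohort: CohortTable, covariate: str, level: float = 0.95) -> EstimateWithCI:
    """IV bias component: Wald ratio with the covariate in place of the outcome."""
    cc = cohort.complete_case([covariate])
    c = cc.column(covariate)
    if np.min(c) == np.max(c):
        return EstimateWithCI.from_point(0.0, 0.0, level, cc.n, cc.n_clusters, degenerate=True)
    _check_first_stage(cc)
    return _slope_fit(c, cc.exposure, cc.instrument, cc.cluster, level)


def first_stage(cohort: CohortTable, level: float = 0.95) -> FirstStage:
    """Instrument strength: risk difference E[X|Z=1]-E[X|Z=0] and partial F.

    With a single instrument the partial F-statistic is the squared
    (cluster-robust) t-ratio of the instrument coefficient in the
    first-stage regression of exposure on instrument.
    """
    cc = cohort.complete_case([])
    x, z = cc.exposure, cc.instrument
    rd = _slope_fit(x, z, z, cc.cluster, level)
    partial_F = (rd.estimate / rd.se) ** 2 if rd.se > 0 else float("inf")
    return FirstStage(risk_difference=rd, partial_F=float(partial_F))
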