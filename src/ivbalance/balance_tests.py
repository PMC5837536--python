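"""Modified Hausman test for OLS-vs-IV bias-component differences.

For a single covariate C the two bias components are estimated JOINTLY from
stacked estimating equations on the same sample.  Writing the OLS residual
r1_i = c_i - a1 - b_ols * x_i and the IV residual r2_i = c_i - a2 - b_iv * x_i,
the moment conditions are

    E[(1, x_i)' r1_i] = 0        (OLS block)
    E[(1, z_i)' r2_i] = 0        (IV block)

— four moments for four parameters, so the system is exactly identified and
the joint point estimates reproduce the single-equation estimates.  What the
joint fit adds is the clustered sandwich covariance of (b_ols, b_iv) over the
stacked per-cluster moment sums, which supplies var(b_iv - b_ols) including
their covariance.  The test statistic

    (b_iv - b_ols) / sqrt(var(b_iv - b_ols))  ~  N(0, 1)

has null hypothesis "no difference between the two bias components"; a small
p-value marks a covariate as informative about the relative bias of the two
designs.  One-step GMM with identity weighting; weighting is irrelevant for
point estimates in an exactly identified system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._linmoments import DegenerateSystemError, fit_linear_moments
from .data_model import CohortTable
from .estimators import (
    DegenerateInstrumentError,
    EstimateWithCI,
    FirstStage,
    first_stage,
)

METHOD_LABEL = "modified Hausman (stacked moments, one-step GMM, identity weighting)"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    difference: float        # b_iv - b_ols
    se_difference: float
    method: str = METHOD_LABEL


@dataclass(frozen=True)
class BiasComponentPair:
    """One balance-table row: both bias components for a covariate plus the test."""

    covariate: str
    ols: EstimateWithCI
    iv: EstimateWithCI
    test: TestResult | None
    degenerate: bool = False


@dataclass(frozen=True)
class BalanceReport:
    """Ordered bias-component pairs plus first-stage strength for a cohort."""

    pairs: Sequence[BiasComponentPair]
    first_stage: FirstStage
    n: int
    n_clusters: int
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append({
                "covariate": p.covariate,
                "ols_estimate": p.ols.estimate, "ols_low": p.ols.ci_low, "ols_high": p.ols.ci_high,
                "iv_estimate": p.iv.estimate, "iv_low": p.iv.ci_low, "iv_high": p.iv.ci_high,
                "difference": p.test.difference if p.test else np.nan,
                "p_value": p.test.p_value if p.test else np.nan,
                "n_used": p.ols.n_used,
                "flags": "degenerate" if p.degenerate else "",
            })
        return pd.DataFrame(rows)


def _stacked_fit(c: np.ndarray, x: np.ndarray, z: np.ndarray, clusters: np.ndarray):
    """Joint fit of (a1, b_ols, a2, b_iv); returns theta and its 4x4 covariance."""
    n = len(c)
    one = np.ones(n)
    zero = np.zeros(n)
    # stacked data: rows 1..n are the OLS equation, rows n+1..2n the IV equation
    X = np.block([[np.column_stack([one, x]), np.zeros((n, 2))],
                  [np.zeros((n, 2)), np.column_stack([one, x])]])
    Z = np.block([[np.column_stack([one, x]), np.zeros((n, 2))],
                  [np.zeros((n, 2)), np.column_stack([one, z])]])
    y = np.concatenate([c, c])
    cl = np.concatenate([clusters, clusters])
    return fit_linear_moments(X, Z, y, cl)


def hausman_bias_test(cohort: CohortTable, covariate: str, level: float = 0.95) -> BiasComponentPair:
    """Jointly estimate both bias components for ``covariate`` and test their difference.

    Raises :class:`DegenerateInstrumentError` on a zero first stage.  A
    constant covariate returns a degenerate pair with the test suppressed.
    """
    cc = cohort.complete_case([covariate])
    c = cc.column(covariate)
    if np.min(c) == np.max(c):
        zero = EstimateWithCI.from_point(0.0, 0.0, level, cc.n, cc.n_clusters, degenerate=True)
        return BiasComponentPair(covariate=covariate, ols=zero, iv=zero,
                                 test=None, degenerate=True)
    x, z = cc.exposure, cc.instrument
    if np.mean(x[z == 1]) == np.mean(x[z == 0]):
        raise DegenerateInstrumentError(
            f"zero first stage: cannot test covariate {covariate!r}"
        )
    try:
        fit = _stacked_fit(c, x, z, cc.cluster)
    except DegenerateSystemError as exc:
        raise DegenerateInstrumentError(str(exc)) from exc

    b_ols, b_iv = fit.theta[1], fit.theta[3]
    ols = EstimateWithCI.from_point(b_ols, fit.se(1), level, cc.n, cc.n_clusters)
    iv = EstimateWithCI.from_point(b_iv, fit.se(3), level, cc.n, cc.n_clusters)
    diff = b_iv - b_ols
    var_diff = fit.vcov[3, 3] + fit.vcov[1, 1] - 2.0 * fit.vcov[1, 3]
    var_diff = max(var_diff, 0.0)
    se_diff = float(np.sqrt(var_diff))
    if se_diff > 0:
        statistic = diff / se_diff
    else:
        statistic = 0.0 if diff == 0 else np.sign(diff) * np.inf
    p_value = float(2.0 * stats.norm.sf(abs(statistic)))
    test = TestResult(statistic=float(statistic), p_value=p_value,
                      difference=float(diff), se_difference=se_diff)
    return BiasComponentPair(covariate=covariate, ols=ols, iv=iv, test=test)


def balance_table(cohort: CohortTable, covariates: Sequence[str] | None = None,
                  level: float = 0.95) -> BalanceReport:
    """Full covariate-balance report: one Hausman pair per covariate + first stage.

    Per-covariate degeneracies (constant columns) are flagged in place; they
    never abort the table.  P-values are raw — no multiplicity adjustment.
    """
    if covariates is None:
        covariates = list(cohort.roles.covariate_cols)
    if len(covariates) == 0:
        raise ValueError("covariate list must be non-empty")
    pairs = [hausman_bias_test(cohort, cov, level=level) for cov in covariates]
    fs = first_stage(cohort, level=level)
    meta = {
        "method": METHOD_LABEL,
        "cluster_col": cohort.roles.cluster_col,
        "variance": "one-way cluster-robust sandwich, G/(G-1) small-sample factor",
        "ci": f"normal quantiles, level={level}",
        "missing_data": "complete-case per covariate",
    }
    return BalanceReport(pairs=pairs, first_stage=fs, n=cohort.n,
                         n_clusters=cohort.n_clusters, metadata=meta)
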