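"""Negative-control outcome and negative-control population tests.

A negative-control outcome is plausibly affected by the same confounders as
the outcome of interest but not by the exposure (for a smoking-cessation
drug: urinary tract infections).  An exposure-outcome association that the
instrument-based estimate does not show suggests residual confounding in the
conventional analysis; an instrument association suggests instrument
invalidity.

A negative-control population shares the confounding structure but is
unexposed (patients who saw the same physician but were not prescribed the
study drugs).  Any instrument-outcome association there signals that the
proposed instrument operates through a pathway other than treatment.

Everything is on the linear (risk-difference) scale; binary outcomes are
reported x100 in serialized reports, continuous ones as raw mean differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import CohortTable
from .estimators import (
    DegenerateInstrumentError,
    EstimateWithCI,
    _slope_fit,
    wald_estimate,
)


@dataclass(frozen=True)
class NCOutcomeResult:
    """Conventional (OLS) and IV estimates of the exposure effect on one negative control."""

    outcome: str
    conventional: EstimateWithCI
    iv: EstimateWithCI | None      # None when the instrument is degenerate
    n: int


@dataclass(frozen=True)
class NCReport:
    """Instrument-outcome associations in a negative-control population."""

    rows: Sequence[tuple[str, EstimateWithCI, bool]]  # (outcome, estimate, is_binary)
    n: int

    def to_frame(self) -> pd.DataFrame:
        out = []
        for name, est, is_binary in self.rows:
            scaled = est.scaled(100.0) if is_binary else est
            out.append({
                "outcome": name,
                "estimate": scaled.estimate,
                "ci_low": scaled.ci_low, "ci_high": scaled.ci_high,
                "scale": "risk difference x 100" if is_binary else "mean difference",
                "n_used": est.n_used,
                "flags": "degenerate" if est.degenerate else "",
            })
        return pd.DataFrame(out)


def nc_outcome_test(cohort: CohortTable, nc_outcome: str, level: float = 0.95) -> NCOutcomeResult:
    """Side-by-side conventional and IV estimates for a negative-control outcome.

    Both estimates are computed on the same complete-case sample.  The
    operation reports estimates only; judging which analysis "passes" is the
    user's call.  A degenerate instrument flags the IV side but still
    returns the conventional estimate.
    """
    cc = cohort.complete_case([nc_outcome])
    y = cc.column(nc_outcome)
    if np.min(y) == np.max(y):
        zero = EstimateWithCI.from_point(0.0, 0.0, level, cc.n, cc.n_clusters, degenerate=True)
        return NCOutcomeResult(outcome=nc_outcome, conventional=zero, iv=zero, n=cc.n)
    conventional = _slope_fit(y, cc.exposure, cc.exposure, cc.cluster, level)
    try:
        iv = wald_estimate(cc, nc_outcome, level=level)
    except DegenerateInstrumentError:
        iv = None
    return NCOutcomeResult(outcome=nc_outcome, conventional=conventional, iv=iv, n=cc.n)


def nc_population_test(nc_cohort: CohortTable, outcomes: Sequence[str],
                       level: float = 0.95) -> NCReport:
    """Instrument-outcome associations across a negative-control population.

    For each outcome, the slope from a least-squares fit of outcome on
    instrument with physician-clustered robust CI.  The exposure role of the
    cohort is unused.  Binary outcomes are tagged for x100 reporting.
    """
    if len(outcomes) == 0:
        raise ValueError("outcome list must be non-empty")
    rows = []
    for name in outcomes:
        cc = nc_cohort.complete_case([name])
        y = cc.column(name)
        if np.min(y) == np.max(y):
            est = EstimateWithCI.from_point(0.0, 0.0, level, cc.n, cc.n_clusters, degenerate=True)
            rows.append((name, est, cc.is_binary(name)))
            continue
        est = _slope_fit(y, cc.instrument, cc.instrument, cc.cluster, level)
        if est.se == 0.0:
            est = EstimateWithCI.from_point(est.estimate, 0.0, level,
                                            est.n_used, est.n_clusters, degenerate=True)
        rows.append((name, est, cc.is_binary(name)))
    return NCReport(rows=rows, n=nc_cohort.n)
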