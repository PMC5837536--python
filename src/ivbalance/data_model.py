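"""Cohort data structures, column-role mapping, and validated delimited-text I/O.

A cohort is a rectangular patient-level table with one row per patient and
columns playing fixed roles: a binary exposure (treatment received), a binary
instrument (e.g. the prescription the physician issued to their previous
patient), one or more numeric outcome columns, one or more numeric covariate
columns, and a cluster identifier (physician or practice) for robust
variance estimation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class CohortValidationError(ValueError):
    """Input data violates a cohort invariant (non-binary exposure, ...)."""


class ConfigurationError(ValueError):
    """A role mapping or configuration problem (missing column, ...)."""


@dataclass(frozen=True)
class ColumnRoleMap:
    """Maps raw column names onto the roles the estimators need.

    ``binary_value_map`` optionally recodes raw exposure/instrument codes
    (e.g. ``{"NRT": 0, "varenicline": 1}``) onto {0, 1}.
    """

    exposure_col: str
    instrument_col: str
    outcome_cols: Sequence[str]
    covariate_cols: Sequence[str]
    cluster_col: str
    weight_col: str | None = None
    binary_value_map: Mapping[object, int] | None = None

    def __post_init__(self) -> None:
        names = [self.exposure_col, self.instrument_col, self.cluster_col]
        names += list(self.outcome_cols) + list(self.covariate_cols)
        if self.weight_col is not None:
            names.append(self.weight_col)
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigurationError(f"column assigned to multiple roles: {sorted(dupes)}")

    @property
    def all_columns(self) -> list[str]:
        cols = [self.exposure_col, self.instrument_col, self.cluster_col]
        cols += list(self.outcome_cols) + list(self.covariate_cols)
        if self.weight_col is not None:
            cols.append(self.weight_col)
        return cols


@dataclass(frozen=True)
class CohortTable:
    """Validated patient-level cohort.

    ``data`` holds the (possibly recoded) columns; ``roles`` names which
    column plays which role.  ``n_rejected`` counts input rows dropped for
    missing exposure/instrument/cluster values — rejection is reported, never
    silent.
    """

    data: pd.DataFrame
    roles: ColumnRoleMap
    n_rejected: int = 0

    def __post_init__(self) -> None:
        _validate(self.data, self.roles)

    # -- convenience accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def exposure(self) -> np.ndarray:
        return self.data[self.roles.exposure_col].to_numpy(dtype=float)

    @property
    def instrument(self) -> np.ndarray:
        return self.data[self.roles.instrument_col].to_numpy(dtype=float)

    @property
    def cluster(self) -> np.ndarray:
        return self.data[self.roles.cluster_col].to_numpy()

    @property
    def n_clusters(self) -> int:
        return self.data[self.roles.cluster_col].nunique()

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise ConfigurationError(f"column {name!r} not present in cohort")
        return self.data[name].to_numpy(dtype=float)

    def is_binary(self, name: str) -> bool:
        """True if the column's non-missing values lie in {0, 1}."""
        vals = self.data[name].dropna().unique()
        return len(vals) > 0 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}

    def complete_case(self, columns: Sequence[str]) -> "CohortTable":
        """Rows with no missing values in ``columns`` (plus the core roles)."""
        core = [self.roles.exposure_col, self.roles.instrument_col, self.roles.cluster_col]
        keep = self.data.dropna(subset=list(dict.fromkeys(core + list(columns))))
        return CohortTable(data=keep.reset_index(drop=True), roles=self.roles,
                           n_rejected=self.n_rejected + (len(self.data) - len(keep)))


def _validate(df: pd.DataFrame, roles: ColumnRoleMap) -> None:
    for col in roles.all_columns:
        if col not in df.columns:
            raise ConfigurationError(f"role column {col!r} missing from data")
    if len(df) < 2:
        raise CohortValidationError(f"cohort needs at least 2 rows, got {len(df)}")
    for role, col in (("exposure", roles.exposure_col), ("instrument", roles.instrument_col)):
        series = df[col]
        if series.isna().any():
            raise CohortValidationError(f"{role} column {col!r} contains missing values")
        bad = sorted(set(np.asarray(series, dtype=float)) - {0.0, 1.0})
        if bad:
            raise CohortValidationError(
                f"{role} column {col!r} must be binary 0/1; offending values: {bad}"
            )
    if df[roles.cluster_col].isna().any():
        raise CohortValidationError(f"cluster column {roles.cluster_col!r} contains missing values")
    z = np.asarray(df[roles.instrument_col], dtype=float)
    if z.min() == z.max():
        raise CohortValidationError("instrument must have both arms present (all values identical)")
    for col in list(roles.outcome_cols) + list(roles.covariate_cols):
        if not np.issubdtype(pd.to_numeric(df[col], errors="coerce").dtype, np.number):
            raise CohortValidationError(f"column {col!r} is not numeric")  # pragma: no cover
    if roles.weight_col is not None:
        w = df[roles.weight_col]
        if (w <= 0).any() or w.isna().any():
            raise CohortValidationError("weights must be positive and non-missing")


def read_cohort(path: str | Path, roles: ColumnRoleMap, delimiter: str = ",") -> CohortTable:
    """Read a delimited text file and return a validated :class:`CohortTable`.

    Exposure and instrument are recoded through ``roles.binary_value_map``
    when given.  Rows with missing exposure, instrument or cluster values are
    rejected and counted in ``n_rejected``.  Non-binary exposure/instrument
    values after mapping raise :class:`CohortValidationError` naming the
    column and values.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    df = pd.read_csv(path, delimiter=delimiter)
    return cohort_from_frame(df, roles)


def cohort_from_frame(df: pd.DataFrame, roles: ColumnRoleMap) -> CohortTable:
    """Validate an in-memory DataFrame as a cohort (same rules as :func:`read_cohort`)."""
    for col in roles.all_columns:
        if col not in df.columns:
            raise ConfigurationError(f"role column {col!r} missing from input")
    df = df.copy()
    if roles.binary_value_map is not None:
        mapping = {k: int(v) for k, v in roles.binary_value_map.items()}
        for col in (roles.exposure_col, roles.instrument_col):
            df[col] = df[col].map(lambda v: mapping.get(v, v))
    core = [roles.exposure_col, roles.instrument_col, roles.cluster_col]
    complete = df.dropna(subset=core).copy()
    n_rejected = len(df) - len(complete)
    for col in (roles.exposure_col, roles.instrument_col):
        try:
            complete[col] = pd.to_numeric(complete[col])
        except (ValueError, TypeError) as exc:
            raise CohortValidationError(
                f"column {col!r} has non-numeric values after mapping: {exc}"
            ) from exc
    for col in list(roles.outcome_cols) + list(roles.covariate_cols):
        complete[col] = pd.to_numeric(complete[col], errors="raise")
    return CohortTable(data=complete.reset_index(drop=True), roles=roles, n_rejected=n_rejected)


def write_cohort(cohort: CohortTable, path: str | Path, delimiter: str = ",") -> None:
    """Write the cohort back to delimited text (numeric columns at 17 sig. digits)."""
    cohort.data.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def write_report(report, path: str | Path, format: str = "csv") -> None:
    """Serialize a balance or negative-control report to delimited text.

    One row per covariate/outcome with estimate, CI bounds and p-value
    columns; numbers round-trip to at least 12 significant digits.
    """
    frame = report.to_frame()
    if len(frame) == 0:
        raise ValueError("refusing to write an empty report")
    if format not in ("csv", "tsv"):
        raise ConfigurationError(f"unknown report format {format!r}")
    sep = "," if format == "csv" else "\t"
    buf = io.StringIO()
    frame.to_csv(buf, sep=sep, index=False, float_format="%.15g")
    Path(path).write_text(buf.getvalue())
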