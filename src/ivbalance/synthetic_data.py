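"""Simulation machinery: validity DGP, collider/selection DGP, and a clustered
physician-preference cohort with negative controls.

Three generators:

``simulate_validity_dgp``
    A hypothetical analysis with a valid binary instrument.  Latent standard
    normals u (confounder), w, v; instrument z ~ Bernoulli(0.2); ten
    dichotomous pseudo-confounders c1..c10 ~ Bernoulli(0.2) independent of
    everything; exposure x = 1(z*gamma + u + w > d) with gamma = 0.5 and d
    calibrated so Pr[x=1] = 0.2; outcome y = x*beta + u + v with beta = 0.5;
    N = 10,000.  OLS of y on x is confounded through u; the Wald/IV estimate
    is consistent for beta.

``simulate_collider_dgp``
    A valid-instrument design plus a treatment-receipt indicator caused by
    BOTH the instrument and the true confounder.  Restricting analysis to
    treated patients conditions on that collider, inducing an
    instrument-confounder association while also shrinking the first stage —
    the IV bias component of a measured proxy confounder (squared correlation
    r2 with the truth, default 0.01) then blows up by an order of magnitude
    relative to the OLS component.  The receipt mechanism's constants are
    package defaults documented in the config; only the proxy r2 and the
    treated-only restriction are externally specified design features.

``simulate_preference_cohort``
    A clustered cohort emulating a physician-preference design: each
    physician has a latent preference; each patient's instrument is the
    physician's PREVIOUS patient's prescription; exposure depends on
    preference plus a patient-level confounder; outcomes include a
    true-effect outcome and a negative-control outcome driven only by the
    confounder.  A companion negative-control population shares physicians
    and confounder structure but has no exposure.

Sampling order within each generator is fixed (documented per function) so a
seed fully determines the table for a given implementation; seeds are not
portable across numpy versions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import CohortTable, ColumnRoleMap, write_cohort


@dataclass(frozen=True)
class SimulationConfig:
    """Data-generating-process parameters.

    Defaults reproduce the validity simulation: N=10,000 patients, instrument
    strength gamma=0.5 on the latent exposure index, treatment effect
    beta=0.5, ten Bernoulli(0.2) pseudo-confounders, instrument and exposure
    prevalences 0.2.  ``proxy_r2`` and the ``selection_*``/``restrict_to_treated``
    fields apply to the collider DGP only.
    """

    n: int = 10_000
    gamma: float = 0.5
    beta: float = 0.5
    n_pseudo_confounders: int = 10
    instrument_prevalence: float = 0.2
    pseudo_confounder_prevalence: float = 0.2
    target_exposure_prevalence: float = 0.2
    seed: int = 0
    # collider DGP only
    proxy_r2: float = 0.01
    restrict_to_treated: bool = False
    selection_instrument_strength: float = 2.0
    selection_confounder_strength: float = 2.0
    selection_prevalence: float = 0.5

    def __post_init__(self) -> None:
        for name in ("instrument_prevalence", "pseudo_confounder_prevalence",
                     "target_exposure_prevalence", "selection_prevalence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.n < 10:
            raise ValueError(f"n must be >= 10, got {self.n}")
        if not 0.0 <= self.proxy_r2 < 1.0:
            raise ValueError(f"proxy_r2 must be in [0,1), got {self.proxy_r2}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_VALIDITY_ROLES_BASE = dict(exposure_col="x", instrument_col="z",
                            outcome_cols=("y",), cluster_col="cluster")


def calibrate_threshold(gamma: float, instrument_prevalence: float,
                        target_exposure_prevalence: float,
                        index_sd: float = np.sqrt(2.0)) -> float:
    """Solve for the exposure threshold d so that Pr[x = 1] hits its target.

    The exposure index is z*gamma + s with s normal (sd ``index_sd``; u + w
    gives sd sqrt(2)), so the exposure prevalence is the two-arm mixture

        p_z * Phi((gamma - d)/sd) + (1 - p_z) * Phi(-d/sd).

    The root is bracketed and solved to |f(d)| < 1e-10.
    """
    p_z, target = instrument_prevalence, target_exposure_prevalence
    if not 0.0 < target < 1.0:
        raise ValueError("target exposure prevalence must be in (0,1)")

    def prevalence_gap(d: float) -> float:
        return (p_z * stats.norm.cdf((gamma - d) / index_sd)
                + (1 - p_z) * stats.norm.cdf(-d / index_sd) - target)

    lo, hi = -10.0, 10.0 + abs(gamma)
    if prevalence_gap(lo) * prevalence_gap(hi) > 0:
        raise ArithmeticError("no sign change in [-10, 10+|gamma|]; cannot bracket d")
    d = optimize.brentq(prevalence_gap, lo, hi, xtol=1e-13)
    if abs(prevalence_gap(d)) >= 1e-10:
        raise ArithmeticError("root finding did not converge to |f(d)| < 1e-10")
    return float(d)


def simulate_validity_dgp(config: SimulationConfig) -> CohortTable:
    """Generate one cohort from the valid-instrument DGP.

    Sampling order (fixed): z, pseudo-confounders c1..ck, u, w, v; then the
    deterministic x and y.  Each row is its own cluster, so cluster-robust
    machinery reduces to heteroskedasticity-robust variances.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    z = (rng.random(n) < config.instrument_prevalence).astype(float)
    cnames = [f"c{j}" for j in range(1, config.n_pseudo_confounders + 1)]
    cmat = (rng.random((n, len(cnames))) < config.pseudo_confounder_prevalence).astype(float)
    u = rng.standard_normal(n)
    w = rng.standard_normal(n)
    v = rng.standard_normal(n)
    d = calibrate_threshold(config.gamma, config.instrument_prevalence,
                            config.target_exposure_prevalence)
    x = (z * config.gamma + u + w > d).astype(float)
    y = x * config.beta + u + v
    df = pd.DataFrame({"z": z, "x": x, "y": y})
    for j, name in enumerate(cnames):
        df[name] = cmat[:, j]
    df["cluster"] = np.arange(n)
    roles = ColumnRoleMap(covariate_cols=tuple(cnames), **_VALIDITY_ROLES_BASE)
    return CohortTable(data=df, roles=roles)


def simulate_collider_dgp(config: SimulationConfig) -> CohortTable:
    """Generate one cohort from the collider/selection DGP.

    On top of the valid-instrument structure (z, u, w, v, thresholded x,
    linear y) two elements are added, sampled in this order after v:
    the proxy noise and the receipt noise.

    * ``proxy`` = sqrt(r2)*u + sqrt(1-r2)*eps with eps ~ N(0,1): a measured
      covariate whose squared correlation with the true confounder is r2.
    * ``treated`` = 1(az*z + au*u + e > d_s): treatment receipt caused by
      both instrument and confounder, with receipt prevalence calibrated to
      ``selection_prevalence``.  Conditioning on treated = 1 (set
      ``restrict_to_treated``) makes z and u dependent and weakens the first
      stage, which is exactly the collider-bias failure mode the diagnostics
      should detect.

    The full table always carries ``u_true`` and ``treated`` so callers can
    apply or study the restriction themselves.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    z = (rng.random(n) < config.instrument_prevalence).astype(float)
    u = rng.standard_normal(n)
    w = rng.standard_normal(n)
    v = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    e_sel = rng.standard_normal(n)

    d = calibrate_threshold(config.gamma, config.instrument_prevalence,
                            config.target_exposure_prevalence)
    x = (z * config.gamma + u + w > d).astype(float)
    y = x * config.beta + u + v
    proxy = np.sqrt(config.proxy_r2) * u + np.sqrt(1.0 - config.proxy_r2) * eps

    az = config.selection_instrument_strength
    au = config.selection_confounder_strength
    d_sel = calibrate_threshold(az, config.instrument_prevalence,
                                config.selection_prevalence,
                                index_sd=float(np.hypot(au, 1.0)))
    treated = (az * z + au * u + e_sel > d_sel).astype(float)

    df = pd.DataFrame({"z": z, "x": x, "y": y, "proxy": proxy,
                       "u_true": u, "treated": treated,
                       "cluster": np.arange(n)})
    if config.restrict_to_treated:
        df = df[df["treated"] == 1.0].reset_index(drop=True)
    roles = ColumnRoleMap(exposure_col="x", instrument_col="z", outcome_cols=("y",),
                          covariate_cols=("proxy", "u_true"), cluster_col="cluster")
    return CohortTable(data=df, roles=roles)


@dataclass(frozen=True)
class PreferenceConfig:
    """Physician-preference cohort parameters.

    ``n_physicians`` physicians each see ~``mean_patients`` index patients
    (Poisson, min 2) plus ~``mean_nc_patients`` negative-control patients.
    Physician preference is a latent normal with sd ``preference_sd``; the
    patient confounder enters the exposure index with weight
    ``confounder_effect`` and the outcome with weight 1.
    """

    n_physicians: int = 300
    mean_patients: float = 30.0
    mean_nc_patients: float = 20.0
    preference_sd: float = 1.0
    confounder_effect: float = 1.0
    beta: float = 0.5
    n_covariates: int = 26
    covariate_prevalence: float = 0.2
    nc_outcome_prevalence: float = 0.2
    n_nc_outcomes: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_physicians < 2:
            raise ValueError("need at least 2 physicians")
        if self.mean_patients < 2:
            raise ValueError("need on average at least 2 patients per physician")


def simulate_preference_cohort(config: PreferenceConfig) -> tuple[CohortTable, CohortTable]:
    """Generate an index cohort and a negative-control population.

    Index cohort: per physician g, preference a_g ~ N(0, sd^2); patient i has
    confounder q_i ~ N(0,1); prescription
    x_i = 1(a_g + lam*q_i + e_i > t) with t set so marginal exposure
    prevalence is ~0.5 (two active drugs); the instrument z_i is the
    physician's previous patient's prescription (the first patient per
    physician is dropped).  Outcomes: y = beta*x + q + noise (true effect)
    and nc_outcome = 1(q + noise > threshold) (confounder-driven only, so a
    valid instrument should show no association).  Binary covariates cov_j
    are probit draws loaded on q, mimicking baseline comorbidity columns.

    Negative-control population: new patients of the same physicians with
    fresh confounders; their "instrument" is the physician's last index
    prescription; outcomes nco_j are confounder-driven Bernoullis, so under
    this valid-preference design the instrument is null for all of them.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_physicians
    pref = rng.normal(0.0, config.preference_sd, size=G)
    counts = np.maximum(rng.poisson(config.mean_patients, size=G), 2)

    lam = config.confounder_effect
    # threshold so that marginal Pr[x=1] = 0.5 for the N(0, sd^2+lam^2+1) index
    t_x = 0.0

    frames = []
    for g in range(G):
        m = counts[g]
        q = rng.standard_normal(m)
        e = rng.standard_normal(m)
        x = (pref[g] + lam * q + e > t_x).astype(float)
        y = config.beta * x + q + rng.standard_normal(m)
        nc = (q + rng.standard_normal(m)
              > np.sqrt(2.0) * stats.norm.ppf(1 - config.nc_outcome_prevalence)).astype(float)
        cov = (stats.norm.ppf(config.covariate_prevalence)
               + 0.5 * q[:, None] + rng.standard_normal((m, config.n_covariates)) > 0)
        frame = pd.DataFrame({"physician": g, "x": x, "y": y, "nc_outcome": nc,
                              "confounder": q})
        for j in range(config.n_covariates):
            frame[f"cov{j + 1}"] = cov[:, j].astype(float)
        frame["z"] = frame["x"].shift(1)      # previous patient's prescription
        frames.append(frame.iloc[1:])         # first patient has no predecessor
    index_df = pd.concat(frames, ignore_index=True)

    cov_names = tuple(f"cov{j + 1}" for j in range(config.n_covariates))
    index_roles = ColumnRoleMap(exposure_col="x", instrument_col="z",
                                outcome_cols=("y", "nc_outcome"),
                                covariate_cols=cov_names, cluster_col="physician")
    index = CohortTable(data=index_df, roles=index_roles)

    # negative-control population: same physicians, fresh patients, no exposure
    last_rx = index_df.groupby("physician")["x"].last()
    nc_counts = np.maximum(rng.poisson(config.mean_nc_patients, size=G), 1)
    nc_frames = []
    thresh = np.sqrt(2.0) * stats.norm.ppf(1 - config.nc_outcome_prevalence)
    for g in range(G):
        m = nc_counts[g]
        q = rng.standard_normal(m)
        outcomes = (q[:, None] + rng.standard_normal((m, config.n_nc_outcomes))
                    > thresh).astype(float)
        frame = pd.DataFrame({"physician": np.full(m, g),
                              "z": np.full(m, float(last_rx.get(g, 0.0))),
                              "x": np.zeros(m)})
        for j in range(config.n_nc_outcomes):
            frame[f"nco{j + 1}"] = outcomes[:, j]
        nc_frames.append(frame)
    nc_df = pd.concat(nc_frames, ignore_index=True)
    nco_names = tuple(f"nco{j + 1}" for j in range(config.n_nc_outcomes))
    nc_roles = ColumnRoleMap(exposure_col="x", instrument_col="z",
                             outcome_cols=nco_names, covariate_cols=(),
                             cluster_col="physician")
    nc_pop = CohortTable(data=nc_df, roles=nc_roles)
    return index, nc_pop


def write_cohort_with_sidecar(cohort: CohortTable, config, path: str | Path) -> None:
    """Write the cohort CSV plus a JSON sidecar echoing the exact parameters."""
    path = Path(path)
    write_cohort(cohort, path)
    sidecar = path.with_suffix(path.suffix + ".config.json")
    cfg = config.to_dict() if hasattr(config, "to_dict") else dataclasses.asdict(config)
    sidecar.write_text(json.dumps(cfg, indent=2, default=str) + "\n")
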