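"""Replicated simulation experiments demonstrating when each diagnostic is informative.

These drive the package's own validation studies: parameter recovery of the
Wald estimator under the validity design, calibration of the exposure
threshold and the proxy construction, null calibration of the modified
Hausman test, and the collider-restriction contrast.  Each function derives
per-replicate seeds from a single master seed via ``numpy.random.SeedSequence``
so results are reproducible end to end.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .balance_tests import hausman_bias_test
from .estimators import iv_bias_component, ols_bias_component, wald_estimate
from .synthetic_data import (
    SimulationConfig,
    simulate_collider_dgp,
    simulate_validity_dgp,
)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """n independent child seeds (< 2^31) from one master seed."""
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(master_seed).spawn(n)]


def wald_recovery(n_replicates: int = 200, master_seed: int = 0,
                  config: SimulationConfig | None = None) -> tuple[float, float]:
    """Mean Wald/2SLS estimate over fresh validity-DGP replicates.

    Returns ``(mean, mc_standard_error_of_mean)``.  Under the default
    configuration the mean recovers the generating effect beta = 0.5.
    """
    base = config or SimulationConfig()
    ests = np.empty(n_replicates)
    for i, seed in enumerate(spawn_seeds(master_seed, n_replicates)):
        cohort = simulate_validity_dgp(dataclasses.replace(base, seed=seed))
        ests[i] = wald_estimate(cohort, "y").estimate
    return float(ests.mean()), float(ests.std(ddof=1) / np.sqrt(n_replicates))


def empirical_exposure_prevalence(n: int = 1_000_000, seed: int = 0,
                                  config: SimulationConfig | None = None) -> float:
    """Exposure prevalence in one large validity-DGP draw with calibrated threshold."""
    base = config or SimulationConfig()
    cohort = simulate_validity_dgp(dataclasses.replace(base, n=n, seed=seed))
    return float(cohort.exposure.mean())


def empirical_proxy_r2(n: int = 1_000_000, seed: int = 0,
                       config: SimulationConfig | None = None) -> float:
    """Squared sample correlation between proxy and true confounder in the collider DGP."""
    base = config or SimulationConfig()
    cohort = simulate_collider_dgp(dataclasses.replace(base, n=n, seed=seed))
    r = np.corrcoef(cohort.column("proxy"), cohort.column("u_true"))[0, 1]
    return float(r**2)


def hausman_null_rejection_rate(n_replicates: int = 1000, n: int = 2000,
                                alpha: float = 0.05, master_seed: int = 0,
                                covariate: str = "c1") -> float:
    """Rejection rate of the bias-difference test on a null pseudo-confounder.

    Under the validity DGP the pseudo-confounders are independent of
    everything, so both bias components are zero and rejections are type-I
    errors.
    """
    rejections = 0
    for seed in spawn_seeds(master_seed, n_replicates):
        cohort = simulate_validity_dgp(SimulationConfig(n=n, seed=seed))
        rejections += hausman_bias_test(cohort, covariate).test.p_value < alpha
    return rejections / n_replicates


def collider_component_ratio(n_seeds: int = 100, n: int = 10_000,
                             restrict_to_treated: bool = True,
                             master_seed: int = 0) -> tuple[float, float, float]:
    """Mean absolute IV and OLS bias components of the weak proxy confounder.

    Returns ``(mean_abs_iv, mean_abs_ols, ratio)`` over fresh collider-DGP
    draws.  With the treated-only restriction the IV component is an order
    of magnitude larger than the OLS component; without it the two are of
    the same order.
    """
    abs_iv = np.empty(n_seeds)
    abs_ols = np.empty(n_seeds)
    for i, seed in enumerate(spawn_seeds(master_seed, n_seeds)):
        cfg = SimulationConfig(n=n, seed=seed, restrict_to_treated=restrict_to_treated)
        cohort = simulate_collider_dgp(cfg)
        abs_iv[i] = abs(iv_bias_component(cohort, "proxy").estimate)
        abs_ols[i] = abs(ols_bias_component(cohort, "proxy").estimate)
    mean_iv, mean_ols = float(abs_iv.mean()), float(abs_ols.mean())
    return mean_iv, mean_ols, mean_iv / mean_ols
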