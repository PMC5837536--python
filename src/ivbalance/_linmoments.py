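"""Just-identified linear moment estimation with cluster-robust sandwich covariance.

All estimators in this package — OLS slopes, the Wald/2SLS ratio, and the
stacked two-equation system behind the modified Hausman test — solve moment
conditions of the form

    (1/n) sum_i z_i (y_i - x_i' theta) = 0

with as many instruments ``z_i`` as parameters.  The point estimate is
``theta = (Z'X)^{-1} Z'y`` and the variance is the sandwich

    V = A^{-1} B A^{-T} / n,   A = Z'X / n,
    B = (1/n) * G/(G-1) * sum_g s_g s_g',   s_g = sum_{i in g} z_i e_i,

where ``g`` indexes clusters and ``e_i`` are residuals.  With every row its
own cluster this reduces to a heteroskedasticity-robust (HC-type) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateSystemError(ValueError):
    """The moment Jacobian is singular (e.g. zero first stage)."""


@dataclass(frozen=True)
class MomentFit:
    """Solution of a just-identified linear moment system."""

    theta: np.ndarray          # (k,) point estimates
    vcov: np.ndarray           # (k, k) cluster-robust covariance of theta
    n: int                     # rows used
    n_clusters: int            # distinct clusters among rows used

    def se(self, j: int) -> float:
        return float(np.sqrt(self.vcov[j, j]))


def cluster_codes(clusters: np.ndarray) -> tuple[np.ndarray, int]:
    """Map opaque cluster labels to consecutive integer codes."""
    codes, uniques = pd_factorize(clusters)
    return codes, len(uniques)


def pd_factorize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # np.unique is deterministic and label-order independent for the sums below
    uniques, codes = np.unique(values, return_inverse=True)
    return codes, uniques


def fit_linear_moments(
    X: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray,
    *,
    rcond_fail: float = 1e-12,
) -> MomentFit:
    """Solve ``E[z (y - x'theta)] = 0`` and return cluster-robust covariance.

    Parameters
    ----------
    X : (n, k) regressor matrix (include the intercept column explicitly).
    Z : (n, k) instrument matrix; pass ``Z = X`` for OLS.
    y : (n,) response.
    clusters : (n,) cluster labels (any hashable dtype).

    Raises
    ------
    DegenerateSystemError
        If ``Z'X`` is numerically singular, which for the Wald systems here
        means a zero first stage or a constant regressor.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if Z.shape != (n, k):
        raise ValueError(f"Z must be {(n, k)}, got {Z.shape}")

    A = Z.T @ X / n
    # guard against singular/near-singular Jacobian before solving
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] <= rcond_fail * max(sv[0], 1.0):
        raise DegenerateSystemError(
            "moment Jacobian is singular (zero first stage or constant regressor)"
        )
    theta = np.linalg.solve(A, Z.T @ y / n)

    resid = y - X @ theta
    scores = Z * resid[:, None]                      # (n, k) per-row moments
    codes, G = cluster_codes(np.asarray(clusters))
    if G < 2:
        # single cluster: fall back to the unclustered outer product (no
        # correction factor is defined for G=1)
        S = scores
        B = S.T @ S / n
        correction = 1.0
    else:
        sums = np.zeros((G, k))
        np.add.at(sums, codes, scores)               # per-cluster score sums
        B = sums.T @ sums / n
        correction = G / (G - 1)
    Ainv = np.linalg.inv(A)
    vcov = correction * Ainv @ B @ Ainv.T / n
    # symmetrize against round-off
    vcov = (vcov + vcov.T) / 2.0
    return MomentFit(theta=theta, vcov=vcov, n=n, n_clusters=G)
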