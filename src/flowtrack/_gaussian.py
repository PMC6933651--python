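"""Multivariate Gaussian log-density primitives.

All covariance work goes through a lower-triangular Cholesky factor: the
log-determinant comes from the factor diagonal and quadratic forms from a
triangular solve.  No explicit matrix inverse is ever formed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import solve_triangular

LOG_2PI = math.log(2.0 * math.pi)

# Relative jitter applied once to the diagonal when factorisation fails;
# a second failure is a hard error (the cluster covariance is degenerate).
_JITTER_REL = 1e-8


class DegenerateCovarianceError(np.linalg.LinAlgError):
    """A cluster covariance matrix is not positive definite."""


def cholesky_factor(sigma: np.ndarray, cluster: int | None = None) -> np.ndarray:
    """Lower Cholesky factor of ``sigma`` with a single jitter retry."""
    sigma = np.asarray(sigma, dtype=float)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        jitter = _JITTER_REL * float(np.mean(np.diag(sigma)))
        try:
            return np.linalg.cholesky(sigma + jitter * np.eye(sigma.shape[0]))
        except np.linalg.LinAlgError as exc:
            name = "?" if cluster is None else str(cluster + 1)
            raise DegenerateCovarianceError(
                f"covariance of cluster {name} is not positive definite"
            ) from exc


def log_kernel_block(Y: np.ndarray, mu: np.ndarray, chol: np.ndarray) -> np.ndarray:
    """Gaussian log-kernel -1/2 (y-mu)' Sigma^-1 (y-mu) + 1/2 log|Sigma^-1|.

    Evaluated for every row of ``Y`` given the lower Cholesky factor of
    Sigma.  The additive -K/2 log(2 pi) normalisation constant is *not*
    included (it cancels when assignment probabilities are normalised).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    diff = (Y - np.asarray(mu, dtype=float)).T
    z = solve_triangular(chol, diff, lower=True, check_finite=False)
    quad = np.einsum("kn,kn->n", z, z)
    half_logdet_prec = -float(np.sum(np.log(np.diag(chol))))
    return -0.5 * quad + half_logdet_prec


def log_gaussian_density(
    y: np.ndarray,
    mu_l: np.ndarray,
    sigma_l: np.ndarray,
    include_norm_const: bool = False,
    cluster: int | None = None,
) -> float:
    """Log Gaussian kernel of one observation under one cluster.

    By default this is the unnormalised kernel used in the Gibbs assignment
    step; with ``include_norm_const=True`` the full log-density
    (including -K/2 log 2 pi) is returned.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    mu_l = np.atleast_1d(np.asarray(mu_l, dtype=float))
    sigma_l = np.atleast_2d(np.asarray(sigma_l, dtype=float))
    if y.shape != mu_l.shape or sigma_l.shape != (y.size, y.size):
        raise ValueError("dimension mismatch between y, mu_l and sigma_l")
    chol = cholesky_factor(sigma_l, cluster)
    val = float(log_kernel_block(y[None, :], mu_l, chol)[0])
    if include_norm_const:
        val -= 0.5 * y.size * LOG_2PI
    return val
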