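"""The four update equations of the stochastic EM algorithm.

* Gibbs sampling of cell-to-cluster assignments from the categorical
  posterior eta (Gaussian kernel times current mixture proportion),
* a fixed-point iteration for the Dirichlet persistency parameter alpha
  (the maximiser of the Dirichlet-multinomial likelihood of the sampled
  counts given the previous timepoint's proportions),
* the posterior-mean update of the mixture proportions pi, and
* MAP updates of the cluster means (Gaussian prior, precision scale tau)
  and covariances (Wishart prior on the precision, parameters nu, Lambda).
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from scipy.special import digamma, logsumexp

from ._gaussian import cholesky_factor, log_kernel_block
from .dataset import ClusterParams

ALPHA_MIN = 1e-6
ALPHA_MAX = 1e8
_PI_FLOOR = 1e-10


def assignment_log_weights(
    Y: np.ndarray,
    params: ClusterParams,
    pi_td: np.ndarray,
    chols: Optional[Sequence[np.ndarray]] = None,
) -> np.ndarray:
    """Unnormalised log assignment weights, shape (N, L)."""
    pi_td = np.asarray(pi_td, dtype=float)
    if np.all(pi_td <= 0):
        raise ValueError("all mixture-proportion entries are zero")
    L = params.n_clusters
    if pi_td.shape != (L,):
        raise ValueError(f"pi_td must have length {L}")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi_td)
    W = np.empty((Y.shape[0], L))
    for l in range(L):
        chol = chols[l] if chols is not None else cholesky_factor(params.sigma[l], l)
        W[:, l] = log_kernel_block(Y, params.mu[l], chol) + log_pi[l]
    return W


def assignment_probs_block(
    Y: np.ndarray,
    params: ClusterParams,
    pi_td: np.ndarray,
    chols: Optional[Sequence[np.ndarray]] = None,
) -> np.ndarray:
    """Categorical assignment probabilities eta for every row of ``Y``.

    Normalised in log space (log-sum-exp), so extreme kernels do not
    overflow.  Rows sum to 1.
    """
    W = assignment_log_weights(Y, params, pi_td, chols)
    W -= logsumexp(W, axis=1, keepdims=True)
    return np.exp(W)


def compute_assignment_probs(
    y: np.ndarray, params: ClusterParams, pi_td: np.ndarray
) -> np.ndarray:
    """Assignment probabilities eta for a single cell (length-L simplex)."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    return assignment_probs_block(y[None, :], params, pi_td)[0]


def sample_assignments_block(eta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical label per row of ``eta`` (0-based labels)."""
    eta = np.atleast_2d(np.asarray(eta, dtype=float))
    cum = np.cumsum(eta, axis=1)
    u = rng.random(eta.shape[0])
    return np.minimum((u[:, None] > cum).sum(axis=1), eta.shape[1] - 1)


def sample_assignment(eta: np.ndarray, rng: np.random.Generator) -> int:
    """Draw one cluster label (0-based) from the categorical eta."""
    return int(sample_assignments_block(np.asarray(eta)[None, :], rng)[0])


def _floor_simplex(pi: np.ndarray) -> np.ndarray:
    """Floor entries at 1e-10 and renormalise (keeps digamma arguments > 0)."""
    pi = np.maximum(np.asarray(pi, dtype=float), _PI_FLOOR)
    return pi / pi.sum()


def update_alpha(
    counts_td: np.ndarray,
    pi_prev: np.ndarray,
    alpha_start: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> float:
    """Fixed-point update of the persistency parameter alpha.

    Iterates ``alpha <- alpha * sum_l pi_prev_l * [psi(N_l + a pi_l) -
    psi(a pi_l)] / [psi(N + a) - psi(a)]`` until the relative change drops
    below ``tol``.  The result is a stationary point of the
    Dirichlet-multinomial log-likelihood in alpha, clamped to
    [1e-6, 1e8].  With no cells (N = 0) the update is undefined and
    ``alpha_start`` is returned unchanged.
    """
    counts = np.asarray(counts_td, dtype=float)
    N = float(counts.sum())
    if N < 1:
        return float(alpha_start)
    pi = _floor_simplex(pi_prev)
    a = float(np.clip(alpha_start, ALPHA_MIN, ALPHA_MAX))
    for _ in range(max_iter):
        num = float(np.sum(pi * (digamma(counts + a * pi) - digamma(a * pi))))
        den = float(digamma(N + a) - digamma(a))
        a_new = a * num / den
        if not np.isfinite(a_new) or a_new <= 0:
            raise FloatingPointError(
                f"alpha fixed-point iterate became non-finite (alpha={a})"
            )
        a_new = float(np.clip(a_new, ALPHA_MIN, ALPHA_MAX))
        done = abs(a_new - a) / a < tol
        a = a_new
        if done:
            break
    return a


def update_pi(
    counts_td: np.ndarray, alpha_hat: float, pi_prev: np.ndarray
) -> np.ndarray:
    """Posterior mean of the mixture proportions at one (t, d).

    ``pi_l = (N_l + alpha * pi_prev_l) / (N + alpha)``; with no cells the
    previous proportions are returned unchanged.
    """
    counts = np.asarray(counts_td, dtype=float)
    pi_prev = np.asarray(pi_prev, dtype=float)
    N = counts.sum()
    if N < 1:
        return pi_prev.copy()
    return (counts + alpha_hat * pi_prev) / (N + alpha_hat)


def update_mu(y_assigned: np.ndarray, tau: float) -> np.ndarray:
    """MAP update of one cluster mean: column sums over (N_l + tau).

    An empty cluster falls back to the prior mean (the zero vector).
    """
    Y = np.atleast_2d(np.asarray(y_assigned, dtype=float))
    n = Y.shape[0]
    return Y.sum(axis=0) / (n + tau)


def update_sigma(
    y_assigned: np.ndarray,
    mu_hat: np.ndarray,
    lam: np.ndarray,
    nu: float,
    tau: float,
) -> np.ndarray:
    """MAP update of one cluster covariance.

    ``Sigma = [Lambda + sum_n (y_n - mu)(y_n - mu)' + tau * mu mu'] /
    (N_l + nu - K - 1)``.  With ``nu >= K + 2`` the denominator is >= 1
    even for an empty cluster, in which case the prior scale Lambda
    (shrunk toward the origin through the tau term) is returned.
    """
    mu_hat = np.atleast_1d(np.asarray(mu_hat, dtype=float))
    K = mu_hat.size
    Y = np.asarray(y_assigned, dtype=float).reshape(-1, K)
    n = Y.shape[0]
    denom = n + nu - K - 1
    if denom <= 0:
        raise ValueError(f"covariance denominator N_l + nu - K - 1 = {denom} <= 0")
    diff = Y - mu_hat
    scatter = diff.T @ diff
    num = np.asarray(lam, dtype=float) + scatter + tau * np.outer(mu_hat, mu_hat)
    out = num / denom
    return 0.5 * (out + out.T)


def m_step(
    X: np.ndarray,
    labels: np.ndarray,
    n_clusters: int,
    tau: float,
    lam: np.ndarray,
    nu: float,
) -> ClusterParams:
    """MAP M-step over globally pooled cells: update every mu_l, Sigma_l."""
    K = X.shape[1]
    mu = np.zeros((n_clusters, K))
    sigma = np.zeros((n_clusters, K, K))
    for l in range(n_clusters):
        Yl = X[labels == l]
        mu[l] = update_mu(Yl, tau)
        sigma[l] = update_sigma(Yl, mu[l], lam, nu, tau)
    return ClusterParams(mu=mu, sigma=sigma)
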