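"""Scikit-learn-style estimator for the time-series Gaussian mixture."""

from __future__ import annotations

from typing import Dict, Optional, Union

import numpy as np
from sklearn.base import BaseEstimator

from . import em
from .dataset import (
    BlockKey,
    ClusterParams,
    FitConfig,
    FitResult,
    Hyperparameters,
    TimeSeriesDataset,
)
from .updates import assignment_probs_block

ArrayOrDataset = Union[np.ndarray, TimeSeriesDataset]


def as_dataset(X: ArrayOrDataset) -> TimeSeriesDataset:
    """Wrap a plain cells-by-markers matrix as a single-block dataset."""
    if isinstance(X, TimeSeriesDataset):
        return X
    return TimeSeriesDataset({(1, 1): np.asarray(X, dtype=float)})


class TimeSeriesGaussianMixture(BaseEstimator):
    """Gaussian mixture with Dirichlet-chained mixture proportions.

    Cells at every (timepoint, case) share global cluster means and
    covariances; the per-(t, d) mixture proportions follow a Dirichlet
    chain ``pi_t | alpha_t, pi_{t-1} ~ Dirichlet(alpha_t * pi_{t-1})``
    whose concentration ``alpha_t`` (the *persistency parameter*) is
    estimated per timepoint — small values mark abrupt composition
    changes.  Fitting is stochastic EM: a single Gibbs draw of the cell
    labels per sweep, followed by MAP updates of the means (Gaussian
    prior, precision scale ``tau``) and covariances (Wishart prior with
    ``nu`` degrees of freedom and scale ``lambda_``).

    Parameters
    ----------
    n_clusters : int, default 3
        Number of mixture components L.
    tau : float, default 1e-5
        Precision scale of the zero-centred Gaussian prior on means.
    nu : float or None, default None
        Wishart degrees of freedom; ``None`` means ``K + 2`` (weakly
        informative, and keeps the covariance-update denominator >= 1).
    lambda_ : float, ndarray or None, default None
        Wishart scale matrix; ``None`` is the identity, a scalar ``c``
        means ``c * I``.
    alpha_init : float, default 1.0
        Starting persistency value.
    n_iter : int, default 100
        Maximum number of EM sweeps.
    burn_in : int, default 0
        Sweeps excluded from convergence monitoring.
    rel_tol : float, default 1e-6
        Relative log-likelihood change below which (sustained for 5
        sweeps) the run stops early.
    init_method : {"kmeans", "random"}, default "kmeans"
    random_state : int or None
        Seed for the k-means init, the initial draw and the Gibbs chain.

    Attributes
    ----------
    means_ : ndarray (L, K)
    covariances_ : ndarray (L, K, K)
    proportions_ : ndarray (T, D, L)
        Estimated mixture proportions per timepoint and case.
    persistency_ : ndarray (T, D)
        Estimated persistency parameters alpha.
    labels_ : dict (t, d) -> ndarray
        Final sampled cluster labels (0-based) per block.
    counts_ : ndarray (T, D, L)
    loglik_trace_ : list of float
    n_iter_ : int
        Number of completed EM sweeps.
    result_ : FitResult
        The full fit bundle.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        *,
        tau: float = 1e-5,
        nu: Optional[float] = None,
        lambda_: Union[None, float, np.ndarray] = None,
        alpha_init: float = 1.0,
        n_iter: int = 100,
        burn_in: int = 0,
        rel_tol: float = 1e-6,
        init_method: str = "kmeans",
        random_state: Optional[int] = None,
    ):
        self.n_clusters = n_clusters
        self.tau = tau
        self.nu = nu
        self.lambda_ = lambda_
        self.alpha_init = alpha_init
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.rel_tol = rel_tol
        self.init_method = init_method
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------

    def _hyper(self) -> Hyperparameters:
        return Hyperparameters(
            n_clusters=self.n_clusters,
            tau=self.tau,
            nu=self.nu,
            lam=self.lambda_,
            alpha_init=self.alpha_init,
        )

    def _config(self) -> FitConfig:
        return FitConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            rel_tol=self.rel_tol,
            seed=self.random_state,
            init_method=self.init_method,
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X: ArrayOrDataset, y=None, callback=None, log_fn=None):
        """Fit the model to a TimeSeriesDataset (or a single matrix)."""
        data = as_dataset(X)
        result = em.fit(data, self._hyper(), self._config(), callback=callback, log_fn=log_fn)
        self.result_: FitResult = result
        self.means_ = result.params.mu
        self.covariances_ = result.params.sigma
        self.proportions_ = result.trajectory.pi
        self.persistency_ = result.trajectory.alpha
        self.labels_: Dict[BlockKey, np.ndarray] = result.assignments.labels
        self.counts_ = result.assignments.counts
        self.loglik_trace_ = result.loglik_trace
        self.n_iter_ = len(result.loglik_trace)
        self.marker_names_ = data.marker_names
        self.n_features_in_ = data.K
        return self

    def _check_fitted(self) -> ClusterParams:
        if not hasattr(self, "means_"):
            raise RuntimeError("estimator is not fitted yet; call fit first")
        return self.result_.params

    def _pooled_weights(self) -> np.ndarray:
        total = self.counts_.sum()
        if total == 0:
            return np.full(self.means_.shape[0], 1.0 / self.means_.shape[0])
        return self.counts_.sum(axis=(0, 1)) / total

    def predict_proba(self, X: ArrayOrDataset):
        """Posterior cluster probabilities for new cells.

        For a dataset whose (T, D) grid matches the fitted one, each
        block uses its fitted proportions; otherwise (and for a plain
        matrix) the pooled assignment frequencies are used as weights.
        """
        params = self._check_fitted()
        if isinstance(X, TimeSeriesDataset):
            out: Dict[BlockKey, np.ndarray] = {}
            grid_matches = (X.T, X.D) == self.proportions_.shape[:2]
            for t, d, Y in X.iter_blocks():
                pi = (
                    self.proportions_[t - 1, d - 1]
                    if grid_matches
                    else self._pooled_weights()
                )
                out[(t, d)] = (
                    assignment_probs_block(Y, params, pi)
                    if Y.shape[0]
                    else np.zeros((0, params.n_clusters))
                )
            return out
        X = np.asarray(X, dtype=float)
        return assignment_probs_block(X, params, self._pooled_weights())

    def predict(self, X: ArrayOrDataset):
        """MAP cluster labels (0-based) for new cells."""
        proba = self.predict_proba(X)
        if isinstance(proba, dict):
            return {k: v.argmax(axis=1) if v.size else np.zeros(0, dtype=int) for k, v in proba.items()}
        return proba.argmax(axis=1)

    def fit_predict(self, X: ArrayOrDataset, y=None):
        self.fit(X, y)
        if isinstance(X, TimeSeriesDataset):
            return {k: v.copy() for k, v in self.labels_.items()}
        return self.labels_[(1, 1)].copy()

    def change_points(self, threshold_quantile: float = 0.25) -> em.ChangePointReport:
        """Flag timepoints whose persistency falls below the given quantile."""
        self._check_fitted()
        return em.detect_change_points(self.result_.trajectory, threshold_quantile)

    def score(self, X: ArrayOrDataset, y=None) -> float:
        """Mean per-cell log-likelihood under the fitted mixture (pooled weights)."""
        from scipy.special import logsumexp

        from ._gaussian import LOG_2PI
        from .updates import assignment_log_weights

        params = self._check_fitted()
        data = as_dataset(X)
        w = self._pooled_weights()
        total, n = 0.0, 0
        for _, _, Y in data.iter_blocks():
            if not Y.shape[0]:
                continue
            W = assignment_log_weights(Y, params, w)
            total += float(np.sum(logsumexp(W, axis=1))) - 0.5 * Y.shape[0] * data.K * LOG_2PI
            n += Y.shape[0]
        return total / max(n, 1)
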