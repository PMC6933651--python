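"""Stochastic EM driver.

One EM sweep alternates (E) a single Gibbs draw of every cell's cluster
label, traversed sequentially in time within each case so that the
Dirichlet chain propagates the freshly updated proportions, with (M) MAP
updates of the global cluster means and covariances from the pooled
assignments.  The complete-data log-likelihood is traced per sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
from sklearn.cluster import KMeans

from ._gaussian import LOG_2PI, cholesky_factor, log_kernel_block
from .dataset import (
    Assignments,
    BlockKey,
    ClusterParams,
    DataValidationError,
    FitConfig,
    FitResult,
    Hyperparameters,
    MixtureTrajectory,
    TimeSeriesDataset,
)
from .updates import (
    assignment_probs_block,
    m_step,
    sample_assignments_block,
    update_alpha,
    update_pi,
)

# Convergence requires the relative log-likelihood change to stay below
# rel_tol for this many consecutive sweeps (single sweeps fluctuate with
# the Gibbs draw).
_PATIENCE = 5


def _streams(seed: Optional[int]) -> Tuple[np.random.Generator, np.random.Generator, int]:
    """Independent init/EM random streams plus an int seed for k-means."""
    ss = np.random.SeedSequence(seed)
    init_ss, em_ss, km_ss = ss.spawn(3)
    km_seed = int(km_ss.generate_state(1)[0] % (2**31))
    return np.random.default_rng(init_ss), np.random.default_rng(em_ss), km_seed


def initialize(
    data: TimeSeriesDataset, hyper: Hyperparameters, config: FitConfig
) -> Tuple[ClusterParams, MixtureTrajectory, Assignments]:
    """Build the starting state for the EM run.

    ``kmeans``: centroids of a pooled k-means become the initial means and
    the Lambda-regularised within-cluster scatter the initial covariances.
    ``random``: L distinct cells as centers, pooled covariance for every
    cluster.  Proportions start uniform, persistency at ``alpha_init``,
    and labels are drawn once from this initial model.
    """
    hyper = hyper.resolve(data.K)
    config = FitConfig(**vars(config))  # re-validate
    L, K = hyper.n_clusters, data.K
    X = data.pooled()
    if L > X.shape[0]:
        raise DataValidationError(
            f"n_clusters={L} exceeds the total cell count {X.shape[0]}"
        )
    init_rng, _, km_seed = _streams(config.seed)

    if config.init_method == "kmeans":
        km = KMeans(n_clusters=L, n_init=10, random_state=km_seed)
        hard = km.fit_predict(X)
        mu0 = km.cluster_centers_.copy()
        sigma0 = np.empty((L, K, K))
        denom_base = hyper.nu - K - 1
        for l in range(L):
            diff = X[hard == l] - mu0[l]
            sigma0[l] = (hyper.lam + diff.T @ diff) / (diff.shape[0] + denom_base)
    else:
        idx = init_rng.choice(X.shape[0], size=L, replace=False)
        mu0 = X[idx].copy()
        diff = X - X.mean(axis=0)
        pooled = (hyper.lam + diff.T @ diff) / (X.shape[0] + hyper.nu - K - 1)
        sigma0 = np.repeat(pooled[None, :, :], L, axis=0)

    params = ClusterParams(mu=mu0, sigma=sigma0)
    trajectory = MixtureTrajectory(
        pi=np.full((data.T, data.D, L), 1.0 / L),
        alpha=np.full((data.T, data.D), hyper.alpha_init),
    )
    chols = [cholesky_factor(params.sigma[l], l) for l in range(L)]
    labels: Dict[BlockKey, np.ndarray] = {}
    for t, d, Y in data.iter_blocks():
        if Y.shape[0] == 0:
            labels[(t, d)] = np.zeros(0, dtype=int)
            continue
        eta = assignment_probs_block(Y, params, trajectory.pi[t - 1, d - 1], chols)
        labels[(t, d)] = sample_assignments_block(eta, init_rng)
    assignments = Assignments.from_labels(labels, data.T, data.D, L)
    return params, trajectory, assignments


def complete_data_loglik(
    data: TimeSeriesDataset,
    params: ClusterParams,
    trajectory: MixtureTrajectory,
    assignments: Assignments,
) -> float:
    """Joint log-probability of the observations and their sampled labels.

    Sum over every cell of the full Gaussian log-density (constant
    included) at its assigned cluster plus the log mixture proportion of
    that cluster at the cell's (t, d).
    """
    L = params.n_clusters
    chols = [cholesky_factor(params.sigma[l], l) for l in range(L)]
    total = 0.0
    with np.errstate(divide="ignore"):
        log_pi = np.log(trajectory.pi)
    for t, d, Y in data.iter_blocks():
        lab = assignments.labels[(t, d)]
        if Y.shape[0] == 0:
            continue
        if lab.size and lab.max() >= L:
            raise DataValidationError(
                f"label {lab.max()} at block {(t, d)} references a missing cluster"
            )
        for l in np.unique(lab):
            mask = lab == l
            total += float(np.sum(log_kernel_block(Y[mask], params.mu[l], chols[l])))
        total += float(np.sum(log_pi[t - 1, d - 1, lab]))
    total -= 0.5 * data.total_cells * data.K * LOG_2PI
    return total


IterCallback = Callable[[int, ClusterParams, MixtureTrajectory, Assignments, float], None]


def fit(
    data: TimeSeriesDataset,
    hyper: Hyperparameters,
    config: Optional[FitConfig] = None,
    callback: Optional[IterCallback] = None,
    log_fn: Optional[Callable[[str], None]] = None,
) -> FitResult:
    """Run the stochastic EM algorithm to completion.

    Per sweep: for each case, timepoints are visited in order; every
    cell's label is redrawn from its categorical posterior under the
    current means/covariances and that block's current proportions; the
    persistency parameter is re-estimated by fixed-point iteration against
    the freshly updated previous-timepoint proportions (anchored at
    ``pi0`` before the first timepoint) and the proportions take their
    posterior-mean update.  Then all cluster means and covariances are
    MAP-updated from the cells pooled across every (t, d).

    Stops at ``n_iter`` sweeps or once the relative change of the traced
    complete-data log-likelihood stays below ``rel_tol`` for 5 consecutive
    sweeps (checked after ``burn_in``).
    """
    if config is None:
        config = FitConfig()
    hyper = hyper.resolve(data.K)
    L = hyper.n_clusters
    params, trajectory, assignments = initialize(data, hyper, config)
    _, em_rng, _ = _streams(config.seed)

    X_pooled = data.pooled()
    pi = trajectory.pi.copy()
    alpha = trajectory.alpha.copy()
    trace: List[float] = []
    streak = 0

    for it in range(config.n_iter):
        try:
            chols = [cholesky_factor(params.sigma[l], l) for l in range(L)]
        except np.linalg.LinAlgError as exc:
            raise type(exc)(f"EM iteration {it + 1}: {exc}") from exc

        labels: Dict[BlockKey, np.ndarray] = {}
        for d in range(1, data.D + 1):
            for t in range(1, data.T + 1):
                Y = data.block(t, d)
                if Y.shape[0] == 0:
                    lab = np.zeros(0, dtype=int)
                    counts = np.zeros(L)
                else:
                    eta = assignment_probs_block(Y, params, pi[t - 1, d - 1], chols)
                    lab = sample_assignments_block(eta, em_rng)
                    counts = np.bincount(lab, minlength=L).astype(float)
                labels[(t, d)] = lab
                pi_prev = hyper.pi0 if t == 1 else pi[t - 2, d - 1]
                alpha[t - 1, d - 1] = update_alpha(
                    counts, pi_prev, alpha_start=alpha[t - 1, d - 1]
                )
                pi[t - 1, d - 1] = update_pi(counts, alpha[t - 1, d - 1], pi_prev)

        assignments = Assignments.from_labels(labels, data.T, data.D, L)
        pooled_labels = np.concatenate(
            [labels[(t, d)] for d in range(1, data.D + 1) for t in range(1, data.T + 1)]
        )
        params = m_step(X_pooled, pooled_labels, L, hyper.tau, hyper.lam, hyper.nu)
        trajectory = MixtureTrajectory(pi=pi.copy(), alpha=alpha.copy())

        ll = complete_data_loglik(data, params, trajectory, assignments)
        trace.append(ll)
        if log_fn is not None:
            mean_alpha = " ".join(f"{a:.3g}" for a in alpha.mean(axis=0))
            log_fn(f"iter={it + 1} loglik={ll:.4f} mean_alpha_per_case=[{mean_alpha}]")
        if callback is not None:
            callback(it, params, trajectory, assignments, ll)

        if it >= max(config.burn_in, 1):
            rel = abs(trace[-1] - trace[-2]) / max(abs(trace[-2]), 1e-300)
            streak = streak + 1 if rel < config.rel_tol else 0
            if streak >= _PATIENCE:
                break

    return FitResult(
        params=params,
        trajectory=trajectory,
        assignments=assignments,
        loglik_trace=trace,
        hyper=hyper,
        config=config,
    )


@dataclass
class ChangePointReport:
    """Flagged change-point timepoints per case, plus the raw alpha table.

    ``flagged[d-1]`` lists 1-based timepoints whose persistency parameter
    falls strictly below the requested quantile of that case's values.
    The first timepoint is excluded: its alpha measures divergence from
    the uniform anchor, not a real transition.  ``alpha`` is the full
    (T, D) table so users can apply their own rule.
    """

    flagged: List[List[int]]
    alpha: np.ndarray
    threshold_quantile: float


def detect_change_points(
    trajectory: MixtureTrajectory, threshold_quantile: float = 0.25
) -> ChangePointReport:
    """Flag timepoints with relatively small persistency parameters."""
    if not (0.0 < threshold_quantile < 1.0):
        raise ValueError("threshold_quantile must lie in (0, 1)")
    alpha = np.asarray(trajectory.alpha, dtype=float)
    T, D = alpha.shape
    if T < 2:
        raise DataValidationError("change-point detection needs at least 2 timepoints")
    flagged: List[List[int]] = []
    for d in range(D):
        vals = alpha[1:, d]
        thr = float(np.quantile(vals, threshold_quantile))
        flagged.append([t + 2 for t in range(T - 1) if vals[t] < thr])
    return ChangePointReport(
        flagged=flagged, alpha=alpha.copy(), threshold_quantile=threshold_quantile
    )
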