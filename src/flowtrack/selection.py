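"""Cluster-number selection and simulation-evaluation statistics.

Two sums of squared errors are used: within-cluster SSE of cells about
their estimated cluster means (the elbow statistic) and the squared error
between estimated and true mixture-proportion trajectories (the
simulation benchmark statistic).  Cluster labels of independent fits are
aligned by optimal assignment on mean distances.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import clone
from sklearn.mixture import GaussianMixture

from .dataset import Assignments, ClusterParams, MixtureTrajectory, TimeSeriesDataset
from .mixture import TimeSeriesGaussianMixture


def compute_cluster_sse(
    data: TimeSeriesDataset, assignments: Assignments, params: ClusterParams
) -> float:
    """Within-cluster sum of squared Euclidean distances, pooled over (t, d)."""
    total = 0.0
    for t, d, Y in data.iter_blocks():
        lab = assignments.labels[(t, d)]
        if Y.shape[0] == 0:
            continue
        diff = Y - params.mu[lab]
        total += float(np.sum(diff * diff))
    return total


def match_clusters(mu_est: np.ndarray, mu_true: np.ndarray) -> np.ndarray:
    """Permutation sigma with sigma[l] = estimated cluster matched to true l.

    Minimises the total squared distance between matched means (optimal
    assignment, Hungarian algorithm).
    """
    mu_est = np.asarray(mu_est, dtype=float)
    mu_true = np.asarray(mu_true, dtype=float)
    if mu_est.shape != mu_true.shape:
        raise ValueError("mean matrices must have equal shapes")
    diff = mu_est[:, None, :] - mu_true[None, :, :]
    cost = np.einsum("ijk,ijk->ij", diff, diff)  # cost[i, j] = ||est_i - true_j||^2
    row, col = linear_sum_assignment(cost)
    perm = np.empty(mu_true.shape[0], dtype=int)
    perm[col] = row
    return perm


def compute_pi_sse(
    estimated: Union[MixtureTrajectory, np.ndarray],
    truth: np.ndarray,
    cluster_matching: Optional[np.ndarray] = None,
) -> float:
    """Squared error between matched estimated and true proportion trajectories.

    ``cluster_matching[l]`` gives the estimated cluster index aligned with
    true cluster ``l`` (identity if omitted).
    """
    pi_est = estimated.pi if isinstance(estimated, MixtureTrajectory) else np.asarray(estimated, float)
    truth = np.asarray(truth, dtype=float)
    L = truth.shape[-1]
    if cluster_matching is None:
        cluster_matching = np.arange(L)
    perm = np.asarray(cluster_matching, dtype=int)
    if sorted(perm.tolist()) != list(range(L)):
        raise ValueError("cluster_matching must be a permutation of 0..L-1")
    if pi_est.shape != truth.shape:
        raise ValueError("estimated and true trajectories must share a shape")
    diff = pi_est[..., perm] - truth
    return float(np.sum(diff * diff))


def elbow_scan(
    data: TimeSeriesDataset,
    l_candidates: Sequence[int],
    base_estimator: Optional[TimeSeriesGaussianMixture] = None,
    random_state: Optional[int] = None,
) -> pd.DataFrame:
    """Fit the model at each candidate L and report the within-cluster SSE.

    No automatic elbow is picked: cell populations form near-continuous
    phenotypes, so the choice of L is left to the user's inspection of
    the returned (L, sse) table.  Each candidate gets a fresh
    seed-derived random stream.
    """
    if any(L < 1 for L in l_candidates):
        raise ValueError("all candidate cluster numbers must be >= 1")
    base = base_estimator if base_estimator is not None else TimeSeriesGaussianMixture()
    seeds = np.random.SeedSequence(random_state).spawn(len(l_candidates))
    rows = []
    for L, ss in zip(l_candidates, seeds):
        est = clone(base)
        est.set_params(n_clusters=int(L), random_state=int(ss.generate_state(1)[0] % (2**31)))
        try:
            est.fit(data)
        except Exception as exc:
            raise RuntimeError(f"fit failed for candidate L={L}: {exc}") from exc
        sse = compute_cluster_sse(data, est.result_.assignments, est.result_.params)
        rows.append({"L": int(L), "sse": sse})
    return pd.DataFrame(rows, columns=["L", "sse"])


def pooled_gmm_proportions(
    data: TimeSeriesDataset, n_clusters: int, random_state: Optional[int] = None
):
    """Temporally-uncoupled baseline: one Gaussian mixture on pooled cells.

    Fits an ordinary GMM to all cells pooled across (t, d) and derives
    per-(t, d) mixture proportions from the empirical frequencies of its
    MAP labels.  Returns (means (L, K), proportions (T, D, L)).
    """
    X = data.pooled()
    gmm = GaussianMixture(
        n_components=n_clusters, covariance_type="full", random_state=random_state
    ).fit(X)
    pi = np.zeros((data.T, data.D, n_clusters))
    for t, d, Y in data.iter_blocks():
        if Y.shape[0] == 0:
            continue
        lab = gmm.predict(Y)
        pi[t - 1, d - 1] = np.bincount(lab, minlength=n_clusters) / Y.shape[0]
    return gmm.means_, pi
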