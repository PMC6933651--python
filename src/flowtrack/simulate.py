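"""Synthetic time-series cytometry data drawn from the generative model.

Cells are Gaussian draws around cluster means that are shared across all
timepoints and cases; per-(t, d) cluster frequencies follow a designed
schedule with abrupt shifts at chosen timepoints, emulating a benchmark
design of K=10 markers, T=5 timepoints, D=2 cases and 1000 cells per
block with change-points at t=3,5 (case 1) and t=2,4 (case 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .dataset import BlockKey, DataValidationError, TimeSeriesDataset

_MIN_SEPARATION = 2.0  # enforced pairwise distance between true cluster means
_MAX_TRIES = 1000


@dataclass
class SimulationConfig:
    """Design of one synthetic experiment.

    ``pi_schedule`` has shape (T, D, L); each (t, d) slice is the true
    mixture-proportion simplex.  ``mu_scale`` is the half-width of the
    uniform box the true cluster means are drawn from.
    """

    n_markers: int = 10
    n_timepoints: int = 5
    n_cases: int = 2
    n_clusters: int = 3
    n_per_block: int = 1000
    pi_schedule: Optional[np.ndarray] = None
    mu_scale: float = 5.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_per_block < 1:
            raise DataValidationError("n_per_block must be >= 1")
        if self.pi_schedule is None:
            self.pi_schedule = np.full(
                (self.n_timepoints, self.n_cases, self.n_clusters),
                1.0 / self.n_clusters,
            )
        self.pi_schedule = np.asarray(self.pi_schedule, dtype=float)
        expect = (self.n_timepoints, self.n_cases, self.n_clusters)
        if self.pi_schedule.shape != expect:
            raise DataValidationError(
                f"pi_schedule must have shape {expect}, got {self.pi_schedule.shape}"
            )
        sums = self.pi_schedule.sum(axis=2)
        if np.any(self.pi_schedule < 0) or np.max(np.abs(sums - 1.0)) > 1e-8:
            raise DataValidationError("each pi_schedule[t, d] must lie on the simplex")

    def change_points(self) -> List[List[int]]:
        """Designed change timepoints (1-based, t >= 2) per case."""
        out: List[List[int]] = []
        for d in range(self.n_cases):
            cps = [
                t + 2
                for t in range(self.n_timepoints - 1)
                if np.max(np.abs(self.pi_schedule[t + 1, d] - self.pi_schedule[t, d]))
                > 1e-12
            ]
            out.append(cps)
        return out


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated dataset."""

    mu: np.ndarray                       # (L, K)
    sigma: np.ndarray                    # (L, K, K)
    pi: np.ndarray                       # (T, D, L)
    labels: Dict[BlockKey, np.ndarray]   # 0-based per block
    change_points: List[List[int]] = field(default_factory=list)


def default_simulation_config(seed: Optional[int] = None) -> SimulationConfig:
    """The benchmark design: K=10, T=5, D=2, L=3, 1000 cells per block.

    The proportion schedule is piecewise constant with total-variation
    shifts of 0.35-0.40 exactly at t=3 and t=5 for case 1 and at t=2 and
    t=4 for case 2.
    """
    case1 = [
        [0.60, 0.30, 0.10],
        [0.60, 0.30, 0.10],
        [0.20, 0.50, 0.30],  # change at t=3
        [0.20, 0.50, 0.30],
        [0.50, 0.10, 0.40],  # change at t=5
    ]
    case2 = [
        [0.10, 0.60, 0.30],
        [0.50, 0.20, 0.30],  # change at t=2
        [0.50, 0.20, 0.30],
        [0.15, 0.25, 0.60],  # change at t=4
        [0.15, 0.25, 0.60],
    ]
    schedule = np.stack([np.array(case1), np.array(case2)], axis=1)
    return SimulationConfig(
        n_markers=10,
        n_timepoints=5,
        n_cases=2,
        n_clusters=3,
        n_per_block=1000,
        pi_schedule=schedule,
        mu_scale=5.0,
        seed=seed,
    )


def _draw_means(rng: np.random.Generator, L: int, K: int, scale: float) -> np.ndarray:
    for _ in range(_MAX_TRIES):
        mu = rng.uniform(-scale, scale, size=(L, K))
        if L == 1:
            return mu
        dists = np.linalg.norm(mu[:, None, :] - mu[None, :, :], axis=2)
        if dists[np.triu_indices(L, k=1)].min() >= _MIN_SEPARATION:
            return mu
    raise DataValidationError(
        f"could not draw {L} cluster means with pairwise separation >= "
        f"{_MIN_SEPARATION} in {_MAX_TRIES} tries; increase mu_scale"
    )


def _draw_covariances(rng: np.random.Generator, L: int, K: int) -> np.ndarray:
    sigma = np.empty((L, K, K))
    for l in range(L):
        Q, _ = np.linalg.qr(rng.standard_normal((K, K)))
        ev = rng.uniform(0.5, 2.0, size=K)
        S = (Q * ev) @ Q.T
        sigma[l] = 0.5 * (S + S.T)
    return sigma


def simulate_dataset(config: SimulationConfig):
    """Draw one dataset plus its ground truth.

    Returns (TimeSeriesDataset, SimulationTruth).  Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    L, K = config.n_clusters, config.n_markers
    mu = _draw_means(rng, L, K, config.mu_scale)
    sigma = _draw_covariances(rng, L, K)
    chols = np.linalg.cholesky(sigma)

    blocks: Dict[BlockKey, np.ndarray] = {}
    labels: Dict[BlockKey, np.ndarray] = {}
    for d in range(1, config.n_cases + 1):
        for t in range(1, config.n_timepoints + 1):
            p = config.pi_schedule[t - 1, d - 1]
            lab = rng.choice(L, size=config.n_per_block, p=p)
            noise = rng.standard_normal((config.n_per_block, K))
            cells = mu[lab] + np.einsum("nij,nj->ni", chols[lab], noise)
            blocks[(t, d)] = cells
            labels[(t, d)] = lab

    data = TimeSeriesDataset(
        blocks,
        marker_names=[f"marker_{j + 1}" for j in range(K)],
        n_timepoints=config.n_timepoints,
        n_cases=config.n_cases,
    )
    truth = SimulationTruth(
        mu=mu,
        sigma=sigma,
        pi=config.pi_schedule.copy(),
        labels=labels,
        change_points=config.change_points(),
    )
    return data, truth
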