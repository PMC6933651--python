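"""Containers for time-series flow cytometry data and fitted model state.

A dataset is a collection of cells-by-markers expression matrices, one per
(timepoint, case) pair.  A *case* is a study subject (a culture, mouse or
patient) measured repeatedly over time; a *timepoint* is an ordinal index
1..T.  All containers validate their own invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np


class DataValidationError(ValueError):
    """Raised when an input matrix or parameter set violates its invariants."""


BlockKey = Tuple[int, int]  # (timepoint, case), both 1-based


class TimeSeriesDataset:
    """Marker-expression matrices organised by (timepoint, case).

    Parameters
    ----------
    blocks : mapping of (t, d) -> ndarray of shape (N_td, K)
        Cell-by-marker intensity matrices.  ``t`` and ``d`` are 1-based.
        Missing (t, d) combinations become empty blocks.
    marker_names : sequence of str, optional
        Column names; defaults to ``marker_1 .. marker_K``.
    n_timepoints, n_cases : int, optional
        Override the grid extent (defaults to the maximum observed index).
    """

    def __init__(
        self,
        blocks: Mapping[BlockKey, np.ndarray],
        marker_names: Optional[Sequence[str]] = None,
        n_timepoints: Optional[int] = None,
        n_cases: Optional[int] = None,
    ):
        if not blocks:
            raise DataValidationError("dataset needs at least one (timepoint, case) block")
        coerced: Dict[BlockKey, np.ndarray] = {}
        K = None
        for key, mat in blocks.items():
            t, d = int(key[0]), int(key[1])
            if t < 1 or d < 1:
                raise DataValidationError(f"timepoint/case indices are 1-based, got {key}")
            arr = np.asarray(mat, dtype=float)
            if arr.ndim == 1:
                arr = arr.reshape(-1, 1) if arr.size else arr.reshape(0, 1)
            if arr.ndim != 2:
                raise DataValidationError(f"block {key} must be 2-D, got ndim={arr.ndim}")
            if K is None:
                K = arr.shape[1]
            elif arr.shape[1] != K:
                raise DataValidationError(
                    f"block {key} has {arr.shape[1]} markers, expected {K}"
                )
            if not np.all(np.isfinite(arr)):
                raise DataValidationError(f"block {key} contains non-finite values")
            coerced[(t, d)] = arr
        assert K is not None
        if K < 1:
            raise DataValidationError("need at least one marker column")
        if not any(v.shape[0] > 0 for v in coerced.values()):
            raise DataValidationError("all blocks are empty")

        T = int(n_timepoints) if n_timepoints else max(t for t, _ in coerced)
        D = int(n_cases) if n_cases else max(d for _, d in coerced)
        if any(t > T or d > D for t, d in coerced):
            raise DataValidationError("block index exceeds declared grid extent")
        empty = np.zeros((0, K))
        self.blocks: Dict[BlockKey, np.ndarray] = {
            (t, d): coerced.get((t, d), empty)
            for t in range(1, T + 1)
            for d in range(1, D + 1)
        }
        if marker_names is None:
            marker_names = [f"marker_{j + 1}" for j in range(K)]
        if len(marker_names) != K:
            raise DataValidationError(
                f"{len(marker_names)} marker names for {K} marker columns"
            )
        self.marker_names: List[str] = [str(m) for m in marker_names]
        self.T = T
        self.D = D
        self.K = K

    def block(self, t: int, d: int) -> np.ndarray:
        return self.blocks[(t, d)]

    def n_cells(self, t: int, d: int) -> int:
        return self.blocks[(t, d)].shape[0]

    @property
    def total_cells(self) -> int:
        return sum(v.shape[0] for v in self.blocks.values())

    def iter_blocks(self) -> Iterator[Tuple[int, int, np.ndarray]]:
        """Yield (t, d, matrix) in case-major, time-ordered traversal order."""
        for d in range(1, self.D + 1):
            for t in range(1, self.T + 1):
                yield t, d, self.blocks[(t, d)]

    def pooled(self) -> np.ndarray:
        """All cells stacked into one (total_cells, K) matrix (traversal order)."""
        return np.vstack([m for _, _, m in self.iter_blocks()])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TimeSeriesDataset(T={self.T}, D={self.D}, K={self.K}, "
            f"cells={self.total_cells})"
        )


def _check_spd(mat: np.ndarray, what: str) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise DataValidationError(f"{what} must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise DataValidationError(f"{what} must be symmetric")
    if np.linalg.eigvalsh(mat)[0] <= 0:
        raise DataValidationError(f"{what} must be positive definite")


@dataclass
class Hyperparameters:
    """Prior hyperparameters of the time-series Gaussian mixture.

    ``tau`` scales the zero-centred Gaussian prior precision on cluster
    means; ``nu`` and ``lam`` parameterise the Wishart prior on cluster
    precisions.  ``nu >= K + 2`` guarantees the covariance MAP denominator
    ``N_l + nu - K - 1`` stays >= 1 even for an empty cluster.  ``pi0`` is the
    mixture-proportion anchor for the step into the first timepoint and
    ``alpha_init`` the starting persistency value.
    """

    n_clusters: int
    tau: float = 1e-5
    nu: Optional[float] = None
    lam: Optional[np.ndarray] = None
    alpha_init: float = 1.0
    pi0: Optional[np.ndarray] = None

    def resolve(self, n_markers: int) -> "Hyperparameters":
        """Return a fully-concrete copy for a K-marker dataset, validated."""
        L = int(self.n_clusters)
        K = int(n_markers)
        if L < 1:
            raise DataValidationError("n_clusters must be >= 1")
        if not self.tau > 0:
            raise DataValidationError("tau must be > 0")
        nu = float(K + 2 if self.nu is None else self.nu)
        if nu < K + 2:
            raise DataValidationError(f"nu must be >= K + 2 = {K + 2}, got {nu}")
        if self.lam is None:
            lam = np.eye(K)
        elif np.isscalar(self.lam):
            if not float(self.lam) > 0:  # type: ignore[arg-type]
                raise DataValidationError("scalar Lambda must be > 0")
            lam = float(self.lam) * np.eye(K)  # type: ignore[arg-type]
        else:
            lam = np.asarray(self.lam, dtype=float)
            _check_spd(lam, "Lambda")
            if lam.shape != (K, K):
                raise DataValidationError(f"Lambda must be {K}x{K}, got {lam.shape}")
        if not self.alpha_init > 0:
            raise DataValidationError("alpha_init must be > 0")
        if self.pi0 is None:
            pi0 = np.full(L, 1.0 / L)
        else:
            pi0 = np.asarray(self.pi0, dtype=float)
            if pi0.shape != (L,) or np.any(pi0 <= 0) or abs(pi0.sum() - 1.0) > 1e-8:
                raise DataValidationError("pi0 must be a strictly positive length-L simplex vector")
        return Hyperparameters(
            n_clusters=L, tau=float(self.tau), nu=nu, lam=lam,
            alpha_init=float(self.alpha_init), pi0=pi0,
        )


@dataclass
class ClusterParams:
    """Global cluster means and covariances, shared across all (t, d)."""

    mu: np.ndarray     # (L, K)
    sigma: np.ndarray  # (L, K, K)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.ndim != 2:
            raise DataValidationError("mu must have shape (L, K)")
        L, K = self.mu.shape
        if self.sigma.shape != (L, K, K):
            raise DataValidationError(
                f"sigma must have shape {(L, K, K)}, got {self.sigma.shape}"
            )

    @property
    def n_clusters(self) -> int:
        return self.mu.shape[0]

    @property
    def n_markers(self) -> int:
        return self.mu.shape[1]

    def validate(self) -> None:
        for l in range(self.n_clusters):
            _check_spd(self.sigma[l], f"Sigma[{l + 1}]")


@dataclass
class MixtureTrajectory:
    """Per-(t, d) mixture proportions and persistency parameters.

    ``pi[t-1, d-1, l]`` is the fraction of cells in cluster ``l+1`` at
    timepoint ``t`` for case ``d``; ``alpha[t-1, d-1]`` is the Dirichlet
    concentration tying that proportion vector to the previous timepoint's
    (small alpha = abrupt change).
    """

    pi: np.ndarray     # (T, D, L)
    alpha: np.ndarray  # (T, D)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.pi.ndim != 3:
            raise DataValidationError("pi must have shape (T, D, L)")
        if self.alpha.shape != self.pi.shape[:2]:
            raise DataValidationError("alpha must have shape (T, D)")

    def validate(self) -> None:
        if np.any(self.pi < 0):
            raise DataValidationError("mixture proportions must be >= 0")
        sums = self.pi.sum(axis=2)
        if np.max(np.abs(sums - 1.0)) > 1e-10:
            raise DataValidationError("each pi[t, d] must sum to 1 within 1e-10")
        if np.any(~(self.alpha > 0)):
            raise DataValidationError("all persistency parameters must be > 0")


@dataclass
class Assignments:
    """Sampled cluster labels per cell (0-based internally) with their counts."""

    labels: Dict[BlockKey, np.ndarray]
    counts: np.ndarray  # (T, D, L), integer

    @classmethod
    def from_labels(
        cls, labels: Mapping[BlockKey, np.ndarray], T: int, D: int, L: int
    ) -> "Assignments":
        counts = np.zeros((T, D, L), dtype=int)
        out: Dict[BlockKey, np.ndarray] = {}
        for (t, d), lab in labels.items():
            lab = np.asarray(lab, dtype=int)
            if lab.size and (lab.min() < 0 or lab.max() >= L):
                raise DataValidationError(f"labels for block {(t, d)} outside 0..{L - 1}")
            out[(t, d)] = lab
            counts[t - 1, d - 1] = np.bincount(lab, minlength=L)
        return cls(labels=out, counts=counts)

    def validate(self) -> None:
        for (t, d), lab in self.labels.items():
            got = np.bincount(lab, minlength=self.counts.shape[2])
            if not np.array_equal(got, self.counts[t - 1, d - 1]):
                raise DataValidationError(f"counts inconsistent with labels at {(t, d)}")


@dataclass
class FitConfig:
    """Run-control knobs for the stochastic EM fit."""

    n_iter: int = 100
    burn_in: int = 0
    rel_tol: float = 1e-6
    seed: Optional[int] = None
    init_method: str = "kmeans"

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise DataValidationError("n_iter must be >= 1")
        if not (0 <= self.burn_in < self.n_iter):
            raise DataValidationError("need 0 <= burn_in < n_iter")
        if not self.rel_tol > 0:
            raise DataValidationError("rel_tol must be > 0")
        if self.init_method not in ("kmeans", "random"):
            raise DataValidationError("init_method must be 'kmeans' or 'random'")


@dataclass
class FitResult:
    """Everything the stochastic EM run produced."""

    params: ClusterParams
    trajectory: MixtureTrajectory
    assignments: Assignments
    loglik_trace: List[float] = field(default_factory=list)
    hyper: Optional[Hyperparameters] = None
    config: Optional[FitConfig] = None
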