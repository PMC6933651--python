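import numpy as np
import pytest

from flowtrack import SimulationConfig, TimeSeriesDataset, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, k, scale=1.0):
    """Random symmetric positive-definite matrix of size k."""
    Q, _ = np.linalg.qr(rng.standard_normal((k, k)))
    ev = rng.uniform(0.3, 3.0, size=k) * scale
    S = (Q * ev) @ Q.T
    return 0.5 * (S + S.T)


@pytest.fixture
def tiny_dataset(rng):
    """Small 2-marker dataset: T=2, D=1, two loose Gaussian blobs."""
    blocks = {
        (1, 1): rng.standard_normal((60, 2)) + np.array([0.0, 0.0]),
        (2, 1): rng.standard_normal((50, 2)) + np.array([6.0, 6.0]),
    }
    return TimeSeriesDataset(blocks)


def blob_dataset(seed=0, n_per_block=400, n_timepoints=1, n_cases=1, n_clusters=3, n_markers=5):
    """Well-separated Gaussian blobs drawn through the simulator.

    With 5 markers and a half-width of 6 the random means sit ~10+ units
    apart while per-axis noise scales are at most sqrt(2).
    """
    cfg = SimulationConfig(
        n_markers=n_markers,
        n_timepoints=n_timepoints,
        n_cases=n_cases,
        n_clusters=n_clusters,
        n_per_block=n_per_block,
        mu_scale=6.0,
        seed=seed,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def blobs3():
    return blob_dataset(seed=7, n_per_block=1000)
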