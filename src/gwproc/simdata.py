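"""Synthetic data with known ground-truth covariance processes.

Two generators mirror the study conditions used throughout the package:

1. ``simulate_wishart_prior`` -- covariance processes drawn from the Wishart
   process prior itself (RBF kernel, lengthscale 0.35, identity scale matrix,
   d=3, v=4, n=300, ten datasets): the well-specified case used to check
   parameter recovery.
2. ``simulate_state_switching`` -- a rapid state-switching process in which
   all off-diagonal covariances alternate between 0 and 0.8 every 50
   observations while variances stay at 1 (n=600, first 300 for training,
   last 300 held out).  The switching pattern is periodic but not itself a
   Wishart-process draw, making it a misspecified test case.

Input ranges: the first design places inputs evenly on [0, 1]; the second on
[0, 2), so that a full on/off cycle of 100 observations spans 1/3 input
units (the period a periodic kernel should recover).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSpec, gram_cholesky
from .model import construct_sigma

__all__ = [
    "SimulationBundle",
    "simulate_wishart_prior",
    "simulate_state_switching",
    "train_test_split",
]


@dataclass
class SimulationBundle:
    """A simulated dataset: grid, ground-truth covariance process, observations."""

    x: np.ndarray  # (n,)
    truth: np.ndarray  # (n, d, d)
    Y: np.ndarray  # (n, d)
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def d(self) -> int:
        return self.Y.shape[1]


def _draw_observations(truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One MVN(0, truth[i]) row per input."""
    chol = np.linalg.cholesky(truth)
    eps = rng.standard_normal(truth.shape[:2])
    return np.einsum("iab,ib->ia", chol, eps)


def simulate_wishart_prior(
    seed: int,
    n: int = 300,
    d: int = 3,
    v: int = 4,
    lengthscale: float = 0.35,
    V: np.ndarray | None = None,
    n_datasets: int = 10,
    x_max: float = 1.0,
) -> list[SimulationBundle]:
    """Datasets whose truth is itself a Wishart-process prior draw.

    The lengthscale and scale matrix are held fixed across datasets; only the
    latent GP draws (and hence the covariance processes) and observation
    noise differ.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, x_max, n)
    kernel = KernelSpec("rbf", {"lengthscale": lengthscale})
    chol_K, _ = gram_cholesky(kernel, x)
    L = np.eye(d) if V is None else np.linalg.cholesky(np.asarray(V, dtype=float))
    bundles = []
    for idx in range(n_datasets):
        white = rng.standard_normal((d, v, n))
        F = np.einsum("nm,dvm->dvn", chol_K, white)
        truth = construct_sigma(F, L)
        Y = _draw_observations(truth + 1e-10 * np.eye(d), rng)
        meta = {
            "design": "wishart-prior",
            "seed": seed,
            "dataset_index": idx,
            "n": n,
            "d": d,
            "v": v,
            "lengthscale": lengthscale,
            "x_max": x_max,
        }
        bundles.append(SimulationBundle(x.copy(), truth, Y, meta))
    return bundles


def state_switching_truth(
    n: int, block: int, rho: float, d: int, first_block_correlated: bool = False
) -> np.ndarray:
    """The alternating equicorrelation covariance process, shape (n, d, d).

    Unit variances; all off-diagonals equal 0 in even blocks and ``rho`` in
    odd blocks (or the reverse).  Positive definiteness of the correlated
    slice requires ``-1/(d-1) < rho < 1``.
    """
    if n % block != 0:
        raise ValueError("block must divide n")
    if d > 1 and not (-1.0 / (d - 1) < rho < 1.0):
        raise ValueError(f"rho={rho} gives a non-PD equicorrelation matrix for d={d}")
    blocks = (np.arange(n) // block) % 2
    on = blocks == (0 if first_block_correlated else 1)
    truth = np.tile(np.eye(d), (n, 1, 1))
    off = np.full((d, d), rho) - rho * np.eye(d)
    truth[on] += off
    return truth


def simulate_state_switching(
    seed: int,
    n: int = 600,
    block: int = 50,
    rho: float = 0.8,
    d: int = 3,
    x_range: float | None = None,
    first_block_correlated: bool = False,
) -> SimulationBundle:
    """One dataset from the alternating 0/``rho`` covariance process.

    The grid is evenly spaced on ``[0, x_range)``; by default ``x_range``
    scales with ``n`` so that one full switching cycle (``2 * block``
    observations) always spans ``1/3`` input units.
    """
    if x_range is None:
        x_range = n / (6.0 * block)
    rng = np.random.default_rng(seed)
    x = np.arange(n) * (x_range / n)
    truth = state_switching_truth(n, block, rho, d, first_block_correlated)
    Y = _draw_observations(truth, rng)
    meta = {
        "design": "state-switching",
        "seed": seed,
        "n": n,
        "block": block,
        "rho": rho,
        "d": d,
        "x_range": x_range,
        "first_block_correlated": first_block_correlated,
        "period": 2 * block * x_range / n,
    }
    return SimulationBundle(x, truth, Y, meta)


def train_test_split(
    bundle: SimulationBundle, n_train: int = 300
) -> tuple[SimulationBundle, SimulationBundle]:
    """Contiguous prefix/suffix split of a bundle."""
    if not 0 <= n_train <= bundle.n:
        raise ValueError("n_train out of range")
    meta_train = {**bundle.meta, "split": "train", "n_train": n_train}
    meta_test = {**bundle.meta, "split": "test", "n_train": n_train}
    train = SimulationBundle(
        bundle.x[:n_train], bundle.truth[:n_train], bundle.Y[:n_train], meta_train
    )
    test = SimulationBundle(
        bundle.x[n_train:], bundle.truth[n_train:], bundle.Y[n_train:], meta_test
    )
    return train, test
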