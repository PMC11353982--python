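"""Evaluation metrics and the HDI+ROPE test for dynamic covariance.

Error metrics compare estimated covariance processes against a known truth
(mean estimate and full posterior), predictive fit is measured by an
observation-averaged Gaussian log-likelihood and by a per-input KL divergence
between predicted and true Gaussians.

``dynamics_test`` labels a covariance pair as *uncorrelated*, *static* (S) or
*dynamic* (D) from posterior samples of :math:`\\Sigma_{ij}(x)`: the 95%
highest-density interval at every input is widened by a region of practical
equivalence (ROPE, default 0.005); if zero lies in every widened interval the
pair is uncorrelated, else if some constant does it is static, else dynamic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import log_likelihood

__all__ = [
    "MetricReport",
    "mse_sigma",
    "mse_samples",
    "avg_loglik",
    "kl_mvn",
    "predictive_kl",
    "hdi",
    "dynamics_test",
]


@dataclass
class MetricReport:
    """The four headline metrics with their averaging conventions."""

    mse_sigma: float
    mse_samples: float
    avg_loglik: float
    kl: float
    conventions: dict | None = None

    def to_dict(self) -> dict:
        return {
            "mse_sigma": self.mse_sigma,
            "mse_samples": self.mse_samples,
            "avg_loglik": self.avg_loglik,
            "kl": self.kl,
            "conventions": self.conventions or {},
        }


def _unique_entry_mask(d: int) -> np.ndarray:
    """Boolean (d, d) mask of the upper triangle including the diagonal."""
    return np.triu(np.ones((d, d), dtype=bool))


def mse_sigma(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared error between two covariance processes.

    Averaged over inputs and over the ``d (d + 1) / 2`` unique entries of
    each symmetric slice (upper triangle plus diagonal), so symmetric
    off-diagonal entries are not double counted.
    """
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError("estimate and truth must have equal shapes")
    mask = _unique_entry_mask(truth.shape[-1])
    diff = (estimate - truth)[:, mask]
    return float(np.mean(diff**2))


def mse_samples(samples: np.ndarray, truth: np.ndarray) -> float:
    """Mean over posterior samples of ``mse_sigma(sample, truth)``.

    ``samples`` has shape ``(S, n, d, d)``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 4 or samples.shape[0] == 0:
        raise ValueError("samples must be a nonempty (S, n, d, d) array")
    return float(np.mean([mse_sigma(s, truth) for s in samples]))


def avg_loglik(
    Y: np.ndarray, Sigma_mean: np.ndarray, mean: np.ndarray | None = None
) -> float:
    """Observation log-likelihood under the mean covariance estimate, per row."""
    Y = np.asarray(Y, dtype=float)
    return log_likelihood(Y, Sigma_mean, mean=mean) / Y.shape[0]


def kl_mvn(Sigma_a: np.ndarray, Sigma_b: np.ndarray) -> float:
    """KL divergence between zero-mean Gaussians, ``KL(N(0, a) || N(0, b))``.

    ``0.5 (tr(b^-1 a) - d + log det b - log det a)``; nonnegative.
    """
    Sigma_a = np.asarray(Sigma_a, dtype=float)
    Sigma_b = np.asarray(Sigma_b, dtype=float)
    d = Sigma_a.shape[0]
    sign_b, logdet_b = np.linalg.slogdet(Sigma_b)
    sign_a, logdet_a = np.linalg.slogdet(Sigma_a)
    if sign_b <= 0:
        raise np.linalg.LinAlgError("Sigma_b must be positive definite")
    tr = np.trace(np.linalg.solve(Sigma_b, Sigma_a))
    return float(0.5 * (tr - d + logdet_b - logdet_a))


def predictive_kl(
    samples: np.ndarray, truth: np.ndarray, moment_match: bool = False
) -> float:
    """KL between predicted and true per-input Gaussians, averaged.

    Default: the mean over posterior samples and inputs of
    ``kl_mvn(Sigma_sample(x), Sigma_true(x))``.  With ``moment_match=True``
    the sample mixture is first collapsed to its mean covariance per input
    (single-Gaussian approximation) before taking the KL.
    """
    samples = np.asarray(samples, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if samples.ndim == 3:
        samples = samples[None]
    if moment_match:
        mean_sig = samples.mean(axis=0)
        return float(
            np.mean([kl_mvn(mean_sig[i], truth[i]) for i in range(truth.shape[0])])
        )
    vals = [
        kl_mvn(samples[s, i], truth[i])
        for s in range(samples.shape[0])
        for i in range(truth.shape[0])
    ]
    return float(np.mean(vals))


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * m)`` sorted samples."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    samples = np.sort(np.asarray(samples, dtype=float).ravel())
    m = samples.size
    if m < 2:
        raise ValueError("need at least 2 samples")
    keep = int(np.ceil(mass * m))
    widths = samples[keep - 1 :] - samples[: m - keep + 1]
    start = int(np.argmin(widths))
    return float(samples[start]), float(samples[start + keep - 1])


def dynamics_test(
    samples: np.ndarray, mass: float = 0.95, rope: float = 0.005
) -> str:
    """Classify a covariance pair as 'uncorrelated', 'static', or 'dynamic'.

    ``samples`` has shape ``(S, n)``: posterior draws of one covariance entry
    at every input.  Each per-input HDI is widened by ``rope`` on both sides;
    zero in all widened intervals means uncorrelated, a nonempty intersection
    means some constant fits everywhere (static), otherwise dynamic.  The
    zero check takes precedence (zero is a valid constant).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be (S, n_inputs)")
    lows, highs = [], []
    for i in range(samples.shape[1]):
        lo, hi = hdi(samples[:, i], mass)
        lows.append(lo - rope)
        highs.append(hi + rope)
    lows = np.array(lows)
    highs = np.array(highs)
    if np.all((lows <= 0.0) & (0.0 <= highs)):
        return "uncorrelated"
    if lows.max() <= highs.min():
        return "static"
    return "dynamic"


def pairwise_dynamics(
    Sigma_samples: np.ndarray, mass: float = 0.95, rope: float = 0.005
) -> dict[tuple[int, int], str]:
    """``dynamics_test`` for every pair ``i < j`` of an (S, n, d, d) sample array."""
    Sigma_samples = np.asarray(Sigma_samples, dtype=float)
    d = Sigma_samples.shape[-1]
    return {
        (i, j): dynamics_test(Sigma_samples[:, :, i, j], mass, rope)
        for i in range(d)
        for j in range(i + 1, d)
    }
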