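"""The generalised Wishart process generative model.

A covariance process :math:`\\Sigma(x)` over a scalar input is built from
``d * v`` i.i.d. zero-mean Gaussian processes :math:`f_{jl}(x)` with a shared
kernel :math:`\\kappa_\\theta` and a lower-Cholesky scale factor ``L``:

.. math::

    \\Sigma(x_i) = \\sum_{l=1}^{v} L f_l(x_i) f_l(x_i)^\\top L^\\top,

so that, when :math:`\\kappa_\\theta(x, x) = 1`, each marginal
:math:`\\Sigma(x_i)` is Wishart distributed with scale ``V = L L^T`` and
``v`` degrees of freedom.  Observations are
:math:`y_i \\sim \\mathrm{MVN}_d(m_i, \\Sigma(x_i))` with a zero (default) or
exponential-moving-average mean.

The prior scheme is: log-normal priors on the kernel hyperparameters, GP
priors on the latent functions, and independent standard normal priors on
the free (lower-triangular) entries of ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import (
    KernelSpec,
    cross_kernel,
    gram_cholesky,
    sample_hyperparams,
)

__all__ = [
    "WishartProcessConfig",
    "ModelState",
    "sample_prior_state",
    "construct_sigma",
    "log_likelihood",
    "mvn_logpdf_sum",
    "predict_latent",
    "predict_observations",
    "ema_mean",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: diagonal jitter added to every covariance slice before likelihood evaluation
LIKELIHOOD_JITTER = 1e-6


@dataclass(frozen=True)
class WishartProcessConfig:
    """Model dimensions, kernel, and mean function.

    ``v < d`` is allowed (rank-deficient covariance slices, stabilised by
    jitter in the likelihood) but a warning is the caller's concern; default
    experiments use ``v >= d``.
    """

    d: int
    v: int
    kernel: KernelSpec
    mean: str = "zero"  # "zero" | "ema"
    ema_k: int = 10

    def __post_init__(self) -> None:
        if self.d < 1 or self.v < 1:
            raise ValueError("d and v must be at least 1")
        if self.mean not in ("zero", "ema"):
            raise ValueError("mean must be 'zero' or 'ema'")
        if self.ema_k < 1:
            raise ValueError("ema_k must be at least 1")


@dataclass
class ModelState:
    """One full parameter set (a particle): latent GPs, kernel, and scale.

    ``F`` has shape ``(d, v, n)`` with entry ``(j, l, i) = f_jl(x_i)``;
    ``L`` is ``(d, d)`` lower triangular with free diagonal sign.
    """

    F: np.ndarray
    kernel: KernelSpec
    L: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if self.F.ndim != 3:
            raise ValueError("F must have shape (d, v, n)")
        d = self.F.shape[0]
        if self.L.shape != (d, d):
            raise ValueError("L must be (d, d) with d matching F")

    @property
    def d(self) -> int:
        return self.F.shape[0]

    @property
    def v(self) -> int:
        return self.F.shape[1]

    @property
    def n(self) -> int:
        return self.F.shape[2]

    def copy(self) -> "ModelState":
        return ModelState(self.F.copy(), self.kernel, self.L.copy())


def sample_prior_state(
    config: WishartProcessConfig,
    x: np.ndarray,
    rng: np.random.Generator,
    jitter: float = 1e-6,
    chol_K: np.ndarray | None = None,
    sample_theta: bool = True,
) -> ModelState:
    """Draw a full parameter set from the prior.

    The kernel hyperparameters are drawn from their log-normal priors (unless
    ``sample_theta`` is False or a pre-factored ``chol_K`` is supplied, in
    which case the config's values are kept), each latent GP row from
    ``MVN(0, K_theta)``, and each free entry of ``L`` i.i.d. standard normal.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    kernel = sample_hyperparams(config.kernel, rng) if sample_theta else config.kernel
    if chol_K is None:
        chol_K, _ = gram_cholesky(kernel, x, jitter=jitter)
    white = rng.standard_normal((config.d, config.v, n))
    F = np.einsum("nm,dvm->dvn", chol_K, white)
    L = np.tril(rng.standard_normal((config.d, config.d)))
    return ModelState(F, kernel, L)


def construct_sigma(F: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Covariance process slices ``Sigma[i] = sum_l (L f_l(x_i))(L f_l(x_i))^T``.

    Returns an ``(n, d, d)`` array; each slice is symmetric PSD by
    construction.
    """
    F = np.asarray(F, dtype=float)
    L = np.asarray(L, dtype=float)
    if F.ndim != 3 or L.shape != (F.shape[0], F.shape[0]):
        raise ValueError("shape mismatch between F (d, v, n) and L (d, d)")
    LF = np.einsum("ab,bvn->avn", L, F)
    return np.einsum("avn,bvn->nab", LF, LF)


def _logpdf_terms(resid: np.ndarray, Sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation log-determinants and quadratic forms of MVN slices.

    Closed forms for d <= 3 (the common case in the experiments); batched
    Cholesky otherwise.
    """
    n, d = resid.shape
    if d == 1:
        s = Sigma[:, 0, 0]
        return np.log(s), resid[:, 0] ** 2 / s
    if d == 2:
        a = Sigma[:, 0, 0]
        b = Sigma[:, 0, 1]
        c = Sigma[:, 1, 1]
        det = a * c - b * b
        r0, r1 = resid[:, 0], resid[:, 1]
        quad = (c * r0 * r0 - 2.0 * b * r0 * r1 + a * r1 * r1) / det
        return np.log(det), quad
    if d == 3:
        a, b, cc = Sigma[:, 0, 0], Sigma[:, 0, 1], Sigma[:, 0, 2]
        e, f = Sigma[:, 1, 1], Sigma[:, 1, 2]
        g = Sigma[:, 2, 2]
        A = e * g - f * f
        B = cc * f - b * g
        C = b * f - cc * e
        det = a * A + b * B + cc * C
        E = a * g - cc * cc
        Ff = b * cc - a * f
        G = a * e - b * b
        r0, r1, r2 = resid[:, 0], resid[:, 1], resid[:, 2]
        quad = (
            A * r0 * r0
            + E * r1 * r1
            + G * r2 * r2
            + 2.0 * (B * r0 * r1 + C * r0 * r2 + Ff * r1 * r2)
        ) / det
        return np.log(det), quad
    chol = np.linalg.cholesky(Sigma)
    z = np.linalg.solve(chol, resid[:, :, None])[:, :, 0]
    logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
    return logdet, (z * z).sum(axis=1)


def mvn_logpdf_sum(
    resid: np.ndarray, Sigma: np.ndarray, jitter: float = LIKELIHOOD_JITTER
) -> float:
    """Sum over rows of ``log MVN(resid_i | 0, Sigma[i] + jitter I)``.

    Returns ``-inf`` for numerically indefinite slices instead of raising.
    """
    resid = np.asarray(resid, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    n, d = resid.shape
    if jitter:
        Sigma = Sigma + jitter * np.eye(d)
    with np.errstate(invalid="ignore", divide="ignore"):
        try:
            logdet, quad = _logpdf_terms(resid, Sigma)
        except np.linalg.LinAlgError:
            return -np.inf
        total = -0.5 * (n * d * _LOG_2PI + logdet.sum() + quad.sum())
    return float(total) if np.isfinite(total) else -np.inf


def log_likelihood(
    Y: np.ndarray,
    Sigma: np.ndarray,
    mean: np.ndarray | None = None,
    jitter: float = LIKELIHOOD_JITTER,
) -> float:
    """Gaussian observation log-likelihood ``sum_i log MVN(y_i | m_i, Sigma[i])``."""
    Y = np.asarray(Y, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if Y.ndim != 2 or Sigma.shape != (Y.shape[0], Y.shape[1], Y.shape[1]):
        raise ValueError("Y must be (n, d) and Sigma (n, d, d)")
    resid = Y if mean is None else Y - np.asarray(mean, dtype=float)
    return mvn_logpdf_sum(resid, Sigma, jitter=jitter)


def state_log_likelihood(
    state: ModelState,
    Y: np.ndarray,
    mean: np.ndarray | None = None,
    jitter: float = LIKELIHOOD_JITTER,
) -> float:
    """Log-likelihood of a parameter set on data ``Y``."""
    return log_likelihood(Y, construct_sigma(state.F, state.L), mean=mean, jitter=jitter)


def predict_latent(
    state: ModelState,
    x: np.ndarray,
    x_star: np.ndarray,
    jitter: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless GP conditional of every latent function at test inputs.

    Returns ``(means, cov)`` where ``means`` has shape ``(d, v, m)`` and
    ``cov`` is the common ``(m, m)`` conditional covariance (all latent GPs
    share the kernel, hence the covariance):

    ``mean = K_*x K_xx^-1 f``, ``cov = K_** - K_*x K_xx^-1 K_*x^T``.
    """
    x = np.asarray(x, dtype=float).ravel()
    x_star = np.asarray(x_star, dtype=float).ravel()
    m = x_star.size
    if m == 0:
        return np.zeros((state.d, state.v, 0)), np.zeros((0, 0))
    chol, _ = gram_cholesky(state.kernel, x, jitter=jitter)
    K_sx = cross_kernel(state.kernel, x_star, x)
    K_ss = cross_kernel(state.kernel, x_star, x_star)
    # A = K_xx^-1 K_*x^T via two triangular solves
    from scipy.linalg import solve_triangular

    tmp = solve_triangular(chol, K_sx.T, lower=True)
    A = solve_triangular(chol.T, tmp, lower=False)
    means = np.einsum("mn,dvn->dvm", A.T, state.F)
    cov = K_ss - tmp.T @ tmp
    # enforce symmetry against floating-point drift
    cov = 0.5 * (cov + cov.T)
    return means, cov


def predict_observations(
    posterior_states: list[ModelState],
    x: np.ndarray,
    x_star: np.ndarray,
    rng: np.random.Generator,
    mean_star: np.ndarray | None = None,
    jitter: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-predictive draws of the covariance process and observations.

    For every posterior state: draw the latent GPs at ``x_star`` from their
    conditional, build ``Sigma(x*)``, and draw ``y* ~ MVN(mean*, Sigma(x*))``.

    Returns ``(Sigma_star, y_star)`` with shapes ``(S, m, d, d)`` and
    ``(S, m, d)``.
    """
    if not posterior_states:
        raise ValueError("posterior_states must be nonempty")
    x_star = np.asarray(x_star, dtype=float).ravel()
    m = x_star.size
    d = posterior_states[0].d
    S = len(posterior_states)
    Sigma_star = np.zeros((S, m, d, d))
    y_star = np.zeros((S, m, d))
    if m == 0:
        return Sigma_star, y_star
    for s_idx, state in enumerate(posterior_states):
        means, cov = predict_latent(state, x, x_star, jitter=jitter)
        chol = np.linalg.cholesky(cov + jitter * np.eye(m))
        white = rng.standard_normal((state.d, state.v, m))
        F_star = means + np.einsum("mk,dvk->dvm", chol, white)
        Sig = construct_sigma(F_star, state.L)
        Sigma_star[s_idx] = Sig
        chol_y = np.linalg.cholesky(Sig + LIKELIHOOD_JITTER * np.eye(d))
        eps = rng.standard_normal((m, d))
        y_star[s_idx] = np.einsum("iab,ib->ia", chol_y, eps)
        if mean_star is not None:
            y_star[s_idx] += mean_star
    return Sigma_star, y_star


def ema_mean(
    Y: np.ndarray, k: int, normalised: bool = False
) -> np.ndarray:
    """Exponential-moving-average mean function over the ``k`` latest rows.

    Row ``i`` of the output is the weighted history
    ``alpha * y_{i-1} + (1-alpha) y_{i-2} + ... + (1-alpha)^{k-1} y_{i-k}``
    with ``alpha = 2 / (k + 1)``: weight ``alpha`` on the most recent
    observation and a plain geometric decay on older ones.  With
    ``normalised=True`` the weights are divided by their sum instead.  Early
    rows use truncated history; row 0 (no history) is zero.
    """
    Y = np.asarray(Y, dtype=float)
    if k < 1:
        raise ValueError("k must be at least 1")
    n = Y.shape[0]
    alpha = 2.0 / (k + 1.0)
    weights = np.concatenate(([alpha], (1.0 - alpha) ** np.arange(1, k)))
    out = np.zeros_like(Y)
    for i in range(1, n):
        hist = min(k, i)
        w = weights[:hist]
        if normalised:
            w = w / w.sum()
        # Y rows i-1, i-2, ..., i-hist
        out[i] = w @ Y[i - 1 :: -1][:hist]
    return out
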