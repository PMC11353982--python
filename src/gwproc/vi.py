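"""Variational baseline: Gaussian posteriors over the latent GPs.

The approximating family places an independent full-rank Gaussian
``q(f_jl) = N(m_jl, C_jl C_jl^T)`` on every latent GP (``C_jl`` lower
triangular, positive diagonal), point estimates on the kernel
hyperparameters ``theta`` and the scale Cholesky ``L``, and a learned
diagonal observation-noise matrix ``Lambda`` (initialised at 0.001) added to
every covariance slice.  The evidence lower bound

``ELBO = E_q[log p(Y | F, L, Lambda)] - sum_jl KL(q(f_jl) || p(f_jl | theta))``

is maximised with Adam (default learning rate 0.001); the expectation is
estimated with a small number of reparameterised Monte Carlo draws (3 by
default) and the KL between Gaussians is closed-form.  Gradients are
analytic except for the kernel hyperparameters, where the Gram-matrix
derivative is taken by central finite differences.  Optimisation stops when
the best ELBO has not improved for a patience window; among several random
restarts the run with the highest ELBO is returned.

This is a deliberately simple full-rank baseline: no inducing points, no
minibatches, and only point estimates for ``theta`` and ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from .kernels import KernelSpec, gram_cholesky
from .mcmc import observation_mean
from .model import ModelState, WishartProcessConfig, construct_sigma

__all__ = ["VIConfig", "VariationalState", "elbo_estimate", "fit_vi"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class VIConfig:
    learning_rate: float = 0.001
    n_mc: int = 3
    patience: int = 10_000
    max_iters: int = 300_000
    n_restarts: int = 4
    lambda_init: float = 0.001
    n_sigma_draws: int = 200
    jitter: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mc < 1 or self.n_restarts < 1 or self.max_iters < 1:
            raise ValueError("n_mc, n_restarts, max_iters must be positive")


@dataclass
class VariationalState:
    """Variational parameters: per-GP Gaussians plus point estimates.

    ``means`` is ``(d*v, n)``; ``chol_factors`` is ``(d*v, n, n)`` lower
    triangular with positive diagonals.  ``log_lambda`` holds the log of the
    diagonal observation noise.
    """

    d: int
    v: int
    means: np.ndarray
    chol_factors: np.ndarray
    kernel: KernelSpec
    L: np.ndarray
    log_lambda: np.ndarray

    @property
    def n(self) -> int:
        return self.means.shape[1]

    def latent_F(self, eps: np.ndarray) -> np.ndarray:
        """Reparameterised draw ``F = m + C eps`` reshaped to ``(d, v, n)``."""
        f = self.means + np.einsum("rij,rj->ri", self.chol_factors, eps)
        return f.reshape(self.d, self.v, self.n)

    def sample_states(self, n_draws: int, rng: np.random.Generator) -> list[ModelState]:
        states = []
        for _ in range(n_draws):
            eps = rng.standard_normal(self.means.shape)
            states.append(ModelState(self.latent_F(eps), self.kernel, self.L.copy()))
        return states


def _gauss_kl_terms(
    vstate: VariationalState, chol_K: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """KL(q || prior) summed over rows, with gradients.

    Returns ``(kl, grad_means, grad_chols, M)`` where ``M = sum_r (S_r +
    m_r m_r^T)`` is the sufficient accumulation needed for the kernel
    hyperparameter gradient.
    """
    r, n = vstate.means.shape
    logdet_K = 2.0 * float(np.log(np.diag(chol_K)).sum())
    # K^-1 m and K^-1 C via triangular solves
    zm = solve_triangular(chol_K, vstate.means.T, lower=True)  # (n, r)
    Kinv_m = solve_triangular(chol_K.T, zm, lower=False).T  # (r, n)
    kl = 0.0
    grad_chols = np.empty_like(vstate.chol_factors)
    M = vstate.means.T @ vstate.means  # sum_r m m^T
    eye = np.eye(n)
    for k in range(r):
        C = vstate.chol_factors[k]
        zc = solve_triangular(chol_K, C, lower=True)
        Kinv_C = solve_triangular(chol_K.T, zc, lower=False)
        diag_C = np.diag(C)
        logdet_S = 2.0 * float(np.log(np.abs(diag_C)).sum())
        tr = float((zc * zc).sum())
        quad = float((zm[:, k] * zm[:, k]).sum())
        kl += 0.5 * (tr + quad - n + logdet_K - logdet_S)
        Cinv_T = solve_triangular(C, eye, lower=True).T
        grad_chols[k] = np.tril(Kinv_C - Cinv_T)
        M += C @ C.T
    return kl, Kinv_m, grad_chols, M


def _likelihood_terms(
    vstate: VariationalState,
    resid: np.ndarray,
    n_mc: int,
    rng: np.random.Generator,
) -> tuple[float, dict[str, np.ndarray]]:
    """MC estimate of ``E_q[log p(Y | F, L, Lambda)]`` and its gradients."""
    n, d = resid.shape
    v = vstate.v
    L = vstate.L
    lam = np.exp(vstate.log_lambda)
    value = 0.0
    g_means = np.zeros_like(vstate.means)
    g_chols = np.zeros_like(vstate.chol_factors)
    g_L = np.zeros_like(L)
    g_loglam = np.zeros_like(vstate.log_lambda)
    for _ in range(n_mc):
        eps = rng.standard_normal(vstate.means.shape)
        F = vstate.latent_F(eps)  # (d, v, n)
        Sigma = construct_sigma(F, L) + np.diag(lam)
        P = np.linalg.inv(Sigma)  # (n, d, d)
        sign, logdet = np.linalg.slogdet(Sigma)
        Pr = np.einsum("iab,ib->ia", P, resid)
        quad = np.einsum("ia,ia->i", resid, Pr)
        value += float(-0.5 * (n * d * _LOG_2PI + logdet.sum() + quad.sum()))
        G = 0.5 * (np.einsum("ia,ib->iab", Pr, Pr) - P)  # d loglik / d Sigma_i
        # Sigma_i = L F_i F_i^T L^T + diag(lam), F_i = F[:, :, i]
        LF = np.einsum("ab,bvi->avi", L, F)
        GLF = np.einsum("iab,bvi->avi", G, LF)
        gF = 2.0 * np.einsum("ba,bvi->avi", L, GLF)  # (d, v, n)
        g_means += gF.reshape(d * v, n)
        geps = gF.reshape(d * v, n)
        g_chols += np.einsum("ri,rj->rij", geps, eps)  # full; mask downstream
        g_L += 2.0 * np.einsum("iab,bvi,cvi->ac", G, LF, F)
        g_loglam += lam * np.einsum("iaa->a", G)
    scale = 1.0 / n_mc
    grads = {
        "means": g_means * scale,
        "chols": g_chols * scale,
        "L": np.tril(g_L * scale),
        "log_lambda": g_loglam * scale,
    }
    return value * scale, grads


def elbo_estimate(
    vstate: VariationalState,
    x: np.ndarray,
    Y: np.ndarray,
    n_mc: int,
    seed: int | np.random.Generator,
    mean: np.ndarray | None = None,
    jitter: float = 1e-6,
    include_likelihood: bool = True,
) -> float:
    """Monte-Carlo ELBO of a variational state on data ``(x, Y)``.

    Deterministic given the seed.  With ``include_likelihood=False`` only the
    negative KL term is returned (zero exactly when q equals the prior).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float).ravel()
    resid = np.asarray(Y, dtype=float)
    if mean is not None:
        resid = resid - mean
    chol_K, _ = gram_cholesky(vstate.kernel, x, jitter=jitter)
    kl, _, _, _ = _gauss_kl_terms(vstate, chol_K)
    if not include_likelihood:
        return -kl
    like, _ = _likelihood_terms(vstate, resid, n_mc, rng)
    return like - kl


class _Adam:
    def __init__(self, shapes: dict[str, tuple], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        """Ascent step (gradients point uphill)."""
        self.t += 1
        corr1 = 1.0 - self.b1**self.t
        corr2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] += self.lr * (self.m[k] / corr1) / (
                np.sqrt(self.v[k] / corr2) + self.eps
            )


@dataclass
class VIResult:
    vstate: VariationalState
    elbo: float
    elbo_trace: np.ndarray
    n_iters: int
    sigma_samples: np.ndarray  # (n_draws, n, d, d)
    states: list[ModelState]
    restart_elbos: list[float] = field(default_factory=list)
    diverged: bool = False


def _whitened_kl(mw: np.ndarray, Cw: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """KL(q || prior) for whitened coordinates, with gradients.

    In whitened coordinates (``f = chol_K (m_w + C_w eps)``) the prior is
    standard normal, so per latent row
    ``KL = 0.5 (|m_w|^2 + |C_w|_F^2 - n - 2 sum log diag C_w)``.
    """
    r, n, _ = Cw.shape
    diag = Cw[:, np.arange(n), np.arange(n)]
    kl = 0.5 * float(
        (mw * mw).sum() + (Cw * Cw).sum() - r * n - 2.0 * np.log(diag).sum()
    )
    g_Cw = Cw.copy()
    g_Cw[:, np.arange(n), np.arange(n)] -= 1.0 / diag
    return kl, mw.copy(), g_Cw


def _fit_single(
    x: np.ndarray,
    resid: np.ndarray,
    model_config: WishartProcessConfig,
    cfg: VIConfig,
    rng: np.random.Generator,
    dist: np.ndarray,
) -> tuple[VariationalState, float, np.ndarray, int, bool]:
    """One Adam run in whitened coordinates; returns the best state seen.

    Whitening (optimising ``m_w, C_w`` with ``f = chol_K (m_w + C_w eps)``)
    removes the Gram matrix's conditioning from the KL term, which otherwise
    dominates the curvature and stalls first-order optimisers.
    """
    n, d = resid.shape
    r = model_config.d * model_config.v
    rr = np.arange(n)
    eye = np.eye(n)
    # scale init: empirical covariance (so v * L L^T matches the data scale)
    # perturbed per restart; latent means start near zero
    emp_cov = resid.T @ resid / n + 1e-6 * np.eye(d)
    L0 = np.linalg.cholesky(emp_cov / model_config.v)
    params = {
        "mw": 0.1 * rng.standard_normal((r, n)),
        "Cw_raw": np.tile(eye, (r, 1, 1)),  # log-diagonal storage
        "L": L0 + 0.2 * np.tril(rng.standard_normal((model_config.d, model_config.d))),
        "log_lambda": np.full(model_config.d, np.log(cfg.lambda_init)),
        "log_theta": np.log(model_config.kernel.param_vector()),
    }
    params["Cw_raw"][:, rr, rr] = 0.0  # log(1)
    adam = _Adam({k: v.shape for k, v in params.items()}, cfg.learning_rate)
    best = -np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    since_best = 0
    trace = []
    diverged = False
    base_kernel = model_config.kernel
    theta_names = base_kernel.param_names
    h = 1e-4
    it = 0

    def natural(mw, Cw, chol):
        means = mw @ chol.T
        C_nat = np.matmul(chol, Cw)
        return means, C_nat

    for it in range(cfg.max_iters):
        theta_nat = np.exp(params["log_theta"])
        kernel = base_kernel.with_params(theta_nat)
        try:
            chol_K, _ = gram_cholesky(kernel, x, jitter=cfg.jitter, dist=dist)
        except np.linalg.LinAlgError:
            diverged = True
            break
        Cw = params["Cw_raw"].copy()
        Cw[:, rr, rr] = np.exp(Cw[:, rr, rr])
        Cw = np.tril(Cw)
        means, C_nat = natural(params["mw"], Cw, chol_K)
        vs = VariationalState(
            d=model_config.d, v=model_config.v, means=means, chol_factors=C_nat,
            kernel=kernel, L=params["L"], log_lambda=params["log_lambda"],
        )
        kl, g_mw_kl, g_Cw_kl = _whitened_kl(params["mw"], Cw)
        like, lg = _likelihood_terms(vs, resid, cfg.n_mc, rng)
        elbo = like - kl
        trace.append(elbo)
        if not np.isfinite(elbo):
            diverged = True
            break
        if elbo > best:
            best = elbo
            best_params = {k: v.copy() for k, v in params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
        # chain likelihood gradients into whitened coordinates
        g_mw = lg["means"] @ chol_K - g_mw_kl
        g_Cw = np.tril(np.matmul(chol_K.T, lg["chols"])) - g_Cw_kl
        g_Cw_raw = g_Cw
        g_Cw_raw[:, rr, rr] = g_Cw[:, rr, rr] * Cw[:, rr, rr]
        # kernel hyperparameters enter through chol_K only: finite-difference
        # the factor and chain through the (linear) whitening map
        g_logtheta = np.empty_like(params["log_theta"])
        for k in range(len(theta_names)):
            tp = theta_nat.copy()
            step = h * tp[k]
            tp[k] += step
            hi, _ = gram_cholesky(base_kernel.with_params(tp), x, jitter=cfg.jitter, dist=dist)
            tp[k] -= 2 * step
            lo, _ = gram_cholesky(base_kernel.with_params(tp), x, jitter=cfg.jitter, dist=dist)
            dchol = (hi - lo) / (2 * step)
            dmn = params["mw"] @ dchol.T
            dCn = np.matmul(dchol, Cw)
            g_logtheta[k] = (
                float((lg["means"] * dmn).sum()) + float((lg["chols"] * dCn).sum())
            ) * theta_nat[k]
        grads = {
            "mw": g_mw,
            "Cw_raw": g_Cw_raw,
            "L": lg["L"],
            "log_lambda": lg["log_lambda"],
            "log_theta": g_logtheta,
        }
        adam.step(params, grads)
    theta_best = np.exp(best_params["log_theta"])
    kernel = base_kernel.with_params(theta_best)
    chol_K, _ = gram_cholesky(kernel, x, jitter=cfg.jitter, dist=dist)
    Cw = best_params["Cw_raw"].copy()
    Cw[:, rr, rr] = np.exp(Cw[:, rr, rr])
    Cw = np.tril(Cw)
    means, C_nat = natural(best_params["mw"], Cw, chol_K)
    final = VariationalState(
        d=model_config.d, v=model_config.v, means=means, chol_factors=C_nat,
        kernel=kernel, L=best_params["L"], log_lambda=best_params["log_lambda"],
    )
    return final, best, np.array(trace), it + 1, diverged


def fit_vi(
    x: np.ndarray,
    Y: np.ndarray,
    model_config: WishartProcessConfig,
    vi_config: VIConfig,
) -> VIResult:
    """Optimise the ELBO from several restarts; return the best run.

    The returned result carries covariance-process draws obtained by sampling
    ``q`` and applying the Wishart construction, plus the point estimates of
    the kernel hyperparameters and scale Cholesky inside ``vstate``.
    """
    x = np.asarray(x, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float)
    mean = observation_mean(Y, model_config)
    resid = Y if mean is None else Y - mean
    dist = np.abs(x[:, None] - x[None, :])
    seeds = np.random.SeedSequence(vi_config.seed).spawn(vi_config.n_restarts + 1)
    runs = []
    for seed in seeds[:-1]:
        rng = np.random.default_rng(seed)
        runs.append(_fit_single(x, resid, model_config, vi_config, rng, dist))
    elbos = [r[1] for r in runs]
    best_idx = int(np.argmax(elbos))
    vstate, elbo, trace, n_iters, diverged = runs[best_idx]
    draw_rng = np.random.default_rng(seeds[-1])
    states = vstate.sample_states(vi_config.n_sigma_draws, draw_rng)
    sigma = np.stack([construct_sigma(s.F, s.L) for s in states])
    return VIResult(
        vstate=vstate,
        elbo=elbo,
        elbo_trace=trace,
        n_iters=n_iters,
        sigma_samples=sigma,
        states=states,
        restart_elbos=elbos,
        diverged=diverged,
    )
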