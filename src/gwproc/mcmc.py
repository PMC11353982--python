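"""Gibbs MCMC for the Wishart process, and the Gelman-Rubin diagnostic.

One Gibbs cycle updates the three parameter blocks from their conditionals:

* latent GPs ``F``  -- elliptical slice sampling, one move per latent row,
  targeting ``p(Y | F, L)^beta * p(F | theta)`` (``beta`` is a likelihood
  tempering exponent; 1 for plain posterior sampling);
* kernel hyperparameters ``theta`` -- random-walk Metropolis on ``log theta``
  targeting ``p(F | x, theta) p(theta)`` (the conditional for ``theta`` does
  not involve the data);
* scale Cholesky ``L`` -- joint random-walk Metropolis on the free
  lower-triangular entries, targeting
  ``p(Y | F, L)^beta * prod N(L_jo | 0, 1)``.

The same cycle serves as the mutation kernel of the SMC sampler.  Full MCMC
runs use several chains with prior-drawn initialisations, thinning, and
burn-in determined by the potential scale reduction factor (PSRF < 1.1 by
default) over the covariance process, the hyperparameters, and the scale
matrix ``V = L L^T`` (monitored instead of ``L`` itself, whose column signs
are not identifiable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from ._fastpath import state_loglik
from .kernels import KernelSpec, kernel_from_dist, log_hyperprior
from .model import (
    LIKELIHOOD_JITTER,
    ModelState,
    WishartProcessConfig,
    construct_sigma,
    ema_mean,
    sample_prior_state,
)

__all__ = ["MCMCConfig", "GibbsSampler", "run_mcmc", "psrf", "psrf_max"]

_LOG_2PI = float(np.log(2.0 * np.pi))
_MAX_SLICE_SHRINKS = 1000


@dataclass(frozen=True)
class MCMCConfig:
    """Settings of the Gibbs MCMC run."""

    n_chains: int = 4
    rw_step: float = 0.01
    rw_step_L: float | None = None  # defaults to rw_step
    thinning: int = 1000
    burn_in: int | str = "auto"
    samples_per_chain_kept: int = 250
    psrf_threshold: float = 1.1
    max_cycles: int = 200_000
    check_interval: int | None = None  # cycles between PSRF checks (auto mode)
    sample_theta: bool = True
    sample_L: bool = True
    jitter: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be positive")
        if self.burn_in == "auto" and self.n_chains < 2:
            raise ValueError("PSRF-based burn-in requires at least 2 chains")
        if self.rw_step <= 0 or self.thinning < 1 or self.samples_per_chain_kept < 1:
            raise ValueError("rw_step, thinning, samples_per_chain_kept must be positive")


def observation_mean(Y: np.ndarray, config: WishartProcessConfig) -> np.ndarray | None:
    """The model's mean matrix for ``Y`` (None for the zero mean)."""
    if config.mean == "ema":
        return ema_mean(Y, config.ema_k)
    return None


class GibbsSampler:
    """Block-conditional updates for one dataset, with Gram-factor caching.

    The sampler mutates :class:`ModelState` objects in place and keeps, per
    state, the Cholesky factor and log-determinant of the current Gram matrix
    in a cache dict (recomputed only when a hyperparameter proposal is
    accepted).  Observations enter through the residual ``Y - mean``.
    """

    def __init__(
        self,
        x: np.ndarray,
        Y: np.ndarray,
        model_config: WishartProcessConfig,
        rw_step: float = 0.01,
        rw_step_L: float | None = None,
        jitter: float = 1e-6,
        sample_theta: bool = True,
        sample_L: bool = True,
    ) -> None:
        self.x = np.asarray(x, dtype=float).ravel()
        Y = np.asarray(Y, dtype=float)
        if Y.shape != (self.x.size, model_config.d):
            raise ValueError("Y must be (n, d) matching the grid and config")
        mean = observation_mean(Y, model_config)
        self.resid = Y if mean is None else Y - mean
        self.config = model_config
        self.rw_step = rw_step
        self.rw_step_L = rw_step if rw_step_L is None else rw_step_L
        self.jitter = jitter
        self.sample_theta = sample_theta
        self.sample_L = sample_L
        self.dist = np.abs(self.x[:, None] - self.x[None, :])
        self._tril = np.tril_indices(model_config.d)
        # evenly spaced grids give Toeplitz Grams: build from the first row
        # instead of all n^2 kernel evaluations
        diffs = np.diff(self.x)
        self._toeplitz = diffs.size > 0 and np.allclose(diffs, diffs[0])
        self.accepts = {"theta": 0, "L": 0}
        self.proposals = {"theta": 0, "L": 0}

    # -- cache -----------------------------------------------------------

    def _gram_chol(self, spec: KernelSpec) -> tuple[np.ndarray, float]:
        """Lower Cholesky of the Gram matrix and its log-determinant."""
        from scipy.linalg import cholesky as s_cholesky
        from scipy.linalg import toeplitz

        if self._toeplitz:
            K = toeplitz(kernel_from_dist(spec, self.dist[0]))
        else:
            K = kernel_from_dist(spec, self.dist)
        n = K.shape[0]
        j = self.jitter
        while True:
            K.flat[:: n + 1] += j
            try:
                chol = s_cholesky(K, lower=True, check_finite=False)
                break
            except np.linalg.LinAlgError:
                K.flat[:: n + 1] -= j
                j = 10.0 * j if j > 0 else 1e-8
                if j > 1e-2:
                    raise
        return chol, 2.0 * float(np.log(np.diag(chol)).sum())

    def make_cache(self, state: ModelState) -> dict:
        chol, logdet = self._gram_chol(state.kernel)
        return {"chol_K": chol, "logdet_K": logdet}

    # -- densities -------------------------------------------------------

    def loglik(self, state: ModelState) -> float:
        """Data log-likelihood of the state (tempering exponent not applied)."""
        return state_loglik(state.F, state.L, self.resid, LIKELIHOOD_JITTER)

    def _log_p_F(self, F: np.ndarray, chol_K: np.ndarray, logdet_K: float) -> float:
        """log p(F | x, theta): independent MVN(0, K) rows."""
        d, v, n = F.shape
        z = solve_triangular(chol_K, F.reshape(d * v, n).T, lower=True)
        return -0.5 * (d * v * (n * _LOG_2PI + logdet_K) + float((z * z).sum()))

    def _log_prior_L(self, L: np.ndarray) -> float:
        free = L[self._tril]
        return float(-0.5 * (free.size * _LOG_2PI + (free * free).sum()))

    # -- block updates ---------------------------------------------------

    def update_latent_gps(
        self,
        state: ModelState,
        cache: dict,
        beta: float,
        rng: np.random.Generator,
        cur_ll: float | None = None,
    ) -> float | None:
        """One elliptical-slice move per latent GP row; returns the new loglik.

        At ``beta == 0`` the move reduces to a rotation between the current
        row and a fresh prior draw, which leaves the GP prior exactly
        invariant without evaluating the likelihood (returns None: loglik
        unknown/stale).
        """
        n = state.n
        # one prior draw per latent row, generated in a single GEMM
        eps = rng.standard_normal((state.d * state.v, n))
        nus = (cache["chol_K"] @ eps.T).T.reshape(state.d, state.v, n)
        for j in range(state.d):
            for l in range(state.v):
                f = state.F[j, l].copy()
                nu = nus[j, l]
                angle = rng.uniform(0.0, 2.0 * np.pi)
                if beta == 0.0:
                    state.F[j, l] = f * np.cos(angle) + nu * np.sin(angle)
                    cur_ll = None
                    continue
                if cur_ll is None:
                    cur_ll = self.loglik(state)
                log_u = np.log(rng.uniform())
                thresh = beta * cur_ll + log_u
                lo, hi = angle - 2.0 * np.pi, angle
                for _ in range(_MAX_SLICE_SHRINKS):
                    state.F[j, l] = f * np.cos(angle) + nu * np.sin(angle)
                    new_ll = self.loglik(state)
                    if beta * new_ll > thresh:
                        cur_ll = new_ll
                        break
                    if angle < 0.0:
                        lo = angle
                    else:
                        hi = angle
                    angle = rng.uniform(lo, hi)
                else:  # pragma: no cover - slice shrinkage always terminates
                    state.F[j, l] = f
        return cur_ll

    def update_hyperparams(
        self,
        state: ModelState,
        cache: dict,
        rng: np.random.Generator,
        rw_step: float | None = None,
    ) -> bool:
        """Random-walk Metropolis on ``log theta``; returns acceptance.

        The conditional for ``theta`` is ``p(F | x, theta) p(theta)``; the
        random walk lives in log space, so the log-normal prior density is
        combined with the log-space Jacobian ``prod theta``.
        """
        step = self.rw_step if rw_step is None else rw_step
        cur = state.kernel.param_vector()
        log_prop = np.log(cur) + step * rng.standard_normal(cur.size)
        prop = np.exp(log_prop)
        self.proposals["theta"] += 1
        prop_prior = log_hyperprior(state.kernel, prop)
        if not np.isfinite(prop_prior):
            rng.uniform()  # keep the draw count deterministic
            return False
        prop_spec = state.kernel.with_params(prop)
        try:
            chol_p, logdet_p = self._gram_chol(prop_spec)
        except np.linalg.LinAlgError:
            rng.uniform()
            return False
        cur_target = (
            self._log_p_F(state.F, cache["chol_K"], cache["logdet_K"])
            + log_hyperprior(state.kernel)
            + float(np.log(cur).sum())
        )
        prop_target = (
            self._log_p_F(state.F, chol_p, logdet_p)
            + prop_prior
            + float(log_prop.sum())
        )
        if np.log(rng.uniform()) < prop_target - cur_target:
            state.kernel = prop_spec
            cache["chol_K"] = chol_p
            cache["logdet_K"] = logdet_p
            self.accepts["theta"] += 1
            return True
        return False

    def update_scale_cholesky(
        self,
        state: ModelState,
        beta: float,
        rng: np.random.Generator,
        cur_ll: float | None = None,
        rw_step: float | None = None,
    ) -> tuple[float | None, bool]:
        """Joint random-walk Metropolis on the free entries of ``L``.

        Returns the (possibly updated) loglik and the acceptance flag.
        """
        step = self.rw_step_L if rw_step is None else rw_step
        self.proposals["L"] += 1
        prop_L = state.L + step * np.tril(rng.standard_normal(state.L.shape))
        if beta > 0.0 and cur_ll is None:
            cur_ll = self.loglik(state)
        prop_ll = (
            state_loglik(state.F, prop_L, self.resid, LIKELIHOOD_JITTER)
            if beta > 0.0
            else 0.0
        )
        log_ratio = self._log_prior_L(prop_L) - self._log_prior_L(state.L)
        if beta > 0.0:
            log_ratio += beta * (prop_ll - cur_ll)
        if np.log(rng.uniform()) < log_ratio:
            state.L = prop_L
            self.accepts["L"] += 1
            return (prop_ll if beta > 0.0 else cur_ll), True
        return cur_ll, False

    def gibbs_cycle(
        self,
        state: ModelState,
        cache: dict,
        beta: float,
        rng: np.random.Generator,
        cur_ll: float | None = None,
    ) -> float | None:
        """One full cycle of block updates, in the order F -> theta -> L."""
        cur_ll = self.update_latent_gps(state, cache, beta, rng, cur_ll)
        if self.sample_theta:
            self.update_hyperparams(state, cache, rng)
        if self.sample_L:
            cur_ll, _ = self.update_scale_cholesky(state, beta, rng, cur_ll)
        return cur_ll

    def acceptance_rates(self) -> dict[str, float]:
        return {
            k: (self.accepts[k] / self.proposals[k] if self.proposals[k] else float("nan"))
            for k in self.accepts
        }


# -- convergence diagnostics ----------------------------------------------


def psrf(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor of one scalar.

    ``chains`` has shape ``(m_chains, n_samples)``.  With ``W`` the mean
    within-chain variance and ``B/n`` the variance of chain means, the PSRF
    is ``sqrt(((n - 1)/n W + B/n) / W)``.  Zero within-chain variance with
    distinct chains yields ``+inf`` (with a warning); identical chains yield
    exactly 1.  The statistic estimates a variance ratio that is at least 1
    for the true posterior; values below 1 arise only from sampling noise and
    are truncated at 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 samples each")
    values = _psrf_vector(chains[:, None, :])
    return float(values[0])


def _psrf_vector(chains: np.ndarray) -> np.ndarray:
    """PSRF per scalar for an (m_chains, n_scalars, n_samples) array."""
    n = chains.shape[2]
    W = chains.var(axis=2, ddof=1).mean(axis=0)
    chain_means = chains.mean(axis=2)
    B_over_n = chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    out = np.empty(W.shape)
    zero_W = W <= 0.0
    if np.any(zero_W & (B_over_n > 0.0)):
        warnings.warn("zero within-chain variance with distinct chains: PSRF is +inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / W)
    out = np.maximum(out, 1.0)
    out[zero_W & (B_over_n > 0.0)] = np.inf
    out[zero_W & (B_over_n <= 0.0)] = 1.0
    return out


def _monitored_scalars(states: list[ModelState]) -> np.ndarray:
    """Per-state monitored quantities: unique Sigma entries, theta, V entries."""
    d = states[0].d
    iu = np.triu_indices(d)
    rows = []
    for st in states:
        Sigma = construct_sigma(st.F, st.L)
        V = st.L @ st.L.T
        rows.append(
            np.concatenate(
                [Sigma[:, iu[0], iu[1]].ravel(), st.kernel.param_vector(), V[iu]]
            )
        )
    return np.array(rows)  # (n_samples, n_scalars)


def psrf_max(chains_of_states: list[list[ModelState]]) -> float:
    """Maximum PSRF over all monitored scalars across chains."""
    arrays = [_monitored_scalars(c) for c in chains_of_states]
    n = min(a.shape[0] for a in arrays)
    stacked = np.stack([a[-n:] for a in arrays])  # (m, n_samples, n_scalars)
    return float(_psrf_vector(np.swapaxes(stacked, 1, 2)).max())


# -- full runs -------------------------------------------------------------


@dataclass
class MCMCResult:
    """Retained chains plus the merged posterior subsample."""

    chains: list[list[ModelState]]
    samples: list[ModelState]
    converged: bool
    psrf_max: float | None
    burn_in_cycles: int
    total_cycles: int
    acceptance_rates: dict[str, float]

    def sigma_samples(self) -> np.ndarray:
        return np.stack([construct_sigma(s.F, s.L) for s in self.samples])


def run_mcmc(
    x: np.ndarray,
    Y: np.ndarray,
    model_config: WishartProcessConfig,
    mcmc_config: MCMCConfig,
) -> MCMCResult:
    """Run ``n_chains`` Gibbs chains and merge a posterior subsample.

    With ``burn_in="auto"`` the chains are extended until the maximum PSRF
    over all monitored scalars drops below the threshold (the first half of
    each chain is treated as burn-in) or ``max_cycles`` is reached, in which
    case the result is returned flagged as non-converged.
    """
    cfg = mcmc_config
    x = np.asarray(x, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float)
    master = np.random.SeedSequence(cfg.seed)
    chain_seeds = master.spawn(cfg.n_chains + 1)
    sampler = GibbsSampler(
        x,
        Y,
        model_config,
        rw_step=cfg.rw_step,
        rw_step_L=cfg.rw_step_L,
        jitter=cfg.jitter,
        sample_theta=cfg.sample_theta,
        sample_L=cfg.sample_L,
    )
    rngs = [np.random.default_rng(s) for s in chain_seeds[:-1]]
    states, caches, lls = [], [], []
    for rng in rngs:
        st = sample_prior_state(model_config, x, rng, jitter=cfg.jitter)
        states.append(st)
        caches.append(sampler.make_cache(st))
        lls.append(None)
    retained: list[list[ModelState]] = [[] for _ in range(cfg.n_chains)]
    total = 0

    def advance(n_cycles: int) -> None:
        nonlocal total
        for _ in range(n_cycles):
            total += 1
            keep = total % cfg.thinning == 0
            for c in range(cfg.n_chains):
                lls[c] = sampler.gibbs_cycle(states[c], caches[c], 1.0, rngs[c], lls[c])
                if keep:
                    retained[c].append(states[c].copy())

    converged = True
    max_r: float | None = None
    if cfg.burn_in == "auto":
        check = cfg.check_interval or max(cfg.thinning * 20, 200)
        converged = False
        while total < cfg.max_cycles:
            advance(min(check, cfg.max_cycles - total))
            if len(retained[0]) >= 4:
                half = len(retained[0]) // 2
                max_r = psrf_max([c[half:] for c in retained])
                if max_r < cfg.psrf_threshold:
                    converged = True
                    break
        burn_idx = len(retained[0]) // 2
        # top up so each chain keeps enough post-burn-in draws
        needed = cfg.samples_per_chain_kept - (len(retained[0]) - burn_idx)
        if needed > 0 and total < cfg.max_cycles:
            advance(min(needed * cfg.thinning, cfg.max_cycles - total))
        burn_cycles = burn_idx * cfg.thinning
    else:
        burn = int(cfg.burn_in)
        advance(burn + cfg.samples_per_chain_kept * cfg.thinning)
        burn_idx = burn // cfg.thinning
        burn_cycles = burn
        if cfg.n_chains >= 2 and len(retained[0]) - burn_idx >= 2:
            max_r = psrf_max([c[burn_idx:] for c in retained])
            converged = max_r < cfg.psrf_threshold

    post = [c[burn_idx:] for c in retained]
    available = min(len(c) for c in post)
    if available < cfg.samples_per_chain_kept:
        raise ValueError(
            f"only {available} retained samples per chain; "
            f"{cfg.samples_per_chain_kept} requested"
        )
    pick_rng = np.random.default_rng(chain_seeds[-1])
    merged: list[ModelState] = []
    for c in post:
        idx = pick_rng.choice(len(c), size=cfg.samples_per_chain_kept, replace=False)
        merged.extend(c[i] for i in sorted(idx))
    return MCMCResult(
        chains=post,
        samples=merged,
        converged=converged,
        psrf_max=max_r,
        burn_in_cycles=burn_cycles,
        total_cycles=total,
        acceptance_rates=sampler.acceptance_rates(),
    )
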