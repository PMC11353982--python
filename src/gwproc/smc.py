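"""Adaptive-tempering Sequential Monte Carlo over Wishart-process particles.

The sampler maintains ``s`` full parameter sets (particles) ``{F, theta, L}``
initialised from the prior with uniform weights.  The likelihood is tempered,
``p_t(Y | ...) = p(Y | ...)^{beta_t}`` with ``beta_0 = 0``, and each iteration

1. *weights* the particles by the incremental likelihood ratio, which for
   tempering reduces to ``delta_beta * log p(Y | F, L)`` per particle;
2. picks the next temperature adaptively so that the effective sample size of
   those weights equals a fixed fraction ``a`` of ``s`` (bisection on
   ``delta_beta``, jumping straight to 1 when the weights stay diverse);
3. *resamples* with replacement in proportion to the weights (systematic by
   default), resetting weights to uniform;
4. *mutates* every particle independently with a number of Gibbs cycles at
   the current temperature, restoring particle diversity.

Once ``beta = 1`` the particles are draws from the posterior; a final extra
mutation pass diversifies duplicates left by the last resampling.  The sum of
the per-iteration log-mean incremental weights estimates the log evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .mcmc import GibbsSampler
from .model import (
    ModelState,
    WishartProcessConfig,
    construct_sigma,
    sample_prior_state,
)

__all__ = [
    "SMCConfig",
    "ParticleSet",
    "init_particles",
    "incremental_log_weights",
    "effective_sample_size",
    "next_temperature",
    "resample",
    "mutate",
    "run_smc",
]


@dataclass(frozen=True)
class SMCConfig:
    """Settings of the SMC sampler.

    ``n_particles`` defaults to the full-scale value (1000); desk-scale runs
    pass smaller values.  ``ess_fraction`` is the target fraction ``a`` of
    independent particles used to choose each temperature increment.
    """

    n_particles: int = 1000
    ess_fraction: float = 0.5
    mutation_steps: int = 20
    resampler: str = "systematic"
    rw_step: float = 0.01
    rw_step_L: float | None = None  # defaults to rw_step
    max_iterations: int = 1000
    sample_theta: bool = True
    sample_L: bool = True
    jitter: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if not 0.0 < self.ess_fraction < 1.0:
            raise ValueError("ess_fraction must be in (0, 1)")
        if self.resampler not in ("systematic", "multinomial"):
            raise ValueError("resampler must be 'systematic' or 'multinomial'")
        if self.mutation_steps < 0:
            raise ValueError("mutation_steps must be nonnegative")


@dataclass
class ParticleSet:
    """Particles, log-weights, current temperature, and per-iteration history."""

    particles: list[ModelState]
    log_weights: np.ndarray
    beta: float = 0.0
    history: list[dict] = field(default_factory=list)
    caches: list[dict] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.particles)

    def normalised_weights(self) -> np.ndarray:
        lw = self.log_weights - logsumexp(self.log_weights)
        return np.exp(lw)


def init_particles(
    model_config: WishartProcessConfig,
    x: np.ndarray,
    smc_config: SMCConfig,
    sampler: GibbsSampler | None = None,
) -> ParticleSet:
    """Prior-drawn particles with uniform weights at ``beta = 0``."""
    s = smc_config.n_particles
    seeds = np.random.SeedSequence(smc_config.seed).spawn(s)
    particles = []
    caches = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        st = sample_prior_state(
            model_config, x, rng, jitter=smc_config.jitter,
            sample_theta=smc_config.sample_theta,
        )
        particles.append(st)
        if sampler is not None:
            caches.append(sampler.make_cache(st))
    return ParticleSet(
        particles=particles,
        log_weights=np.full(s, -np.log(s)),
        beta=0.0,
        caches=caches,
    )


def incremental_log_weights(logliks: np.ndarray, delta_beta: float) -> np.ndarray:
    """Per-particle log incremental weight under likelihood tempering.

    The ratio ``p_t / p_{t-1}`` of tempered likelihoods reduces to
    ``delta_beta * log p(Y | F, L)``; non-finite log-likelihoods give weight
    ``-inf`` (the particle is effectively discarded at resampling).
    """
    if delta_beta < 0:
        raise ValueError("delta_beta must be nonnegative")
    logliks = np.asarray(logliks, dtype=float)
    out = delta_beta * logliks
    out[~np.isfinite(logliks)] = -np.inf
    if delta_beta == 0.0:
        out = np.zeros_like(out)
        out[~np.isfinite(logliks)] = -np.inf
    return out


def effective_sample_size(log_weights: np.ndarray) -> float:
    """ESS ``1 / sum w_bar_i^2`` of normalised weights; in ``[1, s]``."""
    lw = np.asarray(log_weights, dtype=float)
    norm = logsumexp(lw)
    if not np.isfinite(norm):
        raise ValueError("all weights are zero")
    return float(np.exp(-logsumexp(2.0 * (lw - norm))))


def next_temperature(
    logliks: np.ndarray,
    a: float,
    current_beta: float,
    tol: float = 1e-6,
) -> float:
    """The next tempering temperature, via bisection on the ESS condition.

    Solves ``ESS(delta_beta * loglik) = a * s`` for ``delta_beta`` in
    ``(0, 1 - current_beta]``; if even the full remaining jump keeps the ESS
    at or above the target, returns 1 (final iteration).
    """
    if not 0.0 < a < 1.0:
        raise ValueError("a must be in (0, 1)")
    if current_beta >= 1.0:
        raise ValueError("current_beta must be below 1")
    logliks = np.asarray(logliks, dtype=float)
    finite = np.isfinite(logliks)
    if not finite.any():
        raise ValueError("no particle has a finite log-likelihood")
    s = logliks.size
    target = a * s

    def ess_at(delta: float) -> float:
        return effective_sample_size(incremental_log_weights(logliks, delta))

    hi = 1.0 - current_beta
    if ess_at(hi) >= target:
        return 1.0
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ess_at(mid) >= target:
            lo = mid
        else:
            hi = mid
    delta = 0.5 * (lo + hi)
    return min(current_beta + max(delta, tol), 1.0)


def _systematic_indices(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    s = weights.size
    positions = (rng.uniform() + np.arange(s)) / s
    return np.searchsorted(np.cumsum(weights), positions).clip(max=s - 1)


def resample(
    pset: ParticleSet,
    rng: np.random.Generator,
    method: str = "systematic",
) -> ParticleSet:
    """Resample particles with replacement in proportion to their weights.

    Low-weight particles are discarded and high-weight ones duplicated;
    weights reset to uniform.  Both schemes are unbiased (expected copy count
    ``s * w_bar_i``); systematic resampling has lower variance and maps
    uniform weights to the identity.
    """
    w = pset.normalised_weights()
    s = pset.size
    if method == "systematic":
        idx = _systematic_indices(w, rng)
    elif method == "multinomial":
        idx = rng.choice(s, size=s, replace=True, p=w)
    else:
        raise ValueError(f"unknown resampler {method!r}")
    particles = [pset.particles[i].copy() for i in idx]
    caches = [dict(pset.caches[i]) for i in idx] if pset.caches else []
    return ParticleSet(
        particles=particles,
        log_weights=np.full(s, -np.log(s)),
        beta=pset.beta,
        history=pset.history,
        caches=caches,
    )


def mutate(
    pset: ParticleSet,
    sampler: GibbsSampler,
    beta: float,
    n_steps: int,
    seed: np.random.SeedSequence | int,
) -> np.ndarray:
    """Advance every particle by ``n_steps`` Gibbs cycles at exponent ``beta``.

    Particles are mutated independently, each consuming randomness only from
    its own generator spawned from ``seed``, so the result does not depend on
    execution order: a concurrent implementation with the same sub-seeds is
    bit-identical to this sequential one.  Returns the final data
    log-likelihood of every particle.
    """
    if len(pset.caches) != pset.size:
        raise ValueError("particle set has no Gram caches; initialise with a sampler")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(pset.size)
    logliks = np.empty(pset.size)
    for i, (state, cache, child) in enumerate(
        zip(pset.particles, pset.caches, child_seeds)
    ):
        rng = np.random.default_rng(child)
        ll = None
        for _ in range(n_steps):
            ll = sampler.gibbs_cycle(state, cache, beta, rng, ll)
        logliks[i] = sampler.loglik(state) if ll is None else ll
    return logliks


@dataclass
class SMCResult:
    """Posterior particles with provenance: temperature ladder and evidence."""

    particles: list[ModelState]
    log_weights: np.ndarray
    history: list[dict]
    log_evidence: float
    n_iterations: int
    collapsed: bool

    def sigma_samples(self) -> np.ndarray:
        return np.stack([construct_sigma(p.F, p.L) for p in self.particles])

    def hyperparam_samples(self) -> dict[str, np.ndarray]:
        names = self.particles[0].kernel.param_names
        values = np.array([p.kernel.param_vector() for p in self.particles])
        return {name: values[:, k] for k, name in enumerate(names)}

    def posterior_mean_params(self) -> dict[str, float]:
        """Weighted posterior mean of each kernel hyperparameter."""
        w = np.exp(self.log_weights - logsumexp(self.log_weights))
        return {
            name: float(np.sum(w * draws))
            for name, draws in self.hyperparam_samples().items()
        }


def run_smc(
    x: np.ndarray,
    Y: np.ndarray,
    model_config: WishartProcessConfig,
    smc_config: SMCConfig,
    beta_schedule: list[float] | None = None,
    progress: bool = False,
) -> SMCResult:
    """Full adaptive-tempering SMC run; returns posterior particles.

    ``beta_schedule`` overrides the adaptive temperature choice with a fixed
    increasing ladder ending at 1 (a single-element ``[1.0]`` schedule makes
    the run equivalent to plain importance sampling from the prior).
    """
    x = np.asarray(x, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float)
    cfg = smc_config
    if beta_schedule is not None:
        sched = list(beta_schedule)
        if not sched or sched[-1] != 1.0 or any(
            b2 <= b1 for b1, b2 in zip(sched, sched[1:])
        ):
            raise ValueError("beta_schedule must increase and end at 1.0")
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
    loop_seed = np.random.SeedSequence(cfg.seed).spawn(2)[1]
    pset = init_particles(model_config, x, cfg, sampler=sampler)
    # init_particles derives its own particle seeds from cfg.seed; the loop
    # uses an independent stream for resampling and mutation
    loop_rng = np.random.default_rng(loop_seed)
    mutation_seeds = loop_seed.spawn(cfg.max_iterations + 1)
    logliks = np.array([sampler.loglik(p) for p in pset.particles])
    log_evidence = 0.0
    t = 0
    collapse_count = 0
    while pset.beta < 1.0 and t < cfg.max_iterations:
        if beta_schedule is not None:
            new_beta = sched[min(t, len(sched) - 1)]
        else:
            new_beta = next_temperature(logliks, cfg.ess_fraction, pset.beta)
        delta = new_beta - pset.beta
        incr = incremental_log_weights(logliks, delta)
        log_evidence += float(logsumexp(incr) - np.log(pset.size))
        pset.log_weights = pset.log_weights + incr
        ess = effective_sample_size(pset.log_weights)
        if ess <= 1.0 + 1e-9:
            collapse_count += 1
        pset.history.append(
            {
                "iteration": t,
                "beta": new_beta,
                "delta_beta": delta,
                "ess": ess,
                "log_evidence": log_evidence,
            }
        )
        pset = resample(pset, loop_rng, cfg.resampler)
        pset.beta = new_beta
        logliks = mutate(pset, sampler, new_beta, cfg.mutation_steps, mutation_seeds[t])
        if progress:  # pragma: no cover
            print(
                f"smc iter {t}: beta={new_beta:.5f} delta={delta:.5f} ess={ess:.1f}"
            )
        t += 1
    # final diversification pass at beta = 1
    mutate(pset, sampler, 1.0, cfg.mutation_steps, mutation_seeds[t])
    return SMCResult(
        particles=pset.particles,
        log_weights=pset.log_weights,
        history=pset.history,
        log_evidence=log_evidence,
        n_iterations=t,
        collapsed=collapse_count >= 2,
    )
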