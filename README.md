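# gwproc — dynamic covariance with generalised Wishart processes

Many questions in psychology, neuroscience, and econometrics are about how
the *covariance* between several time series changes — across time,
medication dosage, age, or any other scalar index.  `gwproc` models an
input-dependent covariance matrix Σ(x) with a generalised Wishart process
and infers its full posterior distribution, which in turn supports
out-of-sample prediction of covariance and a hypothesis test for whether a
pair of variables is uncorrelated, statically correlated, or dynamically
correlated.

## Model

Observations yᵢ ∈ R^d at input locations xᵢ (arbitrarily spaced) follow

    y_i ~ MVN_d(0, Σ(x_i)),
    Σ(x_i) = Σ_{l=1..v} (L f_l(x_i)) (L f_l(x_i))ᵀ,
    f_jl ~ GP(0, κ_θ)   i.i.d. for j = 1..d, l = 1..v,
    L_jo ~ N(0, 1)      on the free lower-triangular entries,
    θ    ~ log-normal priors per kernel parameter.

When κ(x, x) = 1, each Σ(xᵢ) is marginally Wishart W_d(V, v) with
V = LLᵀ.  The kernel κ_θ (RBF, Matérn-1/2, Periodic, Locally Periodic, or
an RBF+Matérn-1/2 sum) sets how quickly — and whether periodically — the
covariance changes.

Three interchangeable inference backends return posterior draws of
{F, θ, L} and hence of the covariance process:

- **SMC** (the workhorse): an adaptive-tempering Sequential Monte Carlo
  sampler — prior-initialised particles, likelihood tempering
  p(Y|·)^β with β chosen so the effective sample size of the incremental
  weights stays at a fixed fraction of the particle count, systematic
  resampling, and Gibbs-cycle mutation.  Robust to the multimodal
  posteriors of composite kernels.
- **MCMC**: Gibbs sampling with elliptical slice updates for the latent
  GPs and random-walk Metropolis for θ and L, with Gelman–Rubin (PSRF)
  convergence control across chains.
- **VI**: a fast variational baseline with full-rank Gaussian posteriors
  per latent GP and point-estimated θ, L.

See `docs/methods.md` for assumptions, parameter meanings, and numerical
choices.

## Worked example

Recover a rapidly switching correlation structure and test for dynamics:

```python
import numpy as np
from gwproc import (KernelSpec, SMCConfig, WishartProcessConfig,
                    run_smc, mse_sigma)
from gwproc.metrics import pairwise_dynamics
from gwproc.simdata import simulate_state_switching, train_test_split

# d=3 series; every off-diagonal covariance alternates 0 <-> 0.8 every 50
# observations (one full cycle = 1/3 input units), variances 1
bundle = simulate_state_switching(seed=11, n=600)
train, test = train_test_split(bundle, n_train=300)

kernel = KernelSpec("periodic", {"period": 1.0, "per_lengthscale": 1.0})
model = WishartProcessConfig(d=3, v=4, kernel=kernel)
smc = SMCConfig(n_particles=256, mutation_steps=6,
                rw_step=0.01, rw_step_L=0.3, seed=7)
result = run_smc(train.x, train.Y, model, smc)

period = result.posterior_mean_params()["period"]
sigma = result.sigma_samples()                  # (draws, n, d, d)
print(f"posterior-mean period: {period:.3f}")
print(f"training MSE of mean covariance: "
      f"{mse_sigma(sigma.mean(axis=0), train.truth):.3f}")
print(pairwise_dynamics(sigma))
```

Output:

```
posterior-mean period: 0.320
training MSE of mean covariance: 0.034
{(0, 1): 'dynamic', (0, 2): 'dynamic', (1, 2): 'dynamic'}
```

The sampler recovers the design period (1/3 input units) from 300 noisy
observations, tracks the square-wave covariance with a mean-squared error
of 0.03, and the HDI+ROPE hypothesis test labels all three pairs
dynamically correlated — as constructed.

## Command line

`gwproc` exposes `simulate`, `fit`, `predict`, `evaluate`, `test-dynamics`,
and `run-experiment`; configuration is a small YAML file (see
`gwproc.config`).  For example:

```bash
gwproc simulate --design state-switching --seed 11 --out data/
gwproc fit --backend smc --config config.yaml --data data/data.csv --out post/
gwproc test-dynamics --posterior post/
```

`scale: paper` in the config selects the full-scale sampler settings
(1000 particles, thousands of mutation steps, thinning 1000); `scale: desk`
selects small settings for quick runs.

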