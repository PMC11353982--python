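# Methods

## Model

`gwproc` estimates an input-dependent covariance matrix Σ(x) ∈ R^{d×d} for a
multivariate series Y ∈ R^{n×d} observed at scalar input locations
x₁,…,xₙ (time, age, dosage — any ordering variable; the locations may be
unevenly spaced).  The generative model is a generalised Wishart process:

- d·v latent functions f_jl ~ GP(0, κ_θ), i.i.d., with a shared stationary
  kernel κ_θ;
- a lower-triangular scale factor L with independent N(0,1) priors on its
  free entries, V = LLᵀ;
- Σ(xᵢ) = Σ_{l=1..v} (L f_l(xᵢ))(L f_l(xᵢ))ᵀ, so that when κ(x,x)=1 each
  marginal Σ(xᵢ) is Wishart W_d(V, v);
- yᵢ ~ MVN(mᵢ, Σ(xᵢ)) with a zero mean by default.

The kernel controls the temporal character of the covariance process: `rbf`
gives smooth slow dynamics, `matern12` rough dynamics, `periodic` and
`locally_periodic` repeating dynamics, and `sum_rbf_matern12` a mixture of
slow and fast components.  Kernel hyperparameters carry log-normal priors,
by default with location 0 and scale 1 on the natural scale (configurable
per parameter); the priors' parameters are a modelling choice, not a fitted
quantity.

Two conventions worth flagging:

- the sum kernel is *not* normalised: κ(x,x) = 2.  The Wishart marginal
  argument assumes κ(x,x)=1; with the sum kernel the scale matrix V simply
  absorbs the factor.
- the Matérn-1/2 component is parameterised as exp(−|x−x′| / (2 ℓ²)), with
  the lengthscale entering squared.  A common alternative convention is
  exp(−|x−x′|/ℓ); conversions are monotone, so inferences are equivalent up
  to a reparameterisation of the prior.

GP prediction at new inputs uses the standard noiseless conditional
mean K_*x K_xx⁻¹ f and covariance K_** − K_*x K_xx⁻¹ K_*xᵀ, then rebuilds
Σ(x*) from the predicted latents and draws y* from the observation model.

An exponential-moving-average mean (option `mean: ema`) models slow level
changes: row i of the mean is α y_{i−1} + (1−α) y_{i−2} + … +
(1−α)^{k−1} y_{i−k} with α = 2/(k+1), default k = 10.  Note the weights sum
to α + Σ_{m≥1}(1−α)^m ≠ 1 in general; this is the form implemented
(a normalised variant is available behind `normalised=True`).  The EMA is
subtracted from Y before inference and added back for prediction, keeping
the internal likelihood zero-mean.  Early rows use truncated history; row 0
has none and gets mean zero.

## Inference

All three backends target the posterior p(F, θ, L | x, Y) and return a
collection of parameter states from which covariance draws follow
deterministically, so they are interchangeable downstream.

### Gibbs MCMC

One cycle updates three blocks from their conditionals:

1. **Latent GPs** — one elliptical slice sampling move per latent row,
   targeting p(Y|F,L)^β · p(F|θ).  ESS is rejection-free and needs no step
   size; the tempering exponent β is 1 for plain posterior sampling.  At
   β = 0 the move is a rotation with a fresh prior draw and leaves the GP
   prior exactly invariant.
2. **Kernel hyperparameters** — random-walk Metropolis on log θ targeting
   p(F|x,θ)p(θ) (the θ conditional does not involve the data; θ sees Y only
   through F).  The default step is 0.01 in log space.  This conditional is
   extremely sharp — its width shrinks like 1/√(d·v·n) — so θ mixes slowly
   by construction; full runs compensate with heavy thinning and long
   burn-in.
3. **Scale Cholesky** — joint random-walk Metropolis on the d(d+1)/2 free
   entries of L against p(Y|F,L)^β · Π N(L_jo|0,1).  The default step
   matches θ's (0.01); desk-scale configurations use a larger L step
   (≈0.3), which the low-dimensional L conditional tolerates and which
   removes the dependence of short runs on the initial L.

Convergence is monitored by the Gelman–Rubin PSRF over independent chains
(4 by default), computed for every unique Σ_ij(xᵢ) entry, every kernel
hyperparameter, and every entry of V = LLᵀ.  V is monitored instead of L
because column signs of L are not identifiable, so raw L entries never
converge across chains.  The PSRF is truncated at 1 from below (the raw
ratio dips under 1 only by sampling noise); chains count as converged when
the maximum over monitored scalars is below 1.1.  With automatic burn-in
the first half of each chain is discarded and chains are extended until
convergence or a configured cycle cap (then the result is returned flagged
as non-converged).  The merged posterior takes 250 retained draws per chain
uniformly without replacement.

### Adaptive-tempering SMC

The sampler of interest: s particles {F,θ,L} initialised from the prior
with uniform weights, then iteratively

1. weighted by the tempered incremental likelihood Δβ·log p(Y|F,L);
2. the next temperature chosen by bisection so the effective sample size of
   those weights equals a·s (default a = 0.5; if even the full jump to
   β = 1 keeps ESS ≥ a·s the ladder finishes);
3. resampled systematically (multinomial available);
4. mutated by a number of Gibbs cycles at exponent β per particle, with
   independent per-particle generators (results are independent of
   execution order, so mutation can be parallelised bit-identically).

After β = 1 one extra mutation pass diversifies duplicates from the final
resampling.  The sum over iterations of log-mean incremental weights
estimates the log evidence.  Because within-particle θ movement is slow
(see above), the posterior over hyperparameters is represented mainly by
*which* prior-initialised particles survive tempering: particle count s
drives mode discovery (multimodal kernels like the periodic one have
sub-harmonic modes), and mutation steps m drive how well each particle's
latents adapt before selection.  Full-scale settings are s = 1000 with
thousands of mutation steps; the desk-scale experiments in this repository
use s ≈ 200–500 and m ≈ 6–20, which is sufficient for the simulation
studies at reduced reliability (see Limitations).

### Variational baseline

A deliberately simple optimisation-based baseline: independent full-rank
Gaussians q(f_jl) = N(m_jl, C_jl C_jlᵀ), point estimates for θ and L, and a
learned diagonal observation noise Λ (initialised at 0.001) added to every
Σ(xᵢ).  The ELBO
E_q[log p(Y|F,L,Λ)] − Σ KL(q(f_jl) ‖ p(f_jl|θ))
is climbed with Adam (learning rate 0.001 at full scale); the expectation
uses 3 reparameterised Monte Carlo draws, the KL is closed-form.
Optimisation runs in whitened coordinates (f = chol(K)(m_w + C_w ε)): the
family is unchanged but the KL becomes standard-normal-based, removing the
Gram matrix's conditioning from the curvature.  Gradients are analytic
except θ, where the Cholesky factor's derivative is taken by central finite
differences and chained through the (linear) whitening map.  The scale L is
initialised at chol(empirical covariance / v) plus per-restart noise; with
a fully random scale the optimiser crawls along a Σ/Λ identifiability ridge.
Among n_restarts (default 4) random restarts the run with the highest ELBO
is returned.  Because Λ is free, diagonal variance splits between Σ and Λ;
comparisons against empirical covariances should use Σ + Λ.  Stopping:
best ELBO unimproved for a patience window (default 10,000 iterations).

## Evaluation

- `mse_sigma`: squared error between covariance processes, averaged over
  inputs and the d(d+1)/2 unique entries (upper triangle + diagonal), so
  symmetric entries are not double counted.
- `mse_samples`: mean of `mse_sigma` over posterior draws (distribution
  accuracy, not just the mean).
- `avg_loglik`: observation log-likelihood under the posterior-mean
  covariance process, divided by n.
- `predictive_kl`: KL(N(0,Σ_draw(x)) ‖ N(0,Σ_true(x))) averaged over draws
  and inputs; a moment-matched variant (mixture collapsed to its mean
  covariance before the KL) is available behind a flag.
- `hdi`: shortest contiguous interval over sorted samples containing
  ⌈mass·m⌉ of them.
- `dynamics_test`: per input, the 95% HDI of Σ_ij(x) draws widened by the
  ROPE (±0.005); zero inside every widened interval → *uncorrelated*, else
  a nonempty intersection of all intervals → *static* (some constant fits
  everywhere), else *dynamic*.  The zero check takes precedence, and
  widening the ROPE can only move a label towards static/uncorrelated.

## Synthetic data

Two generators define the study conditions:

1. **Wishart-prior draws** (well-specified): RBF kernel with lengthscale
   0.35 on inputs evenly spaced in [0,1], V = I, d = 3, v = 4, n = 300, ten
   datasets sharing the lengthscale and scale matrix but not the latent
   draws.  Scaled-down variants (n = 100, d = 2, v = 2) are used in fast
   tests; note the lengthscale is much more weakly identified there — some
   datasets' marginal likelihoods genuinely peak away from 0.35, so
   parameter-recovery statistics at that scale are fragile by construction,
   not by sampler defect.
2. **State switching** (misspecified): all off-diagonals alternate between
   0 and 0.8 every 50 observations, variances 1, d = 3; n = 600 with the
   first 300 used for training and the rest held out.  Inputs are spaced so
   one full on/off cycle spans exactly 1/3 input units (the value a periodic
   kernel's period should recover).  The first block is uncorrelated
   (configurable).  Fitting uses v = 4, matching the first design's degrees
   of freedom.

Neither generator emulates heavy tails, missing data, or observational
noise beyond the Gaussian model, so passing tests demonstrate correct
inference under the model's own assumptions and under a square-wave
misspecification — not robustness to arbitrary real data.

## Numerical choices

- Gram matrices get diagonal jitter 1e−6, escalated ×10 to at most 1e−2
  before a hard failure; likelihood evaluations add 1e−6 to every Σ(xᵢ)
  slice (this also makes v < d usable).
- The observation likelihood is evaluated by a fused per-slice LDLᵀ kernel
  (compiled with numba when available, with a numpy fallback asserted to
  agree); indefinite slices yield −inf rather than exceptions so samplers
  reject naturally.
- Evenly spaced grids make the Gram Toeplitz: samplers then build it from
  its first row (n kernel evaluations instead of n²).
- Hyperparameters live in log space inside samplers and the VI optimiser;
  densities are evaluated on the natural scale with the Jacobian included.
- The GP predictive conditional uses the standard inverse (the printed
  form of the source model's prediction equation omits it in the mean term).
- Systematic resampling maps exactly-uniform weights to the identity
  permutation; ESS bisection tolerance is 1e−6 on Δβ.

## Limitations

- Within-particle hyperparameter mixing is slow (sharp θ conditional, RW
  step 0.01); at desk scale the SMC hyperparameter posterior can collapse
  to few surviving values (point estimates remain accurate; spreads are
  understated), and occasional runs lock onto sub-harmonic period modes.
  Full-scale settings (1000 particles, thousands of mutation steps)
  resolve this at 10–100× the compute.
- The VI baseline's Λ/Σ split is only weakly identified; its covariance
  point estimates are shrunk relative to sampling-based posteriors,
  mirroring the general behaviour of variational point estimation for this
  model.
- Single scalar inputs only; no missing data; no sparse/inducing-point or
  factored variants.
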