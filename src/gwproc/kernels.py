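"""Gaussian-process covariance functions and their hyperpriors.

Each latent GP in the Wishart process carries a stationary kernel
:math:`\\kappa_\\theta(x, x')` on scalar inputs.  Five kernels are supported:

``rbf``
    squared exponential, ``exp(-(x-x')^2 / (2 l^2))``
``periodic``
    ``exp(-2 sin^2(pi |x-x'| / p) / l_p^2)``
``locally_periodic``
    product of ``periodic`` and ``rbf``
``matern12``
    exponential (Ornstein-Uhlenbeck), ``exp(-|x-x'| / (2 l^2))`` -- see note
``sum_rbf_matern12``
    sum of ``rbf`` and ``matern12`` (not normalised: ``k(x,x) = 2``)

All hyperparameters are strictly positive and carry independent log-normal
priors, by default with location 0 and scale 1 on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KernelSpec",
    "KERNEL_PARAM_NAMES",
    "evaluate_kernel",
    "kernel_from_dist",
    "gram_matrix",
    "gram_cholesky",
    "log_hyperprior",
]

#: parameter names required by each kernel kind, in canonical order
KERNEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "rbf": ("lengthscale",),
    "periodic": ("period", "per_lengthscale"),
    "locally_periodic": ("period", "per_lengthscale", "lengthscale"),
    "matern12": ("m12_lengthscale",),
    "sum_rbf_matern12": ("lengthscale", "m12_lengthscale"),
}

DEFAULT_PRIOR = (0.0, 1.0)  # log-normal (location, scale) on the natural scale

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class KernelSpec:
    """A kernel kind, its positive hyperparameters, and their log-normal priors.

    Parameters
    ----------
    kind
        One of the keys of :data:`KERNEL_PARAM_NAMES`.
    params
        Mapping from parameter name to a strictly positive value.  Exactly
        the names required by ``kind`` must be present.
    prior
        Mapping from parameter name to a ``(location, scale)`` pair of the
        log-normal prior.  Missing entries default to ``(0, 1)``.
    """

    kind: str
    params: dict[str, float]
    prior: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_PARAM_NAMES:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        required = KERNEL_PARAM_NAMES[self.kind]
        missing = set(required) - set(self.params)
        extra = set(self.params) - set(required)
        if missing or extra:
            raise ValueError(
                f"kernel {self.kind!r} requires parameters {required}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        for name, value in self.params.items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"kernel parameter {name!r} must be positive, got {value}")
        for name, (_, scale) in self.prior.items():
            if name not in required:
                raise ValueError(f"prior given for unknown parameter {name!r}")
            if scale <= 0:
                raise ValueError(f"prior scale for {name!r} must be positive")

    @property
    def param_names(self) -> tuple[str, ...]:
        return KERNEL_PARAM_NAMES[self.kind]

    def param_vector(self) -> np.ndarray:
        """Hyperparameters as an array in canonical order."""
        return np.array([self.params[p] for p in self.param_names], dtype=float)

    def with_params(self, values: np.ndarray | dict[str, float]) -> "KernelSpec":
        """A copy of this spec with replaced parameter values."""
        if isinstance(values, dict):
            new = dict(values)
        else:
            new = dict(zip(self.param_names, (float(v) for v in values)))
        return replace(self, params=new)

    def prior_for(self, name: str) -> tuple[float, float]:
        return self.prior.get(name, DEFAULT_PRIOR)


def kernel_from_dist(spec: KernelSpec, dist: np.ndarray) -> np.ndarray:
    """Evaluate the kernel elementwise on an array of absolute distances.

    Stationary kernels only depend on ``|x - x'|``; samplers precompute the
    pairwise distance matrix of the grid once and re-evaluate the kernel on
    it for every hyperparameter proposal.
    """
    dist = np.asarray(dist, dtype=float)
    p = spec.params
    if spec.kind == "rbf":
        return np.exp(-0.5 * (dist / p["lengthscale"]) ** 2)
    if spec.kind == "periodic":
        s = np.sin(np.pi * dist / p["period"])
        return np.exp(-2.0 * (s / p["per_lengthscale"]) ** 2)
    if spec.kind == "locally_periodic":
        s = np.sin(np.pi * dist / p["period"])
        return np.exp(
            -2.0 * (s / p["per_lengthscale"]) ** 2 - 0.5 * (dist / p["lengthscale"]) ** 2
        )
    if spec.kind == "matern12":
        return np.exp(-dist / (2.0 * p["m12_lengthscale"] ** 2))
    if spec.kind == "sum_rbf_matern12":
        return np.exp(-0.5 * (dist / p["lengthscale"]) ** 2) + np.exp(
            -dist / (2.0 * p["m12_lengthscale"] ** 2)
        )
    raise ValueError(f"unknown kernel kind {spec.kind!r}")  # pragma: no cover


def evaluate_kernel(spec: KernelSpec, x: float, x_prime: float) -> float:
    """Evaluate ``kappa_theta(x, x')`` for scalar inputs."""
    return float(kernel_from_dist(spec, np.abs(np.asarray(x) - np.asarray(x_prime))))


def cross_kernel(spec: KernelSpec, x: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Kernel matrix between two input vectors, shape ``(len(x), len(x2))``."""
    x = np.asarray(x, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    return kernel_from_dist(spec, np.abs(x[:, None] - x2[None, :]))


def gram_matrix(spec: KernelSpec, x: np.ndarray, jitter: float = 0.0) -> np.ndarray:
    """Symmetric Gram matrix of the kernel on a grid, plus ``jitter * I``."""
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    K = cross_kernel(spec, x, x)
    if jitter:
        K = K + jitter * np.eye(K.shape[0])
    return K


def gram_cholesky(
    spec: KernelSpec,
    x: np.ndarray,
    jitter: float = 1e-6,
    max_jitter: float = 1e-2,
    dist: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of the Gram matrix, escalating jitter on failure.

    Jitter starts at ``jitter`` and is multiplied by 10 until the factorisation
    succeeds or ``max_jitter`` is exceeded, in which case the grid is
    numerically degenerate and a ``LinAlgError`` is raised.

    Returns the factor and the jitter actually used.
    """
    if dist is None:
        x = np.asarray(x, dtype=float).ravel()
        dist = np.abs(x[:, None] - x[None, :])
    K = kernel_from_dist(spec, dist)
    eye = np.eye(K.shape[0])
    j = jitter
    while True:
        try:
            return np.linalg.cholesky(K + j * eye), j
        except np.linalg.LinAlgError:
            j = 10.0 * j if j > 0 else 1e-8
            if j > max_jitter:
                raise np.linalg.LinAlgError(
                    f"Gram matrix not positive definite up to jitter {max_jitter}"
                )


def log_hyperprior(spec: KernelSpec, params: np.ndarray | None = None) -> float:
    """Sum of log-normal log-densities over the kernel's hyperparameters.

    Non-positive parameter values yield ``-inf`` rather than an exception so
    that Metropolis samplers reject such proposals naturally.
    """
    values = spec.param_vector() if params is None else np.asarray(params, dtype=float)
    total = 0.0
    for value, name in zip(values, spec.param_names):
        if not np.isfinite(value) or value <= 0:
            return -np.inf
        mu, sigma = spec.prior_for(name)
        z = (np.log(value) - mu) / sigma
        total += -np.log(value * sigma) - 0.5 * _LOG_2PI - 0.5 * z * z
    return float(total)


def sample_hyperparams(spec: KernelSpec, rng: np.random.Generator) -> KernelSpec:
    """Draw fresh hyperparameters from their log-normal priors."""
    new = {}
    for name in spec.param_names:
        mu, sigma = spec.prior_for(name)
        new[name] = float(rng.lognormal(mean=mu, sigma=sigma))
    return spec.with_params(new)
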