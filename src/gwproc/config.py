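"""Run configuration: schema, presets, and strict validation.

A run configuration is a small YAML/JSON mapping with sections ``model``,
``backend``, per-backend settings, and (for experiments) ``simulation``.
Unknown keys anywhere are rejected before any computation starts.  The
``scale`` preset fills backend defaults: ``paper`` encodes the full-scale
sampler settings (1000 particles, thousands of mutation steps, thinning
1000, 250 draws kept per chain), ``desk`` a small configuration for quick
runs; explicit keys override the preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kernels import KernelSpec
from .mcmc import MCMCConfig
from .model import WishartProcessConfig
from .smc import SMCConfig
from .vi import VIConfig

__all__ = ["RunConfig", "load_run_config", "run_config_from_dict"]

_PRESETS: dict[str, dict[str, dict]] = {
    "paper": {
        "smc": {"n_particles": 1000, "mutation_steps": 3000},
        "mcmc": {"thinning": 1000, "samples_per_chain_kept": 250,
                 "max_cycles": 10_000_000},
        "vi": {"max_iters": 300_000, "patience": 10_000, "learning_rate": 0.001},
    },
    "desk": {
        "smc": {"n_particles": 100, "mutation_steps": 5},
        "mcmc": {"thinning": 5, "samples_per_chain_kept": 100, "max_cycles": 20_000,
                 "rw_step": 0.1},
        "vi": {"max_iters": 2000, "patience": 500, "learning_rate": 0.01,
               "n_restarts": 2, "n_sigma_draws": 100},
    },
}

_SIM_KEYS = {"design", "n", "d", "v", "lengthscale", "block", "rho", "n_train",
             "dataset_index", "x_max", "x_range", "first_block_correlated",
             "n_datasets"}


@dataclass
class RunConfig:
    """Validated configuration of one inference run or experiment."""

    model: WishartProcessConfig
    backend: str
    backend_config: MCMCConfig | SMCConfig | VIConfig
    seed: int = 0
    scale: str = "desk"
    simulation: dict = field(default_factory=dict)


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {section}: {sorted(unknown)}")


def _kernel_from_dict(raw: dict) -> KernelSpec:
    _check_keys("model.kernel", raw, {"kind", "params", "prior"})
    prior = {
        name: (float(pair[0]), float(pair[1]))
        for name, pair in (raw.get("prior") or {}).items()
    }
    params = {k: float(v) for k, v in (raw.get("params") or {}).items()}
    return KernelSpec(raw["kind"], params, prior)


def run_config_from_dict(raw: dict) -> RunConfig:
    _check_keys(
        "config", raw,
        {"model", "backend", "seed", "scale", "simulation", "mcmc", "smc", "vi"},
    )
    backend = raw.get("backend", "smc")
    if backend not in ("mcmc", "smc", "vi"):
        raise ValueError(f"backend must be mcmc, smc or vi, got {backend!r}")
    scale = raw.get("scale", "desk")
    if scale not in _PRESETS:
        raise ValueError(f"scale must be one of {sorted(_PRESETS)}")
    seed = int(raw.get("seed", 0))

    model_raw = dict(raw.get("model") or {})
    _check_keys("model", model_raw, {"d", "v", "kernel", "mean", "ema_k"})
    if "kernel" not in model_raw:
        raise ValueError("model.kernel is required")
    kernel = _kernel_from_dict(model_raw["kernel"])
    model = WishartProcessConfig(
        d=int(model_raw.get("d", 3)),
        v=int(model_raw.get("v", int(model_raw.get("d", 3)) + 1)),
        kernel=kernel,
        mean=model_raw.get("mean", "zero"),
        ema_k=int(model_raw.get("ema_k", 10)),
    )

    cls = {"mcmc": MCMCConfig, "smc": SMCConfig, "vi": VIConfig}[backend]
    settings = dict(_PRESETS[scale].get(backend, {}))
    overrides = dict(raw.get(backend) or {})
    allowed = set(cls.__dataclass_fields__)
    _check_keys(backend, overrides, allowed)
    settings.update(overrides)
    settings["seed"] = int(settings.get("seed", seed))
    backend_config = cls(**settings)

    simulation = dict(raw.get("simulation") or {})
    _check_keys("simulation", simulation, _SIM_KEYS)
    return RunConfig(
        model=model,
        backend=backend,
        backend_config=backend_config,
        seed=seed,
        scale=scale,
        simulation=simulation,
    )


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return run_config_from_dict(raw)
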