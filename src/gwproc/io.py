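"""Dataset readers/writers and posterior serialisation.

Datasets are CSV with a header; the first column holds the input locations
``x`` and the remaining columns the observed variables.  Posterior
covariance draws are stored as a compressed ``.npz`` array container with a
JSON sidecar recording the axis names, configuration hash, and seeds, so
that every backend's output is interchangeable downstream.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_dataset",
    "write_dataset",
    "save_posterior",
    "load_posterior",
    "config_hash",
]

SIGMA_AXES = ("draw", "input", "row", "col")


def read_dataset(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read ``(x, Y, column_names)`` from a delimited text file.

    The first column is the input grid; at least one observation column must
    follow.  Malformed cells are reported with their row and column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    names = [h.strip() for h in header]
    if len(names) < 2:
        raise ValueError(f"{path}: need an x column plus at least one value column")
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate header names {names}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in df.columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or missing cell at row {int(bad[0]) + 2}, "
                f"column {col!r}"
            )
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite values present")
    return values[:, 0], values[:, 1:], list(df.columns)


def write_dataset(
    path: str | Path,
    x: np.ndarray,
    Y: np.ndarray,
    columns: list[str] | None = None,
) -> None:
    """Write ``(x, Y)`` as CSV with 17 significant digits (roundtrip-exact)."""
    x = np.asarray(x, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float)
    if columns is None:
        columns = ["x"] + [f"y{j + 1}" for j in range(Y.shape[1])]
    df = pd.DataFrame(np.column_stack([x, Y]), columns=columns)
    df.to_csv(path, index=False, float_format="%.17g")


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def save_posterior(
    out_dir: str | Path,
    sigma_samples: np.ndarray,
    x: np.ndarray,
    meta: dict,
    hyperparams: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write posterior covariance draws plus provenance to a directory.

    ``sigma_samples`` has axes ``(draw, input, row, col)``.  Returns the
    directory path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {"sigma": np.asarray(sigma_samples), "x": np.asarray(x, dtype=float)}
    if hyperparams:
        for name, draws in hyperparams.items():
            arrays[f"hyper_{name}"] = np.asarray(draws)
    np.savez_compressed(out_dir / "posterior.npz", **arrays)
    sidecar = {
        "axes": {"sigma": list(SIGMA_AXES), "x": ["input"]},
        "config_hash": config_hash(meta),
        **meta,
    }
    with open(out_dir / "posterior.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)
    return out_dir


def load_posterior(
    post_dir: str | Path,
) -> tuple[np.ndarray, np.ndarray, dict, dict[str, np.ndarray]]:
    """Read back ``(sigma_samples, x, meta, hyperparams)`` written by save_posterior."""
    post_dir = Path(post_dir)
    with np.load(post_dir / "posterior.npz") as data:
        sigma = data["sigma"]
        x = data["x"]
        hyper = {
            key[len("hyper_") :]: data[key]
            for key in data.files
            if key.startswith("hyper_")
        }
    with open(post_dir / "posterior.json") as fh:
        meta = json.load(fh)
    return sigma, x, meta, hyper
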