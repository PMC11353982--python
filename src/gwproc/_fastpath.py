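"""Compiled hot path for the samplers' likelihood evaluations.

The elliptical-slice updates evaluate the full Gaussian observation
log-likelihood thousands of times per Gibbs cycle.  This module provides a
fused "build Sigma slices and accumulate the log-density" kernel compiled
with numba; :mod:`gwproc.model` holds the plain numpy reference
implementation, and the samplers fall back to it when numba is unavailable.
Both paths are asserted to agree in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _loglik_fused(F: np.ndarray, L: np.ndarray, resid: np.ndarray, jitter: float) -> float:
    # LDL^T factorisation per covariance slice: no square roots and a single
    # log per input keep the inner loop arithmetic-bound
    d, v, n = F.shape
    log_2pi = 1.8378770664093453
    total = -0.5 * n * d * log_2pi
    S = np.empty((d, d))
    u = np.empty(d)
    z = np.empty(d)
    D = np.empty(d)
    for i in range(n):
        for a in range(d):
            for b in range(a + 1):
                S[a, b] = 0.0
            S[a, a] = jitter
        for l in range(v):
            for a in range(d):
                acc = 0.0
                for b in range(d):
                    acc += L[a, b] * F[b, l, i]
                u[a] = acc
            for a in range(d):
                for b in range(a + 1):
                    S[a, b] += u[a] * u[b]
        # in-place unit-lower LDL^T of the lower triangle
        det = 1.0
        for a in range(d):
            acc = S[a, a]
            for k in range(a):
                acc -= S[a, k] * S[a, k] * D[k]
            if acc <= 0.0 or not np.isfinite(acc):
                return -np.inf
            D[a] = acc
            det *= acc
            for b in range(a + 1, d):
                acc = S[b, a]
                for k in range(a):
                    acc -= S[b, k] * S[a, k] * D[k]
                S[b, a] = acc / D[a]
        # forward solve (unit lower) and accumulate the quadratic form
        quad = 0.0
        for a in range(d):
            acc = resid[i, a]
            for k in range(a):
                acc -= S[a, k] * z[k]
            z[a] = acc
            quad += acc * acc / D[a]
        total += -0.5 * (np.log(det) + quad)
    return total


def state_loglik(F: np.ndarray, L: np.ndarray, resid: np.ndarray, jitter: float) -> float:
    """Log-likelihood of observations given latents and scale (fast path)."""
    if HAVE_NUMBA:
        val = _loglik_fused(F, L, resid, jitter)
        return float(val) if np.isfinite(val) else -np.inf
    from .model import construct_sigma, mvn_logpdf_sum

    return mvn_logpdf_sum(resid, construct_sigma(F, L), jitter=jitter)
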