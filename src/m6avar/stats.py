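"""Shared statistical primitives: BH correction and hypergeometric tails.

A single Benjamini-Hochberg implementation serves every module (peak
classification, VSEA batches, chromosome and annotation permutation tests)
so the correction is identical everywhere it is applied.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps

__all__ = ["benjamini_hochberg", "hypergeom_tail", "permutation_pvalue"]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]

    Returns
    -------
    numpy.ndarray
        Adjusted p-values in the input order, each >= its raw p and <= 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    # step-up: enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def hypergeom_tail(N: int, K: int, m: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, m).

    N is the population size, K the number of marked items, m the sample
    size, k the threshold count. Survival functions are evaluated through
    scipy's log-space-stable hypergeometric implementation.
    """
    for name, v in (("N", N), ("K", K), ("m", m), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if k > m or m > N or K > N:
        raise ValueError(f"require 0 <= k <= m <= N and K <= N, got N={N} K={K} m={m} k={k}")
    if k == 0:
        return 1.0
    if k > K:
        return 0.0
    return float(_sps.hypergeom.sf(k - 1, N, K, m))


def permutation_pvalue(null_ge_count: int, n_perm: int) -> float:
    """Add-one permutation p-value (1 + b) / (1 + n): never exactly zero."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    return (1 + null_ge_count) / (1 + n_perm)
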