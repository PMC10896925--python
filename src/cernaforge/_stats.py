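"""Shared statistical primitives.

The hypergeometric upper tail drives both the shared-miRNA test on candidate
ceRNA pairs and gene-set over-representation.  Both callers route through the
single implementation here, so the two stages can never disagree on identical
(N, K, n, k).
"""
from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: population (universe) size; K: marked items; n: draws; k: observed
    marked draws.  Returns 1.0 for k <= 0 (the upper tail at or below zero
    is the whole distribution).
    """
    if N <= 0:
        raise ValueError("hypergeometric universe size N must be positive")
    if not (0 <= K <= N):
        raise ValueError(f"K={K} outside [0, N={N}]")
    if not (0 <= n <= N):
        raise ValueError(f"n={n} outside [0, N={N}]")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (same order as input)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def pearson_matrix(X: np.ndarray, Y: np.ndarray):
    """Pearson r and two-sided p for every row of X against every row of Y.

    X is (nx, s) and Y is (ny, s); returns (R, P) of shape (nx, ny).
    Rows with zero variance yield NaN in both outputs.  p is from the exact
    t distribution with s - 2 degrees of freedom, the same null as
    scipy.stats.pearsonr.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    s = X.shape[1]
    if Y.shape[1] != s:
        raise ValueError("sample dimensions differ")
    if s < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")

    def _standardize(A):
        mu = A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (A - mu) / sd
        Z[np.broadcast_to(sd == 0, Z.shape)] = np.nan
        return Z

    R = _standardize(X) @ _standardize(Y).T / s
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = R * np.sqrt((s - 2) / (1.0 - R * R))
    P = 2.0 * stats.t.sf(np.abs(t), df=s - 2)
    P[np.abs(R) == 1.0] = 0.0
    P[np.isnan(R)] = np.nan
    return R, P
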