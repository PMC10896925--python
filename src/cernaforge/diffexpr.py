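"""Negative-binomial differential expression.

Counts are normalized by median-of-ratios size factors, per-feature
dispersion comes from a pooled within-group method-of-moments estimate, and
significance is a Wald test on the difference of log group means with the
delta-method variance Var(log mu_g) ~ 1/(n_g mu_g) + alpha/n_g.  This is a
deliberately transparent NB variant of the DESeq2-style analysis: no
shrinkage, no GLM, every formula testable by hand.  DE calls use
|log2FC| >= 1 (inclusive) and adjusted p < 0.05 (strict) by default.

A 2^-ddCt helper covers relative RT-qPCR quantification against an
endogenous control and a calibrator condition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .quantify import CountMatrix

logger = logging.getLogger("cernaforge")

#: pseudo-mean added to group means in the fold change (and its variance)
#: so zero groups yield finite log2FC
PSEUDO_MEAN = 0.5

DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 10.0


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    The reference is the per-feature geometric mean across samples over
    features with strictly positive counts everywhere; each sample's factor
    is the median ratio of its counts to the reference.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature with positive counts in every sample; size factors "
            "are undefined (consider adding a pseudocount)")
    logs = np.log(arr[all_pos])
    log_ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_ref, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def estimate_dispersion(counts: CountMatrix, factors: pd.Series) -> pd.Series:
    """Method-of-moments NB dispersion alpha per feature.

    alpha = (pooled within-group variance - mean) / mean^2 on normalized
    counts, clamped to [1e-8, 10].  Poisson-like or constant features hit
    the floor; zero-mean features are floored with a warning.
    """
    norm = counts.counts.div(factors, axis=1)
    groups = counts.groups
    n_tot, ss = 0, np.zeros(len(norm))
    for _, cols in groups.groupby(groups).groups.items():
        sub = norm[cols].to_numpy(dtype=float)
        if sub.shape[1] >= 2:
            ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
            n_tot += sub.shape[1] - 1
    mean = norm.mean(axis=1).to_numpy(dtype=float)
    if n_tot == 0:
        logger.warning("no replicated group; dispersion floored for all "
                       "features")
        alpha = np.full(len(norm), DISPERSION_FLOOR)
    else:
        var = ss / n_tot
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (var - mean) / mean**2
        zero = mean == 0
        if zero.any():
            logger.warning("%d zero-mean feature(s): dispersion floored",
                           int(zero.sum()))
        alpha = np.where(zero, DISPERSION_FLOOR, alpha)
        alpha = np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEIL)
    return pd.Series(alpha, index=norm.index, name="alpha")


def nb_wald_test(counts: CountMatrix, factors: pd.Series, alpha,
                 c: float = PSEUDO_MEAN) -> pd.DataFrame:
    """Wald test of MOD vs NOR on normalized group means.

    log2FC = log2((mu_MOD + c) / (mu_NOR + c)); per-group variance of the
    log mean is 1/(n_g (mu_g + c)) + alpha/n_g (delta method; the pseudo-mean
    keeps it finite when a group is all zero, in which limit p -> 1).
    Returns a DataFrame with baseMean, log2fc, se, p and BH-adjusted p_adj.
    """
    groups = counts.groups
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    ref, alt = ("NOR", "MOD") if set(labels) == {"NOR", "MOD"} else labels
    norm = counts.counts.div(factors, axis=1)
    if isinstance(alpha, pd.Series):
        alpha = alpha.reindex(norm.index).to_numpy(dtype=float)
    else:
        alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (len(norm),))
    if np.isnan(alpha).any():
        raise ValueError("dispersion missing for some features")

    mu, n = {}, {}
    for g in (ref, alt):
        cols = groups.index[groups == g]
        n[g] = len(cols)
        mu[g] = norm[cols].mean(axis=1).to_numpy(dtype=float)
        if n[g] < 2:
            logger.warning("group %s has < 2 samples; variance estimate is "
                           "model-based only", g)
    log2fc = np.log2((mu[alt] + c) / (mu[ref] + c))
    var = sum(1.0 / (n[g] * (mu[g] + c)) + alpha / n[g] for g in (ref, alt))
    se = np.sqrt(var) / np.log(2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    both_zero = (mu[ref] == 0) & (mu[alt] == 0)
    p[both_zero] = 1.0
    return pd.DataFrame({
        "baseMean": norm.mean(axis=1),
        "log2fc": log2fc,
        "se": se,
        "p": p,
        "p_adj": bh_adjust(p),
    }, index=norm.index)


def call_de(results: pd.DataFrame, lfc_min: float = 1.0,
            p_max: float = 0.05, use_adjusted: bool = True,
            fold_ratio: float | None = None):
    """Flag DE features at |log2FC| >= lfc_min (inclusive) and p < p_max
    (strict, adjusted by default).

    ``fold_ratio`` switches to the legacy no-replicates rule (fold ratio
    strictly greater than the given multiple, raw p).  Returns the annotated
    table and the (n_total, n_up, n_down) census.
    """
    res = results.copy()
    if len(res) == 0:
        res["is_de"] = pd.Series(dtype=bool)
        res["direction"] = pd.Series(dtype=object)
        return res, {"n_total": 0, "n_up": 0, "n_down": 0}
    if fold_ratio is not None:
        effect_ok = np.abs(res["log2fc"]) > np.log2(fold_ratio)
        pcol = res["p"]
    else:
        effect_ok = np.abs(res["log2fc"]) >= lfc_min
        pcol = res["p_adj"] if use_adjusted else res["p"]
    res["is_de"] = effect_ok & (pcol < p_max)
    res["direction"] = np.where(res["log2fc"] >= 0, "up", "down")
    n_up = int((res["is_de"] & (res["direction"] == "up")).sum())
    n_down = int((res["is_de"] & (res["direction"] == "down")).sum())
    return res, {"n_total": n_up + n_down, "n_up": n_up, "n_down": n_down}


@dataclass(frozen=True)
class QpcrMeasurement:
    """Cycle thresholds for one condition: target gene and endogenous
    control (e.g. beta-actin)."""

    ct_target: float
    ct_reference: float

    def __post_init__(self):
        for v in (self.ct_target, self.ct_reference):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be finite and positive")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct(treated: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt method."""
    return float(2.0 ** -(treated.dct - calibrator.dct))
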