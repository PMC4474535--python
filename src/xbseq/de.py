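"""Exact test for differential expression on background-corrected counts.

Given pooled corrected counts x and y for the two conditions, every split
(a, b) of K = x + y is enumerated, each condition's count modelled by a
negative binomial under the null hypothesis of a common expression level,
and the p value is the probability mass of all splits no more likely than
the observed one:

    p = sum_{p(a,b) <= p(x,y)} p(a,b) / sum_all p(a,b),  p(a,b) = Pr(a) Pr(b)

The null NB parameters come from the pooled normalized mean and the fitted
mean-variance trend, following the DESeq exact-test template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .model import (
    PairedCounts,
    SignalModel,
    VARIANCE_FLOOR_REL,
    fit_signal_model,
)

logger = logging.getLogger(__name__)

__all__ = ["NBParams", "exact_test", "adjust_pvalues", "run_de", "ENUMERATION_CAP"]

#: above this K_total the enumeration switches to a normal approximation
ENUMERATION_CAP = 10 ** 6

#: relative tie tolerance so the observed outcome is never excluded from the
#: numerator by floating-point jitter
TIE_TOL = 1e-7


@dataclass(frozen=True)
class NBParams:
    """NB(number of successes r, success probability p); ``degenerate`` marks
    a point mass at zero (mean 0)."""

    r: float = np.nan
    p: float = np.nan
    degenerate: bool = False


def nb_logpmf(k, r, p):
    """Log pmf of NB(r, p) with support k = 0, 1, ... (scipy convention)."""
    k = np.asarray(k, dtype=float)
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1.0)
        + r * np.log(p)
        + k * np.log1p(-p)
    )


def _normal_approx_p(x: int, y: int, nbA: NBParams, nbB: NBParams) -> float:
    """Two-sided p value from the normal approximation of a | a + b = K.

    Used when K_total exceeds the enumeration cap; at such counts the NB
    masses are effectively Gaussian and the conditional law of the first
    condition's count given the total is normal with moments below.
    """
    muA = nbA.r * (1 - nbA.p) / nbA.p
    varA = muA / nbA.p
    muB = nbB.r * (1 - nbB.p) / nbB.p
    varB = muB / nbB.p
    K = x + y
    w = varA / (varA + varB)
    mu_c = muA + w * (K - muA - muB)
    sd_c = np.sqrt(varA * varB / (varA + varB))
    from scipy.stats import norm

    z = (x - mu_c) / sd_c
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def exact_test(
    x: int,
    y: int,
    nbA: Optional[NBParams],
    nbB: Optional[NBParams],
    cap: int = ENUMERATION_CAP,
) -> Tuple[float, str]:
    """Exact p value for one gene; returns (p, flag).

    ``nbA``/``nbB`` may be ``None`` or degenerate markers (point mass at
    zero).  If K_total = 0 the only outcome is the observed one and p = 1.
    """
    x, y = int(x), int(y)
    K = x + y
    if K == 0:
        return 1.0, "degenerate"
    degA = nbA is None or nbA.degenerate
    degB = nbB is None or nbB.degenerate
    if degA and degB:
        # positive total under a null that puts all mass at zero: the
        # observed split is the only one with positive probability
        return 1.0, "degenerate"
    if degA or degB:
        # one condition is a point mass at zero: only one split has
        # positive probability, which must be the observed one
        return 1.0, "degenerate"
    if K > cap:
        return _normal_approx_p(x, y, nbA, nbB), "normal_approx"

    a = np.arange(K + 1)
    logp = nb_logpmf(a, nbA.r, nbA.p) + nb_logpmf(K - a, nbB.r, nbB.p)
    m = logp.max()
    rel = np.exp(logp - m)
    total = rel.sum()
    thresh = logp[x] + np.log1p(TIE_TOL)
    num = rel[logp <= thresh].sum()
    return float(min(1.0, num / total)), ""


def adjust_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _null_nb_params(
    q0: np.ndarray,
    n_reps: int,
    inv_sf_sum: float,
    raw_var_q0: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Null NB parameters for the pooled count of one condition.

    On the normalized scale the pooled count of a condition with ``n_reps``
    replicates has mean ``q0 * n_reps``; its variance decomposes into shot
    noise ``q0 * sum_j 1/s_j`` plus the biological raw variance of the trend,
    ``raw_var(q0) * n_reps``.
    """
    mu = q0 * n_reps
    var = q0 * inv_sf_sum + raw_var_q0 * n_reps
    var = np.maximum(var, mu * (1.0 + VARIANCE_FLOOR_REL))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = mu ** 2 / (var - mu)
        p = mu / var
    return r, p


def _batched_exact_test(
    x: np.ndarray,
    y: np.ndarray,
    rA: np.ndarray,
    pA: np.ndarray,
    rB: np.ndarray,
    pB: np.ndarray,
    cap: int = ENUMERATION_CAP,
    chunk_elems: int = 4_000_000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized enumeration of the exact test over many genes.

    Genes are processed in chunks bounded by total enumeration length to
    keep memory flat.  Returns (p values, flag strings).
    """
    n = x.size
    pvals = np.ones(n)
    flags = np.array([""] * n, dtype=object)
    K = x + y
    degenerate = ~np.isfinite(rA) | ~np.isfinite(rB) | (K == 0)
    flags[degenerate & (K == 0)] = "degenerate"
    flags[degenerate & (K > 0)] = "degenerate"
    big = (~degenerate) & (K > cap)
    for i in np.flatnonzero(big):
        pvals[i] = _normal_approx_p(
            int(x[i]), int(y[i]), NBParams(rA[i], pA[i]), NBParams(rB[i], pB[i])
        )
        flags[i] = "normal_approx"
    todo = np.flatnonzero(~degenerate & ~big)
    if todo.size == 0:
        return pvals, flags

    order = todo[np.argsort(K[todo])]
    start = 0
    while start < order.size:
        stop = start
        total = 0
        while stop < order.size and (total == 0 or total + K[order[stop]] + 1 <= chunk_elems):
            total += int(K[order[stop]]) + 1
            stop += 1
        idx = order[start:stop]
        lengths = K[idx] + 1
        offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        gene_of = np.repeat(np.arange(idx.size), lengths)
        a = np.arange(int(lengths.sum())) - offsets[gene_of]
        logp = nb_logpmf(a, rA[idx][gene_of], pA[idx][gene_of]) + nb_logpmf(
            K[idx][gene_of] - a, rB[idx][gene_of], pB[idx][gene_of]
        )
        mx = np.maximum.reduceat(logp, offsets)
        rel = np.exp(logp - mx[gene_of])
        denom = np.add.reduceat(rel, offsets)
        l_obs = logp[offsets + x[idx].astype(int)]
        keep = logp <= (l_obs[gene_of] + np.log1p(TIE_TOL))
        numer = np.add.reduceat(np.where(keep, rel, 0.0), offsets)
        pvals[idx] = np.minimum(1.0, numer / denom)
        start = stop
    return pvals, flags


def run_de(
    pc: PairedCounts,
    use_background: bool = True,
    span: float = 0.3,
    cap: int = ENUMERATION_CAP,
) -> pd.DataFrame:
    """Full differential-expression pipeline for a two-condition design.

    Returns a table with one row per gene: normalized corrected base means
    per condition, log2 fold change, exact-test p value, BH-adjusted p
    value, and flags.  With ``use_background=False`` the non-exonic counts
    are ignored (lambda = 0, corrected signal = X), which is the classical
    uncorrected NB test used as the internal comparator.
    """
    levels = pc.condition_levels
    if len(levels) != 2:
        raise ValueError(f"exactly two conditions required, got {levels}")
    if not use_background:
        pc = PairedCounts(
            gene_ids=pc.gene_ids,
            sample_ids=pc.sample_ids,
            conditions=pc.conditions,
            X=pc.X,
            B=np.zeros_like(np.asarray(pc.B)),
        )
    sm = fit_signal_model(pc, span=span)
    condA, condB = levels
    colsA = pc.samples_of(condA)
    colsB = pc.samples_of(condB)
    nA, nB = colsA.size, colsB.size
    sf = sm.size_factors

    x = np.rint(sm.normalized[:, colsA].sum(axis=1)).astype(np.int64)
    y = np.rint(sm.normalized[:, colsB].sum(axis=1)).astype(np.int64)
    q0 = (x + y) / (nA + nB)

    # raw (biological) variance of the trend at q0: fitted full variance of
    # one normalized replicate minus the average shot-noise contribution
    zbar = float(np.mean(1.0 / sf))
    v_full = np.asarray(sm.fitted_variance(q0), dtype=float)
    raw_var = np.maximum(v_full - q0 * zbar, 0.0)

    rA, pA = _null_nb_params(q0, nA, float((1.0 / sf[colsA]).sum()), raw_var)
    rB, pB = _null_nb_params(q0, nB, float((1.0 / sf[colsB]).sum()), raw_var)

    pvals, flags = _batched_exact_test(x, y, rA, pA, rB, pB, cap=cap)
    padj = adjust_pvalues(pvals)

    muA = sm.mu[condA]
    muB = sm.mu[condB]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(muB) - np.log2(muA)
    return pd.DataFrame(
        {
            "gene_id": sm.gene_ids,
            "baseMeanA": muA,
            "baseMeanB": muB,
            "log2FC": log2fc,
            "pval": pvals,
            "padj": padj,
            "flags": flags,
        }
    )
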