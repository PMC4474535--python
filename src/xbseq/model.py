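"""Background-corrected signal model for paired exonic / non-exonic counts.

The observed exonic read count of a gene is modelled as the sum of a latent
negative-binomial expression signal S and Poisson sequencing noise B whose
rate is measured from reads falling into a matched non-exonic ("shifted")
region of identical length::

    X = S + B,   S ~ NB(r, p),   B ~ Poisson(lambda)

The marginal distribution of X is then a Delaporte distribution (NB-Poisson
convolution).  This module estimates lambda from the non-exonic counts,
recovers a per-replicate corrected signal ``max(0, x - b)``, normalizes it
with median-of-ratios size factors, and converts moment estimates into NB
parameters ``(r, p)`` after a DESeq-style variance correction against a
local-regression mean-variance trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PairedCounts",
    "SignalModel",
    "estimate_lambda",
    "correct_signal",
    "compute_size_factors",
    "normalize_counts",
    "condition_moments",
    "fit_mean_variance",
    "correct_variance",
    "nb_params",
    "fit_signal_model",
    "VARIANCE_FLOOR_REL",
]

#: relative floor keeping corrected variance strictly above the mean so the
#: NB conversion r = mu^2/(var - mu) stays finite (Poisson limit).
VARIANCE_FLOOR_REL = 1e-8


@dataclass
class PairedCounts:
    """Exonic count matrix X and matched non-exonic count matrix B.

    Rows are genes, columns samples; both matrices share shape and ordering.
    ``conditions`` assigns each sample to exactly one experimental group.
    """

    gene_ids: List[str]
    sample_ids: List[str]
    conditions: List[str]
    X: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.B = np.asarray(self.B)
        if self.X.shape != self.B.shape:
            raise ValueError(
                f"exonic matrix {self.X.shape} and non-exonic matrix "
                f"{self.B.shape} must share shape"
            )
        n_genes, n_samples = self.X.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.sample_ids) != n_samples or len(self.conditions) != n_samples:
            raise ValueError("sample_ids/conditions length does not match columns")
        if (self.X < 0).any() or (self.B < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def condition_levels(self) -> List[str]:
        """Distinct condition labels in order of first appearance."""
        seen: Dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c, None)
        return list(seen)

    def samples_of(self, condition: str) -> np.ndarray:
        """Column indices belonging to one condition."""
        return np.flatnonzero(np.asarray(self.conditions) == condition)


@dataclass
class SignalModel:
    """Per-gene estimates of the background-corrected expression signal."""

    gene_ids: List[str]
    conditions: List[str]                      # condition levels, order kept
    lam: np.ndarray                            # Poisson rate, all samples
    lam_by_condition: Dict[str, np.ndarray]
    s_hat: np.ndarray                          # corrected signal, raw scale
    size_factors: np.ndarray
    normalized: np.ndarray                     # s_hat / size_factors
    mu: Dict[str, np.ndarray]                  # per-condition mean
    var_raw: Dict[str, np.ndarray]             # sample variance (NaN if m=1)
    var_corrected: Dict[str, np.ndarray]
    var_analytic: Dict[str, np.ndarray]        # sigma_X^2 - lambda diagnostic
    r: Dict[str, np.ndarray]
    p: Dict[str, np.ndarray]
    n_replicates: Dict[str, int]
    fitted_variance: Callable[[np.ndarray], np.ndarray]
    flags: Dict[str, np.ndarray] = field(default_factory=dict)


def estimate_lambda(B: np.ndarray, sample_subset: Sequence[int]) -> np.ndarray:
    """Per-gene Poisson rate: mean non-exonic count over a sample subset."""
    subset = np.asarray(sample_subset, dtype=int)
    if subset.size == 0:
        raise ValueError("sample_subset must be non-empty")
    B = np.asarray(B)
    return B[:, subset].mean(axis=1)


def correct_signal(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-replicate background subtraction, clamped at zero.

    Negative differences (background exceeding the observed count) are set
    to 0: the corrected signal estimates a non-negative latent count.
    """
    X = np.asarray(X)
    B = np.asarray(B)
    if X.shape != B.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs B {B.shape}")
    return np.maximum(X - B, 0)


def compute_size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq median-of-ratios size factors.

    For each sample, the median over reference genes of count / geometric
    mean, where the reference set consists of genes with strictly positive
    counts in every sample (positive geometric mean).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.size == 0:
        raise ValueError("counts must be a non-empty 2-D matrix")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "size factor estimation failed: no gene has positive counts in "
            "every sample"
        )
    ref = counts[positive]
    log_geo = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo[:, None]
    return np.exp(np.median(ratios, axis=0))


def normalize_counts(counts: np.ndarray, size_factors: np.ndarray) -> np.ndarray:
    """Divide each column by its size factor."""
    return np.asarray(counts, dtype=float) / np.asarray(size_factors)[None, :]


def condition_moments(
    normalized: np.ndarray, conditions: Sequence[str]
) -> Dict[str, Dict[str, np.ndarray]]:
    """Sample mean and unbiased variance of normalized counts per condition.

    Conditions with a single replicate get NaN variance and are expected to
    rely on the fitted mean-variance trend downstream.
    """
    conditions = np.asarray(conditions)
    out: Dict[str, Dict[str, np.ndarray]] = {}
    seen: Dict[str, None] = {}
    for c in conditions:
        seen.setdefault(str(c), None)
    for cond in seen:
        cols = np.flatnonzero(conditions == cond)
        sub = normalized[:, cols]
        mu = sub.mean(axis=1)
        if cols.size >= 2:
            var = sub.var(axis=1, ddof=1)
        else:
            var = np.full(normalized.shape[0], np.nan)
        out[cond] = {"mu": mu, "var": var, "m": cols.size}
    return out


class LocalVarianceFit:
    """Tricube-weighted local linear regression of log variance on log mean.

    Mirrors the role of a locfit/loess mean-variance trend.  Raw log sample
    variances are biased low at small replicate numbers (Jensen bias of the
    log of a chi-squared variable); each training point is de-biased with
    the analytic correction E[ln s^2] - ln sigma^2 = psi(nu/2) + ln 2 - ln nu
    for its degrees of freedom nu before fitting, so the back-transformed
    trend is centred on the true variance.  The fit is evaluated on a grid
    spanning the training range and queried by interpolation, with queries
    outside the range clamped to the boundary values.
    """

    def __init__(
        self,
        log_mu: np.ndarray,
        log_var: np.ndarray,
        span: float = 0.3,
        df: Optional[np.ndarray] = None,
    ):
        from scipy.special import digamma

        if df is not None:
            bias = digamma(np.asarray(df, dtype=float) / 2.0) + np.log(2.0) - np.log(df)
            log_var = log_var - bias
        order = np.argsort(log_mu)
        self._x = log_mu[order]
        self._y = log_var[order]
        self.span = float(span)
        n = self._x.size
        k = max(int(np.ceil(self.span * n)), 3)
        grid = np.linspace(self._x[0], self._x[-1], min(200, n))
        fitted = np.empty_like(grid)
        for i, x0 in enumerate(grid):
            d = np.abs(self._x - x0)
            h = np.partition(d, k - 1)[k - 1]
            if h <= 0:
                h = max(d.max(), 1e-12)
            w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
            sw = w.sum()
            xm = (w * self._x).sum() / sw
            ym = (w * self._y).sum() / sw
            sxx = (w * (self._x - xm) ** 2).sum()
            if sxx > 1e-12:
                beta = (w * (self._x - xm) * (self._y - ym)).sum() / sxx
            else:
                beta = 0.0
            fitted[i] = ym + beta * (x0 - xm)
        self._grid = grid
        self._fitted = fitted

    @property
    def x_range(self):
        return float(self._x[0]), float(self._x[-1])

    def __call__(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        scalar = q.ndim == 0
        q = np.atleast_1d(q)
        logq = np.full(q.shape, -np.inf)
        pos = q > 0
        logq[pos] = np.log(q[pos])
        logq = np.clip(logq, self._grid[0], self._grid[-1])
        v = np.exp(np.interp(logq, self._grid, self._fitted))
        return float(v[0]) if scalar else v


class ParametricVarianceFit:
    """Fallback trend var(q) = q + c * q^2 with c >= 0 by least squares."""

    def __init__(self, mu: np.ndarray, var: np.ndarray):
        q2 = mu ** 2
        denom = (q2 ** 2).sum()
        c = ((var - mu) * q2).sum() / denom if denom > 0 else 0.0
        self.c = max(float(c), 0.0)

    def __call__(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return q + self.c * q ** 2


def fit_mean_variance(
    mu: np.ndarray,
    var: np.ndarray,
    span: float = 0.3,
    min_points: int = 10,
    df=None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit the mean-variance trend on genes with positive mean and variance.

    Returns a callable ``v(q)`` giving the fitted variance of a single
    normalized replicate at mean ``q``.  ``df`` (scalar or per-point) gives
    the degrees of freedom of each sample variance for the Jensen bias
    correction of the log-scale fit.  With fewer than ``min_points`` usable
    genes a parametric ``q + c q^2`` fit is used instead and a warning is
    logged.
    """
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    ok = np.isfinite(mu) & np.isfinite(var) & (mu > 0) & (var > 0)
    if ok.sum() < min_points:
        logger.warning(
            "only %d usable genes for the mean-variance trend; falling back "
            "to parametric var = q + c*q^2",
            int(ok.sum()),
        )
        use = np.isfinite(mu) & np.isfinite(var) & (mu > 0)
        if not use.any():
            return ParametricVarianceFit(np.array([1.0]), np.array([1.0]))
        return ParametricVarianceFit(mu[use], var[use])
    if df is not None:
        df = np.broadcast_to(np.asarray(df, dtype=float), mu.shape)[ok]
    return LocalVarianceFit(np.log(mu[ok]), np.log(var[ok]), span=span, df=df)


def correct_variance(
    mu: np.ndarray,
    var_raw: np.ndarray,
    fitted: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray:
    """DESeq-style corrected variance: max of the per-gene sample variance
    and the fitted trend, floored just above the mean so (r, p) exist."""
    mu = np.asarray(mu, dtype=float)
    var_raw = np.asarray(var_raw, dtype=float)
    v_fit = np.asarray(fitted(mu), dtype=float)
    var = np.where(np.isfinite(var_raw), np.maximum(var_raw, v_fit), v_fit)
    floor = mu * (1.0 + VARIANCE_FLOOR_REL)
    return np.maximum(var, floor)


def nb_params(mu: np.ndarray, var_corrected: np.ndarray):
    """Convert mean/variance to NB (number of successes, success probability).

    r = mu^2 / (var - mu),  p = mu / var, so that NB(r, p) has mean
    r (1-p)/p = mu and variance mu/p = var.  Genes with mu = 0 are
    degenerate (point mass at zero) and get NaN parameters plus a flag.
    """
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var_corrected, dtype=float)
    degenerate = mu <= 0
    r = np.full(mu.shape, np.nan)
    p = np.full(mu.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        good = ~degenerate
        r[good] = mu[good] ** 2 / (var[good] - mu[good])
        p[good] = mu[good] / var[good]
    return r, p, degenerate


def fit_signal_model(pc: PairedCounts, span: float = 0.3) -> SignalModel:
    """Run the full estimation pipeline on paired counts.

    lambda estimation, per-replicate correction, size factors on the
    corrected matrix, per-condition moments on the normalized scale, a
    pooled mean-variance trend, variance correction and NB conversion.
    """
    levels = pc.condition_levels
    lam_by = {c: estimate_lambda(pc.B, pc.samples_of(c)) for c in levels}
    lam = estimate_lambda(pc.B, np.arange(len(pc.sample_ids)))
    s_hat = correct_signal(pc.X, pc.B)
    size_factors = compute_size_factors(s_hat)
    normalized = normalize_counts(s_hat, size_factors)
    moments = condition_moments(normalized, pc.conditions)

    # pooled trend over both conditions' (mean, variance) pairs; each point
    # carries its condition's variance degrees of freedom for de-biasing
    mu_all = np.concatenate([moments[c]["mu"] for c in levels])
    var_all = np.concatenate([moments[c]["var"] for c in levels])
    df_all = np.concatenate(
        [np.full(len(pc.gene_ids), max(moments[c]["m"] - 1, 1)) for c in levels]
    )
    fitted = fit_mean_variance(mu_all, var_all, span=span, df=df_all)

    mu_d, var_raw_d, var_c_d, var_an_d, r_d, p_d = {}, {}, {}, {}, {}, {}
    n_reps = {}
    flags: Dict[str, np.ndarray] = {}
    X_norm = normalize_counts(pc.X, size_factors)
    for c in levels:
        cols = pc.samples_of(c)
        mu_c = moments[c]["mu"]
        var_c = moments[c]["var"]
        var_corr = correct_variance(mu_c, var_c, fitted)
        r_c, p_c, degen = nb_params(mu_c, var_corr)
        if cols.size >= 2:
            var_x = X_norm[:, cols].var(axis=1, ddof=1)
        else:
            var_x = np.full(len(pc.gene_ids), np.nan)
        mu_d[c] = mu_c
        var_raw_d[c] = var_c
        var_c_d[c] = var_corr
        var_an_d[c] = var_x - lam_by[c]
        r_d[c] = r_c
        p_d[c] = p_c
        n_reps[c] = int(cols.size)
        flags[f"degenerate_{c}"] = degen
        flags[f"single_replicate_{c}"] = np.full(len(pc.gene_ids), cols.size < 2)

    return SignalModel(
        gene_ids=list(pc.gene_ids),
        conditions=levels,
        lam=lam,
        lam_by_condition=lam_by,
        s_hat=s_hat,
        size_factors=size_factors,
        normalized=normalized,
        mu=mu_d,
        var_raw=var_raw_d,
        var_corrected=var_c_d,
        var_analytic=var_an_d,
        r=r_d,
        p=p_d,
        n_replicates=n_reps,
        fitted_variance=fitted,
        flags=flags,
    )
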