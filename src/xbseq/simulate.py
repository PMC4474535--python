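"""Synthetic paired-count generator for benchmarking the corrected test.

True signal S is negative binomial (mean mu, variance mu + phi mu^2),
background noise is Poisson at baseline or an amplified hybrid model at
elevated noise: per gene and replicate a rate mu* ~ Poisson(lambda + NF)
(or a binomial / uniform / normal substitute) is drawn and the count is
round(M * Normal(mu*, sigma)) clamped at zero.  Observed counts are
X = S + B exactly.

Gene-level parameters (mu, phi, lambda) come from a pinned synthetic
generator emulating bulk RNA-seq estimates: log-normal means, a decreasing
dispersion-mean trend with the top decile of dispersions redrawn, and
background rates weakly correlated with expression at roughly 5% of its
magnitude.  Externally estimated parameter tables can be supplied instead
and are resampled with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSettings",
    "SimulationConfig",
    "SimulatedDataset",
    "generate_gene_parameters",
    "assign_de",
    "simulate_signal",
    "simulate_background",
    "assemble_dataset",
]

NOISE_FAMILIES = ("poisson", "binomial", "uniform", "normal")


@dataclass(frozen=True)
class ParameterSettings:
    """Pinned settings of the synthetic gene-parameter generator.

    ``log_mean``/``log_sd`` define the log-normal spread of gene means
    (natural log).  Dispersion follows the trend phi = disp_a/mu + disp_b
    times log-normal noise, with the top ``disp_trim`` fraction redrawn.
    Background rates follow log lambda = lambda_slope * log mu + noise,
    scaled so median(lambda)/median(mu) = lambda_ratio.
    """

    log_mean: float = 4.0
    log_sd: float = 1.8
    disp_a: float = 3.0
    disp_b: float = 0.1
    disp_noise_sd: float = 0.25
    disp_trim: float = 0.10
    lambda_slope: float = 0.32
    lambda_noise_sd: float = 1.70
    lambda_ratio: float = 0.05
    min_mean: float = 1.0


@dataclass
class SimulationConfig:
    """One simulation scenario.

    ``noise_factor`` (NF) inflates the background rate and ``m_amp`` (M)
    amplifies it; NF = 0 with M = 1 is the plain Poisson baseline.  ``sigma``
    is the jitter of the amplified normal draw.
    """

    n_genes: int = 5000
    n_replicates: int = 3
    de_fraction: float = 0.10
    fold_change: float = 1.5
    noise_factor: float = 0.0
    m_amp: float = 10.0
    sigma: float = 3.0
    noise_family: str = "poisson"
    seed: int = 0
    settings: ParameterSettings = field(default_factory=ParameterSettings)
    parameter_table: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if not 0 < self.de_fraction < 1:
            raise ValueError("de_fraction must lie in (0, 1)")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.noise_factor < 0 or self.m_amp < 1:
            raise ValueError("noise_factor >= 0 and m_amp >= 1 required")
        if self.noise_family not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {self.noise_family!r}")

    @classmethod
    def baseline(cls, **kwargs) -> "SimulationConfig":
        """Plain Poisson background (NF = 0, M = 1)."""
        kwargs.setdefault("noise_factor", 0.0)
        kwargs["m_amp"] = 1.0
        return cls(**kwargs)


@dataclass
class SimulatedDataset:
    """Matrices for both conditions stacked column-wise (first condition
    then second); ``X = S + B`` exactly, and ``B`` is also the non-exonic
    background measurement handed to a test."""

    gene_ids: list
    sample_ids: list
    conditions: list
    S: np.ndarray
    B: np.ndarray
    X: np.ndarray
    truth: np.ndarray          # +1 up, -1 down, 0 non-DE
    mu: np.ndarray
    dispersion: np.ndarray
    lam: np.ndarray
    multipliers: np.ndarray
    config: SimulationConfig = None


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _streams(seed: int, n: int = 5):
    """Independent RNGs for parameters, DE assignment, signal and
    background noise, all spawned from one seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in children]


def generate_gene_parameters(
    n: int, rng: np.random.Generator, settings: ParameterSettings = ParameterSettings()
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-gene (mean, dispersion, background rate) vectors.

    Dispersions above the 90th percentile are redrawn from the same trend
    until below it, mimicking the removal of the most dispersed genes from
    an empirical parameter pool.
    """
    rng = _as_rng(rng)
    if n < 1:
        raise ValueError("n must be >= 1")
    st = settings
    mu = np.exp(rng.normal(st.log_mean, st.log_sd, size=n))
    trend = st.disp_a / mu + st.disp_b
    phi = trend * np.exp(rng.normal(0.0, st.disp_noise_sd, size=n))
    if 0 < st.disp_trim < 1:
        cutoff = np.quantile(phi, 1.0 - st.disp_trim)
        bad = phi > cutoff
        tries = 0
        while bad.any() and tries < 100:
            phi[bad] = trend[bad] * np.exp(
                rng.normal(0.0, st.disp_noise_sd, size=int(bad.sum()))
            )
            bad = phi > cutoff
            tries += 1
        phi = np.minimum(phi, cutoff)
    log_lam = st.lambda_slope * np.log(mu) + rng.normal(
        0.0, st.lambda_noise_sd, size=n
    )
    lam = np.exp(log_lam)
    med = np.median(lam)
    if med > 0 and st.lambda_ratio > 0:
        lam *= st.lambda_ratio * np.median(mu) / med
    elif st.lambda_ratio == 0:
        lam = np.zeros(n)
    return mu, phi, lam


def assign_de(
    n: int, de_fraction: float, fold_change: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Pick ceil(n * de_fraction) genes as DE; half get multiplier FC, half
    1/FC.  Returns (multipliers, signed truth labels)."""
    rng = _as_rng(rng)
    if not 0 < de_fraction < 1:
        raise ValueError("de_fraction must lie in (0, 1)")
    n_de = int(np.ceil(n * de_fraction))
    chosen = rng.choice(n, size=n_de, replace=False)
    up = chosen[: n_de // 2 + n_de % 2]
    down = chosen[n_de // 2 + n_de % 2:]
    multipliers = np.ones(n)
    multipliers[up] = fold_change
    multipliers[down] = 1.0 / fold_change
    truth = np.zeros(n, dtype=int)
    truth[up] = 1
    truth[down] = -1
    return multipliers, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray, size):
    """NB draws via the gamma-Poisson mixture; phi = 0 reduces to Poisson."""
    mean = np.broadcast_to(mean, size).astype(float)
    phi = np.broadcast_to(phi, size).astype(float)
    lam = np.where(
        phi > 0,
        rng.gamma(np.where(phi > 0, 1.0 / np.maximum(phi, 1e-300), 1.0),
                  phi * mean),
        mean,
    )
    return rng.poisson(lam)


def simulate_signal(
    mu: np.ndarray,
    dispersion: np.ndarray,
    multipliers: np.ndarray,
    m_reps: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """NB true-signal matrices for both conditions (genes x m_reps each)."""
    rng = _as_rng(rng)
    n = mu.size
    s1 = _nb_draw(rng, mu[:, None], dispersion[:, None], (n, m_reps))
    s2 = _nb_draw(
        rng, (mu * multipliers)[:, None], dispersion[:, None], (n, m_reps)
    )
    return s1, s2


def _latent_rates(
    lam: np.ndarray,
    m_reps: int,
    noise_factor: float,
    m_amp: float,
    noise_family: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent per-gene, per-replicate background rate mu*.

    At baseline (NF = 0, M = 1) the rate is lambda itself; in the amplified
    model it is drawn per gene and replicate from the chosen family at
    location lambda + NF.
    """
    lam = np.asarray(lam, dtype=float)
    if (lam < 0).any():
        raise ValueError("lambda must be non-negative")
    shape = (lam.size, m_reps)
    if noise_factor == 0 and m_amp == 1:
        return np.broadcast_to(lam[:, None], shape)
    loc = np.broadcast_to(lam[:, None] + noise_factor, shape)
    if noise_family == "poisson":
        return rng.poisson(loc).astype(float)
    if noise_family == "binomial":
        return rng.binomial(np.rint(2 * loc).astype(np.int64), 0.5).astype(float)
    if noise_family == "uniform":
        return rng.uniform(0.0, 2.0 * loc)
    if noise_family == "normal":
        return np.maximum(rng.normal(loc, np.sqrt(np.maximum(loc, 1e-12))), 0.0)
    raise ValueError(f"unknown noise family {noise_family!r}")


def _emit_background(
    rates: np.ndarray,
    m_amp: float,
    sigma: float,
    baseline: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Count realization given the latent rates."""
    if baseline:
        return rng.poisson(rates)
    b = np.rint(m_amp * rng.normal(rates, sigma))
    return np.maximum(b, 0).astype(np.int64)


def simulate_background(
    lam: np.ndarray,
    m_reps: int,
    noise_factor: float,
    m_amp: float,
    sigma: float,
    noise_family: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Background count matrix (genes x m_reps).

    Baseline (NF = 0, M = 1): Poisson(lambda).  Otherwise the amplified
    hybrid model: per gene and replicate, rate mu* drawn from the chosen
    family at location lambda + NF, count = max(0, round(M * N(mu*, sigma))).
    """
    rng = _as_rng(rng)
    baseline = noise_factor == 0 and m_amp == 1
    rates = _latent_rates(lam, m_reps, noise_factor, m_amp, noise_family, rng)
    return _emit_background(rates, m_amp, sigma, baseline, rng)


def assemble_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Build one complete dataset from a scenario configuration.

    RNG streams for parameters, DE assignment, signal, added background and
    observed background are independent sub-streams of ``config.seed``, so
    changing e.g. the noise level leaves the signal draws untouched.
    """
    rng_par, rng_de, rng_sig, rng_bg = _streams(config.seed, 4)
    n = config.n_genes
    if config.parameter_table is not None:
        tab = config.parameter_table
        tab = tab[tab["mu"] >= config.settings.min_mean]
        if tab.empty:
            raise ValueError("parameter table empty after expression filter")
        rows = rng_par.choice(len(tab), size=n, replace=True)
        mu = tab["mu"].to_numpy()[rows].astype(float)
        phi = tab["dispersion"].to_numpy()[rows].astype(float)
        lam = tab["lambda"].to_numpy()[rows].astype(float)
    else:
        mu, phi, lam = generate_gene_parameters(n, rng_par, config.settings)
    multipliers, truth = assign_de(
        n, config.de_fraction, config.fold_change, rng_de
    )
    s1, s2 = simulate_signal(mu, phi, multipliers, config.n_replicates, rng_sig)
    S = np.hstack([s1, s2])
    m_total = 2 * config.n_replicates
    B = simulate_background(
        lam,
        m_total,
        config.noise_factor,
        config.m_amp,
        config.sigma,
        config.noise_family,
        rng_bg,
    )
    X = S + B
    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    sample_ids = [f"A_{j + 1}" for j in range(config.n_replicates)] + [
        f"B_{j + 1}" for j in range(config.n_replicates)
    ]
    conditions = ["A"] * config.n_replicates + ["B"] * config.n_replicates
    return SimulatedDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        conditions=conditions,
        S=S,
        B=B,
        X=X,
        truth=truth,
        mu=mu,
        dispersion=phi,
        lam=lam,
        multipliers=multipliers,
        config=config,
    )
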