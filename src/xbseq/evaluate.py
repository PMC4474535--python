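"""Benchmark harness: ROC/AUC, false-discovery curves, and power.

Runs the background-corrected test and the uncorrected NB comparator over
simulated scenarios, scoring the p-value ranking against the ground-truth
DE labels.  Additional test methods can be plugged in as callables taking
``(X, B, conditions) -> p-value vector``.
"""

from __future__ import annotations

import logging
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .de import run_de
from .model import PairedCounts
from .simulate import SimulatedDataset, SimulationConfig, assemble_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "baseline_nb_test",
    "roc_auc",
    "false_discovery_curve",
    "power_at",
    "scenario_grid",
    "run_benchmark",
]

TestFunc = Callable[[np.ndarray, np.ndarray, Sequence[str]], np.ndarray]


def _paired(X, B, conditions) -> PairedCounts:
    n, m = np.asarray(X).shape
    return PairedCounts(
        gene_ids=[f"gene_{i:05d}" for i in range(n)],
        sample_ids=[f"s{j}" for j in range(m)],
        conditions=list(conditions),
        X=np.asarray(X),
        B=np.asarray(B),
    )


def xbseq_test(X, B, conditions) -> np.ndarray:
    """Background-corrected exact test; returns the p-value vector."""
    return run_de(_paired(X, B, conditions)).pval.to_numpy()


def baseline_nb_test(X, conditions, B=None) -> pd.DataFrame:
    """Uncorrected NB exact test on the observed counts.

    The identical pipeline with the background input ignored (lambda = 0,
    corrected signal = X); stands in for a classical NB exact-test method.
    Returns the full per-gene result table.
    """
    if B is None:
        B = np.zeros_like(np.asarray(X))
    return run_de(_paired(X, B, conditions), use_background=False)


def roc_auc(pvalues, truth) -> Tuple[pd.DataFrame, float]:
    """ROC points and trapezoid AUC of the ascending-p ranking.

    Equivalent to the Mann-Whitney statistic on -p scores; ties share rank.
    Degenerate truth (no positives or no negatives) yields NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    t = np.asarray(truth) != 0
    if p.size != t.size:
        raise ValueError("pvalues and truth must have the same length")
    if t.all() or not t.any():
        return pd.DataFrame(columns=["fpr", "tpr"]), float("nan")
    fpr, tpr, _ = roc_curve(t.astype(int), -p)
    auc = roc_auc_score(t.astype(int), -p)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), float(auc)


def false_discovery_curve(pvalues, truth, k_max: Optional[int] = None) -> np.ndarray:
    """Entry k-1: number of truth-negative genes among the k smallest p values."""
    p = np.asarray(pvalues, dtype=float)
    t = np.asarray(truth) != 0
    if k_max is None:
        k_max = p.size
    if k_max > p.size:
        raise ValueError("k_max exceeds number of genes")
    order = np.argsort(p, kind="stable")
    return np.cumsum(~t[order])[:k_max]


def power_at(pvalues, truth, alpha: float = 0.05) -> float:
    """Fraction of truth-positive genes with raw p below alpha."""
    p = np.asarray(pvalues, dtype=float)
    t = np.asarray(truth) != 0
    if not t.any():
        raise ValueError("truth must contain at least one positive")
    return float((p[t] < alpha).mean())


def scenario_grid(
    replicates=(3, 6),
    de_fractions=(0.10,),
    fold_changes=(1.5,),
    noise_levels=((0.0, 1.0), (0.0, 10.0), (7.0, 10.0), (20.0, 10.0)),
    **common,
) -> List[Dict]:
    """Cartesian scenario grid; each noise level is a (NF, M) pair
    ((0, 1) being the plain Poisson baseline)."""
    grid = []
    for m in replicates:
        for frac in de_fractions:
            for fc in fold_changes:
                for nf, m_amp in noise_levels:
                    grid.append(
                        dict(
                            n_replicates=m,
                            de_fraction=frac,
                            fold_change=fc,
                            noise_factor=nf,
                            m_amp=m_amp,
                            **common,
                        )
                    )
    return grid


def _iteration_seed(seed: int, scenario_idx: int, iteration: int) -> int:
    ss = np.random.SeedSequence(entropy=[seed, scenario_idx, iteration])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _stratum_mask(ds: SimulatedDataset, stratum: str) -> np.ndarray:
    if stratum == "all":
        return np.ones(len(ds.mu), dtype=bool)
    if stratum == "high":
        return ds.mu > np.quantile(ds.mu, 0.75)
    if stratum == "low":
        return ds.mu < np.quantile(ds.mu, 0.25)
    raise ValueError(f"unknown stratum {stratum!r}")


def run_benchmark(
    scenarios: Sequence[Dict],
    iterations: int = 10,
    seed: int = 0,
    n_genes: int = 5000,
    methods: Optional[Dict[str, TestFunc]] = None,
    strata: Sequence[str] = ("all",),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Simulate each scenario ``iterations`` times and score every method.

    Expression strata ("high": above the 75% quantile of the true simulated
    mean; "low": below the 25% quantile) restrict both the p values and the
    truth labels before scoring.  Returns one row per
    scenario x iteration x method x stratum.
    """
    if methods is None:
        methods = {
            "xbseq": lambda X, B, cond: xbseq_test(X, B, cond),
            "baseline": lambda X, B, cond: baseline_nb_test(X, cond).pval.to_numpy(),
        }
    rows = []
    for si, scen in enumerate(scenarios):
        for it in range(iterations):
            cfg = SimulationConfig(
                n_genes=n_genes,
                seed=_iteration_seed(seed, si, it),
                **scen,
            )
            ds = assemble_dataset(cfg)
            for name, func in methods.items():
                p = np.asarray(func(ds.X, ds.B, ds.conditions), dtype=float)
                for stratum in strata:
                    mask = _stratum_mask(ds, stratum)
                    _, auc = roc_auc(p[mask], ds.truth[mask])
                    pw = (
                        power_at(p[mask], ds.truth[mask], alpha)
                        if (ds.truth[mask] != 0).any()
                        else float("nan")
                    )
                    rows.append(
                        dict(
                            scenario=si,
                            iteration=it,
                            method=name,
                            stratum=stratum,
                            n_replicates=cfg.n_replicates,
                            de_fraction=cfg.de_fraction,
                            fold_change=cfg.fold_change,
                            noise_factor=cfg.noise_factor,
                            m_amp=cfg.m_amp,
                            auc=auc,
                            power=pw,
                        )
                    )
            logger.debug("scenario %d iteration %d done", si, it)
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of AUC and power per scenario x method x stratum."""
    keys = [
        "scenario",
        "method",
        "stratum",
        "n_replicates",
        "de_fraction",
        "fold_change",
        "noise_factor",
        "m_amp",
    ]
    agg = results.groupby(keys, as_index=False).agg(
        auc_mean=("auc", "mean"),
        auc_sd=("auc", "std"),
        power_mean=("power", "mean"),
        power_sd=("power", "std"),
        iterations=("iteration", "count"),
    )
    return agg
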