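"""Small deterministic fixtures: toy genomes, toy counts, and a four-gene
mouse liver (wild type vs MYC transgenic) worked example used in the tests.
"""

from __future__ import annotations

import os
from typing import Dict, Tuple

import numpy as np

from . import io as xio
from .annotation import GeneModel, Interval, write_background_gtf
from .simulate import SimulationConfig, assemble_dataset

__all__ = ["WORKED_EXAMPLE", "make_fixture", "worked_example_counts"]

# Exonic / non-exonic read counts of four mouse liver genes, three WT and
# three MYC replicates each: Nat1 and Brca2 become significant only after
# background correction; Calcr and Adh7 lose significance after it.
WORKED_EXAMPLE: Dict[str, Dict[str, list]] = {
    "Nat1": {
        "exonic": [63, 47, 77, 91, 110, 120],
        "nonexonic": [20, 20, 28, 23, 14, 34],
    },
    "Brca2": {
        "exonic": [213, 88, 165, 132, 191, 188],
        "nonexonic": [216, 77, 142, 90, 108, 101],
    },
    "Calcr": {
        "exonic": [22, 4, 20, 68, 68, 64],
        "nonexonic": [64, 4, 64, 193, 218, 199],
    },
    "Adh7": {
        "exonic": [633, 438, 429, 827, 1149, 708],
        "nonexonic": [430, 241, 322, 643, 771, 513],
    },
}

SAMPLE_IDS = ["WT_1", "WT_2", "WT_3", "MYC_1", "MYC_2", "MYC_3"]
CONDITIONS = ["WT", "WT", "WT", "MYC", "MYC", "MYC"]


def worked_example_counts() -> Tuple[np.ndarray, np.ndarray, list, list, list]:
    """The four-gene worked example as (X, B, gene_ids, sample_ids, conditions)."""
    genes = list(WORKED_EXAMPLE)
    X = np.array([WORKED_EXAMPLE[g]["exonic"] for g in genes])
    B = np.array([WORKED_EXAMPLE[g]["nonexonic"] for g in genes])
    return X, B, genes, list(SAMPLE_IDS), list(CONDITIONS)


def _toy_genome(outdir: str, rng: np.random.Generator) -> None:
    chrom_sizes = {"chrA": 200_000, "chrB": 150_000}
    genes = []
    exclusions = []
    for chrom, size, n_genes in [("chrA", 200_000, 6), ("chrB", 150_000, 4)]:
        pos = 5_000
        for k in range(n_genes):
            n_ex = int(rng.integers(1, 5))
            exons = []
            p = pos
            for _ in range(n_ex):
                length = int(rng.integers(100, 800))
                exons.append(Interval(chrom, p, p + length, "+"))
                p += length + int(rng.integers(200, 1_500))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = tuple(Interval(chrom, e.start, e.end, strand) for e in exons)
            genes.append(GeneModel(f"{chrom}_g{k}", chrom, strand, exons))
            pos = p + int(rng.integers(3_000, 12_000))
        # a couple of extra evidence intervals (e.g. ESTs) to exclude
        for _ in range(3):
            s = int(rng.integers(0, size - 2_000))
            exclusions.append(Interval(chrom, s, s + int(rng.integers(200, 1_500))))

    with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
        for c, s in chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")
    write_background_gtf(genes, os.path.join(outdir, "genes.gtf"))
    with open(os.path.join(outdir, "exclude.bed"), "w") as fh:
        for iv in exclusions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _toy_counts(outdir: str, seed: int) -> None:
    cfg = SimulationConfig.baseline(n_genes=60, n_replicates=3,
                                    de_fraction=0.1, fold_change=3.0, seed=seed)
    ds = assemble_dataset(cfg)
    xio.write_counts(os.path.join(outdir, "exonic.tsv"), ds.X,
                     ds.gene_ids, ds.sample_ids)
    xio.write_counts(os.path.join(outdir, "nonexonic.tsv"), ds.B,
                     ds.gene_ids, ds.sample_ids)
    xio.write_condition_map(os.path.join(outdir, "conditions.tsv"),
                            ds.sample_ids, ds.conditions)
    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write("gene_id\tde\n")
        for g, t in zip(ds.gene_ids, ds.truth):
            fh.write(f"{g}\t{int(t)}\n")


def _table_fixture(outdir: str) -> None:
    X, B, genes, samples, conditions = worked_example_counts()
    xio.write_counts(os.path.join(outdir, "exonic.tsv"), X, genes, samples)
    xio.write_counts(os.path.join(outdir, "nonexonic.tsv"), B, genes, samples)
    xio.write_condition_map(os.path.join(outdir, "conditions.tsv"),
                            samples, conditions)


def make_fixture(kind: str, outdir: str, seed: int = 0) -> str:
    """Write a named fixture set into ``outdir`` and return the directory.

    Kinds: ``toy-genome`` (two-chromosome annotation set for the shifter),
    ``toy-counts`` (small simulated paired count set plus truth), and
    ``worked-example`` (the four-gene mouse liver example verbatim).
    """
    os.makedirs(outdir, exist_ok=True)
    if kind == "toy-genome":
        _toy_genome(outdir, np.random.default_rng(seed))
    elif kind == "toy-counts":
        _toy_counts(outdir, seed)
    elif kind == "worked-example":
        _table_fixture(outdir)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return outdir
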