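"""Tab-separated file I/O for count matrices, condition maps and configs."""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_counts",
    "write_counts",
    "read_condition_map",
    "write_condition_map",
    "load_config",
]


def read_counts(path) -> Tuple[np.ndarray, List[str], List[str]]:
    """Read a gene x sample integer count matrix.

    First column gene IDs, header row sample IDs, tab-separated.  Returns
    (matrix, gene_ids, sample_ids).  Non-integer cells and duplicate gene
    IDs are rejected with the offending location named.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"{path}: empty or header-less count file") from err
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty count file")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene ID {dup!r}")
    mat = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-integer cell {raw!r} at gene "
                    f"{df.index[i]!r}, sample {col!r} (line {i + 2})"
                ) from None
            if val < 0:
                raise ValueError(
                    f"{path}: negative count at gene {df.index[i]!r}, "
                    f"sample {col!r}"
                )
            mat[i, j] = val
    return mat, [str(g) for g in df.index], [str(s) for s in df.columns]


def write_counts(path, matrix: np.ndarray, gene_ids, sample_ids) -> None:
    """Write a count matrix as TSV (gene IDs in the first column)."""
    df = pd.DataFrame(np.asarray(matrix), index=list(gene_ids),
                      columns=list(sample_ids))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_condition_map(path, sample_ids=None) -> List[str]:
    """Two-column (sample_id, condition) TSV; returns conditions ordered to
    match ``sample_ids`` when given."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "condition"],
                     dtype=str, comment="#")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample in condition map")
    mapping: Dict[str, str] = dict(zip(df["sample"], df["condition"]))
    if sample_ids is None:
        return list(df["condition"])
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"{path}: samples missing from condition map: {missing}")
    return [mapping[s] for s in sample_ids]


def write_condition_map(path, sample_ids, conditions) -> None:
    with open(path, "w") as fh:
        for s, c in zip(sample_ids, conditions):
            fh.write(f"{s}\t{c}\n")


def load_config(path, allowed_keys) -> Dict:
    """Flat key-value YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    unknown = set(raw) - set(allowed_keys)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return raw
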