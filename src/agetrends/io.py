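"""Plain-text I/O: TSV matrices, MTX triplets, sample metadata."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = ["read_counts", "read_metadata", "read_table", "write_table", "write_counts_mtx"]


def _check_unique(ids, what: str):
    s = pd.Series(ids)
    dup = s[s.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate {what} {dup.iloc[0]!r}")


def read_table(path) -> pd.DataFrame:
    """Generic TSV with the first column as index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "row id")
    return df


def write_table(df: pd.DataFrame, path, float_format: str = "%.10g"):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=float_format)


def read_counts(path, genes_path=None, samples_path=None) -> pd.DataFrame:
    """Gene x sample counts from TSV (header = sample ids, first column =
    gene ids) or MTX plus row/column name files."""
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or samples_path is None:
            raise ValueError("MTX input needs genes_path and samples_path")
        mat = spio.mmread(path)
        genes = [line.strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
        cols = [line.strip() for line in Path(samples_path).read_text().splitlines() if line.strip()]
        dense = np.asarray(mat.todense()) if sparse.issparse(mat) else np.asarray(mat)
        if dense.shape != (len(genes), len(cols)):
            raise ValueError(
                f"MTX dimensions {dense.shape} do not match "
                f"{len(genes)} genes x {len(cols)} samples"
            )
        df = pd.DataFrame(dense, index=genes, columns=cols)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "gene id")
    _check_unique(df.columns, "sample id")
    if (df.to_numpy() < 0).any():
        raise ValueError("counts contain negative entries")
    return df


def write_counts_mtx(counts: pd.DataFrame, path, genes_path, samples_path):
    """Counts as MatrixMarket plus one-name-per-line gene and sample files."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(path), sparse.csr_matrix(counts.to_numpy()))
    Path(genes_path).write_text("\n".join(map(str, counts.index)) + "\n")
    Path(samples_path).write_text("\n".join(map(str, counts.columns)) + "\n")


REQUIRED_METADATA = ("sample_id", "age", "sex")


def read_metadata(path) -> pd.DataFrame:
    """Sample table TSV with at least sample_id, age, sex (batch optional)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_METADATA if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    _check_unique(df["sample_id"], "sample id")
    df["age"] = pd.to_numeric(df["age"])
    return df
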