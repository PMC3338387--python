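"""Delimited-table readers for the aligned Dataset.

Dialect: tab-separated UTF-8 with a header row; the first column is the
sample id. Tables are inner-joined on sample id (order-insensitive) and
samples with missing values are dropped by the Dataset completeness filter.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from ..network.dataset import Dataset

__all__ = ["read_table", "read_tables", "write_table"]

logger = logging.getLogger(__name__)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read one sample x variable table; index = first (sample id) column."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicated sample ids {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        df[col] = coerced
    return df


def read_tables(
    expression: str | Path,
    genotypes: str | Path,
    phenotypes: str | Path,
    covariates: str | Path | None = None,
) -> Dataset:
    """Read and align the study tables into a Dataset (inner join on sample id)."""
    expr = read_table(expression)
    geno = read_table(genotypes)
    pheno = read_table(phenotypes)
    cov = read_table(covariates) if covariates else None
    ds = Dataset(expression=expr, genotypes=geno, phenotypes=pheno, covariates=cov)
    logger.info("dataset: %d samples kept, %d dropped", ds.n, ds.n_dropped)
    return ds


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "sample_id") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)
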