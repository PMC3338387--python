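"""Aligned multi-table dataset for network reconstruction."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset"]

ROLE_EXPRESSION = "expression"
ROLE_GENOTYPE = "genotype"
ROLE_PHENOTYPE = "phenotype"


@dataclass
class Dataset:
    """Sample-aligned expression, genotype, phenotype and covariate tables.

    All tables are indexed by sample id in identical order; rows with any
    missing value in any used table are dropped at construction (complete-case
    filter).
    """

    expression: pd.DataFrame
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame | None = None
    n_dropped: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        tables = [self.expression, self.genotypes, self.phenotypes]
        if self.covariates is not None and self.covariates.shape[1] > 0:
            tables.append(self.covariates)
        else:
            self.covariates = pd.DataFrame(index=self.expression.index)
            tables.append(self.covariates)
        for t in tables:
            if t.index.has_duplicates:
                raise ValueError("duplicated sample ids in input table")
        common = tables[0].index
        for t in tables[1:]:
            common = common.intersection(t.index)
        if len(common) == 0:
            raise ValueError("no shared sample ids across tables")
        total = max(len(t) for t in tables)
        aligned = [t.loc[common] for t in tables]
        complete = np.ones(len(common), dtype=bool)
        for t in aligned:
            if t.shape[1]:
                complete &= ~t.isna().any(axis=1).to_numpy()
        self.expression, self.genotypes, self.phenotypes, self.covariates = (
            t.loc[common[complete]] for t in aligned
        )
        self.n_dropped = total - int(complete.sum())

        names = set(self.expression.columns) | set(self.genotypes.columns) | set(
            self.phenotypes.columns
        )
        if len(names) < (
            self.expression.shape[1] + self.genotypes.shape[1] + self.phenotypes.shape[1]
        ):
            raise ValueError("node ids must be unique across expression/genotype/phenotype tables")

    @property
    def n(self) -> int:
        return len(self.expression)

    def node_roles(self) -> dict[str, str]:
        roles = {c: ROLE_EXPRESSION for c in self.expression.columns}
        roles.update({c: ROLE_GENOTYPE for c in self.genotypes.columns})
        roles.update({c: ROLE_PHENOTYPE for c in self.phenotypes.columns})
        return roles
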