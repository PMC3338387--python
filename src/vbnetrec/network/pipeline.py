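"""Two-phase neighborhood selection and graph assembly.

Phase 1 regresses each downstream phenotype on all expression traits and
genotypes; phase 2 regresses each expression trait on the remaining
expression traits and genotypes. Both phases carry the top expression
principal components (plus any extra covariates such as sex) as unpenalized
effects. Scores are averaged across the two directions of regression where
both exist and thresholded strictly.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from numpy.random import SeedSequence

from ..vb_core import RegressionProblem, fit_restarts
from .dataset import Dataset
from .scores import EdgeScoreTable, average_directions

__all__ = [
    "expression_pcs",
    "phase1_phenotypes",
    "phase2_expression",
    "build_union_graph",
    "refit_ols_ci",
]

logger = logging.getLogger(__name__)


def expression_pcs(expression: pd.DataFrame | np.ndarray, k: int = 20) -> np.ndarray:
    """Top-k across-sample eigenvectors of the centered expression table.

    Returns the left singular vectors ordered by singular value (descending),
    sign-fixed so each vector's largest-magnitude entry is positive.
    """
    E = np.asarray(expression, dtype=float)
    n = E.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the sample count {n}")
    E = E - E.mean(axis=0)
    U, s, _ = np.linalg.svd(E, full_matrices=False)
    U = U[:, :k]
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    return U * flip


def _covariate_matrix(dataset: Dataset, n_pcs: int) -> np.ndarray:
    parts = []
    if n_pcs > 0:
        parts.append(expression_pcs(dataset.expression, k=n_pcs))
    if dataset.covariates is not None and dataset.covariates.shape[1]:
        parts.append(dataset.covariates.to_numpy(dtype=float))
    if not parts:
        return np.empty((dataset.n, 0))
    return np.hstack(parts)


def _run_phase(
    dataset: Dataset,
    responses: pd.DataFrame,
    pool_expr: pd.DataFrame,
    n_restarts: int,
    seed: int,
    n_pcs: int,
    drop_self: bool,
    **fit_kwargs,
) -> EdgeScoreTable:
    T = _covariate_matrix(dataset, n_pcs)
    table = EdgeScoreTable(roles=dataset.node_roles())
    X = dataset.genotypes.to_numpy(dtype=float)
    geno_names = list(dataset.genotypes.columns)
    children = SeedSequence(seed).spawn(responses.shape[1])
    for col, child in zip(responses.columns, children):
        if drop_self:
            Z_df = pool_expr.drop(columns=[col])
        else:
            Z_df = pool_expr
        names = list(Z_df.columns) + geno_names
        try:
            problem = RegressionProblem(
                y=responses[col].to_numpy(dtype=float),
                Z=Z_df.to_numpy(dtype=float),
                X=X,
                T=T,
                feature_names=names,
            )
            fit = fit_restarts(
                problem,
                n_restarts=n_restarts,
                master_seed=int(child.generate_state(1)[0]),
                **fit_kwargs,
            )
        except Exception as exc:
            raise RuntimeError(f"VB fit failed for response {col!r}: {exc}") from exc
        for name, score in zip(names, fit.p_hat):
            table.add(col, name, float(score))
    return table


def phase1_phenotypes(
    dataset: Dataset,
    n_restarts: int = 1000,
    seed: int = 0,
    n_pcs: int = 20,
    **fit_kwargs,
) -> EdgeScoreTable:
    """Neighborhood selection for each downstream phenotype on all expression
    traits and genotypes (single-direction scores)."""
    return _run_phase(
        dataset,
        responses=dataset.phenotypes,
        pool_expr=dataset.expression,
        n_restarts=n_restarts,
        seed=seed,
        n_pcs=n_pcs,
        drop_self=False,
        **fit_kwargs,
    )


def phase2_expression(
    dataset: Dataset,
    n_restarts: int = 50,
    seed: int = 0,
    n_pcs: int = 20,
    **fit_kwargs,
) -> EdgeScoreTable:
    """Neighborhood selection for each expression trait on all other
    expression traits and genotypes (both directions of every
    expression-expression pair get scored)."""
    return _run_phase(
        dataset,
        responses=dataset.expression,
        pool_expr=dataset.expression,
        n_restarts=n_restarts,
        seed=seed,
        n_pcs=n_pcs,
        drop_self=True,
        **fit_kwargs,
    )


def build_union_graph(
    phase1: EdgeScoreTable | None,
    phase2: EdgeScoreTable | None,
    threshold: float = 0.99,
) -> nx.Graph:
    """Union of the two phases' thresholded edge sets.

    Edges require a direction-averaged score strictly greater than
    ``threshold``. An edge present in both phases is kept once with
    provenance 'both' and the maximum of the two symmetric scores. Vertices
    are those incident to a retained edge plus all phenotypes.
    """
    g = nx.Graph()
    roles: dict[str, str] = {}
    per_phase: list[tuple[str, dict]] = []
    for label, table in (("phase1", phase1), ("phase2", phase2)):
        if table is None:
            continue
        roles.update(table.roles)
        per_phase.append((label, average_directions(table).symmetric()))

    for label, sym in per_phase:
        for key, score in sym.items():
            if score > threshold:
                a, b = sorted(key)
                if g.has_edge(a, b):
                    prev = g.edges[a, b]
                    prev["provenance"] = "both"
                    prev["p_hat_sym"] = max(prev["p_hat_sym"], score)
                else:
                    g.add_edge(a, b, p_hat_sym=score, provenance=label)

    for node, role in roles.items():
        if role == "phenotype" and node not in g:
            g.add_node(node)
    for node in g.nodes:
        g.nodes[node]["role"] = roles.get(node, "unknown")
    return g


def refit_ols_ci(
    dataset: Dataset,
    phenotype: str,
    selected: list[str],
    level: float = 0.95,
    n_pcs: int = 20,
) -> pd.DataFrame:
    """Unpenalized OLS refit of a phenotype on its selected features.

    Fits ordinary least squares of the phenotype on the selected features
    plus the unpenalized covariates (PCs and extras) and an intercept, and
    returns t-based confidence intervals at ``level`` with a flag for
    intervals covering zero. Aliased (collinear) selected columns are
    reported and dropped.
    """
    import statsmodels.api as sm

    y = dataset.phenotypes[phenotype].to_numpy(dtype=float)
    cols = []
    names = []
    lookup = pd.concat([dataset.expression, dataset.genotypes, dataset.phenotypes], axis=1)
    for f in selected:
        if f not in lookup.columns:
            raise KeyError(f"selected feature {f!r} not present in dataset")
        cols.append(lookup[f].to_numpy(dtype=float))
        names.append(f)
    F = np.column_stack(cols) if cols else np.empty((dataset.n, 0))

    # drop aliased columns by greedy rank check
    keep: list[int] = []
    for i in range(F.shape[1]):
        trial = F[:, keep + [i]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(i)
        else:
            logger.warning("dropping aliased selected feature %r", names[i])
    F = F[:, keep]
    names = [names[i] for i in keep]

    T = _covariate_matrix(dataset, n_pcs)
    design = np.hstack([np.ones((dataset.n, 1)), F, T])
    if design.shape[1] >= dataset.n:
        raise ValueError("selected features + covariates + 1 must be < n")
    model = sm.OLS(y, design).fit()
    ci = model.conf_int(alpha=1.0 - level)
    rows = []
    for i, name in enumerate(names):
        lo, hi = ci[1 + i]
        rows.append(
            {
                "feature": name,
                "estimate": model.params[1 + i],
                "ci_low": lo,
                "ci_high": hi,
                "covers_zero": bool(lo <= 0.0 <= hi),
            }
        )
    return pd.DataFrame(rows, columns=["feature", "estimate", "ci_low", "ci_high", "covers_zero"])
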