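"""Programmatic fixture datasets with planted ground truth.

Expression traits are sampled from a simulated network, genotypes are
Binomial(2, maf) allele dosages, and downstream phenotypes are planted linear
combinations of chosen features plus optional confounder contributions (which
load on every expression trait, exercising the principal-component
correction) and Gaussian noise. Effect sizes are expressed in residual-sd
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.random import SeedSequence

from ..netsim import simulate_network, true_edges
from ..network.dataset import Dataset

__all__ = ["FixtureSpec", "generate_fixture", "build_fixture_dataset"]


@dataclass(frozen=True)
class FixtureSpec:
    """Layout and planted structure of a synthetic study dataset.

    ``planted`` maps phenotype index -> list of (feature_name, effect_size)
    with feature names like 'expr_3' or 'geno_1'; effect sizes in residual-sd
    units. ``n_confounders``/``confounder_strength`` add sample-level factors
    loading on all expression traits and phenotypes.
    """

    n: int = 300
    p_expr: int = 50
    m_markers: int = 10
    q_phenotypes: int = 2
    edge_prob: float | None = None
    maf: float = 0.5
    planted: dict[int, list[tuple[str, float]]] = field(default_factory=dict)
    n_confounders: int = 0
    confounder_strength: float = 0.0
    sex_covariate: bool = True

    def feature_index(self, name: str) -> tuple[str, int]:
        kind, _, idx = name.partition("_")
        if kind not in ("expr", "geno") or not idx.isdigit():
            raise ValueError(f"unknown feature name {name!r}")
        i = int(idx)
        limit = self.p_expr if kind == "expr" else self.m_markers
        if i >= limit:
            raise ValueError(f"feature {name!r} out of range (limit {limit})")
        return kind, i


def build_fixture_dataset(spec: FixtureSpec, seed: int = 0):
    """Generate the Dataset and its ground truth in memory.

    Returns (dataset, truth) where truth holds the expression network edge
    set (over expr indices) and the planted phenotype neighborhoods.
    """
    ss = SeedSequence(seed)
    net_ss, geno_ss, conf_ss, pheno_ss, sex_ss = ss.spawn(5)
    net = simulate_network(
        p=spec.p_expr, n=spec.n, edge_prob=spec.edge_prob, seed=int(net_ss.generate_state(1)[0])
    )
    E = net.Y
    rng_g = np.random.default_rng(geno_ss)
    G = rng_g.binomial(2, spec.maf, size=(spec.n, spec.m_markers)).astype(float)

    rng_c = np.random.default_rng(conf_ss)
    confounders = rng_c.standard_normal((spec.n, spec.n_confounders))
    if spec.n_confounders and spec.confounder_strength:
        load = rng_c.standard_normal((spec.n_confounders, spec.p_expr))
        E = E + spec.confounder_strength * confounders @ load

    rng_p = np.random.default_rng(pheno_ss)
    P = np.empty((spec.n, spec.q_phenotypes))
    planted_truth: dict[str, list[tuple[str, float]]] = {}
    for q in range(spec.q_phenotypes):
        noise = rng_p.standard_normal(spec.n)
        signal = np.zeros(spec.n)
        effects = spec.planted.get(q, [])
        for name, size in effects:
            kind, i = spec.feature_index(name)
            col = E[:, i] if kind == "expr" else G[:, i]
            sd = col.std()
            if sd == 0:
                raise ValueError(f"planted feature {name!r} has zero variance")
            signal += size * (col - col.mean()) / sd
        if spec.n_confounders and spec.confounder_strength:
            signal += spec.confounder_strength * confounders @ rng_p.standard_normal(
                spec.n_confounders
            )
        P[:, q] = signal + noise
        planted_truth[f"pheno_{q}"] = [(n_, float(s_)) for n_, s_ in effects]

    samples = [f"S{i:04d}" for i in range(spec.n)]
    expression = pd.DataFrame(E, index=samples, columns=[f"expr_{i}" for i in range(spec.p_expr)])
    genotypes = pd.DataFrame(G, index=samples, columns=[f"geno_{i}" for i in range(spec.m_markers)])
    phenotypes = pd.DataFrame(P, index=samples, columns=[f"pheno_{q}" for q in range(spec.q_phenotypes)])
    cov = None
    if spec.sex_covariate:
        sex = np.random.default_rng(sex_ss).integers(0, 2, size=spec.n).astype(float)
        cov = pd.DataFrame({"sex": sex}, index=samples)
    dataset = Dataset(expression=expression, genotypes=genotypes, phenotypes=phenotypes,
                      covariates=cov)
    truth = {
        "expression_edges": sorted(
            [f"expr_{i}", f"expr_{j}"] for i, j in true_edges(net.Theta)
        ),
        "planted": planted_truth,
    }
    return dataset, truth


def generate_fixture(spec: FixtureSpec, seed: int, out_dir: str | Path) -> Dataset:
    """Write the fixture tables and truth files under ``out_dir``."""
    import json

    from .tables import write_table

    dataset, truth = build_fixture_dataset(spec, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(dataset.expression, out / "expression.tsv")
    write_table(dataset.genotypes, out / "genotypes.tsv")
    write_table(dataset.phenotypes, out / "phenotypes.tsv")
    if dataset.covariates is not None and dataset.covariates.shape[1]:
        write_table(dataset.covariates, out / "covariates.tsv")
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return dataset
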