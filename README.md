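# vbnetrec

Sparse undirected network reconstruction from expression, genotype and
downstream-phenotype data, using coordinate-ascent variational Bayes for
spike-and-slab regression with aggressive false-positive control:

- a **truncated-Beta bound** on the prior inclusion fraction
  (`p ≤ √n / (m + p − 1)`) keeps the expected model size O(√n) without
  cross-validation or information criteria;
- **multi-restart Bayesian model averaging** weights each restart's posterior
  inclusion probabilities by the evidence (lower bound) of the mode it found;
- **two-direction score averaging** symmetrizes the neighborhood-selection
  scores before thresholding (default cutoff: averaged score > 0.99);
- the top **expression principal components** (default 20) and extra
  covariates (e.g. sex) enter every regression as unpenalized effects.

The package also ships the comparison methods (a KKT-certified coordinate
descent lasso, the type-I-error penalty bound for neighborhood selection,
randomized lasso with stability selection, cross-validated lasso / adaptive
lasso), a network simulator with moralized precision matrices, and the
evaluation harness (confusion counts, precision–recall curves, replicate
benchmarks).

## Layout

| module | contents |
|---|---|
| `vbnetrec.netsim` | random weighted graphs, `Θ = A·Aᵀ` moralization, MVN sampling |
| `vbnetrec.vb_core` | spike-and-slab VB: feature/hyperparameter updates, lower bound, restarts |
| `vbnetrec.network` | two-phase orchestration, PCA covariates, direction averaging, union graph, OLS refits |
| `vbnetrec.baselines` | lasso solver, penalty bound, stability selection, CV (adaptive) lasso |
| `vbnetrec.evalmetrics` | confusion counts, PR curves, replicate benchmark |
| `vbnetrec.io_cli` | TSV readers/writers, fixture generator, graph export, CLI |

## CLI

```bash
vbnetrec simulate --p 1000 --n 300 --replicates 20 --seed 1 --out-dir scratch/sim
vbnetrec fixture --n 300 --p-expr 50 --m-markers 10 --q-phenotypes 2 \
    --planted '{"0": [["expr_1", 3.0], ["geno_0", 3.0]]}' --seed 1 --out-dir scratch/fx

vbnetrec fit-phenotypes --expression expr.tsv --genotypes geno.tsv \
    --phenotypes pheno.tsv --covariates cov.tsv --restarts 1000 --seed 1 --out phase1.tsv
vbnetrec fit-network   --expression expr.tsv --genotypes geno.tsv \
    --phenotypes pheno.tsv --restarts 50 --seed 1 --out phase2.tsv
vbnetrec build-graph --phase1 phase1.tsv --phase2 phase2.tsv --threshold 0.99 --out graph.tsv
vbnetrec refit-ols --expression expr.tsv --genotypes geno.tsv --phenotypes pheno.tsv \
    --scores phase1.tsv --out ols.tsv

vbnetrec baseline --method stability --fp-bound 1 --expression expr.tsv \
    --genotypes geno.tsv --phenotypes pheno.tsv --out edges.tsv
vbnetrec benchmark --config config.yaml --out report.json
```

Input tables are tab-separated with a header row; the first column is the
sample id. Tables are inner-joined on sample id and incomplete samples are
dropped. Graphs export as lossless edge-list TSV, GraphML or SIF.

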