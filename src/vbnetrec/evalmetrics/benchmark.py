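"""Replicate benchmark: simulate networks, run methods, score against truth."""

from __future__ import annotations

import hashlib
import json
from typing import Any

import numpy as np
from numpy.random import SeedSequence

from ..netsim import simulate_network, true_edges
from ..vb_core import RegressionProblem, fit_restarts
from ..baselines import bound_via_mb_penalty, stability_selection_network
from .metrics import confusion, pr_curve

__all__ = ["vb_edge_scores", "run_benchmark"]


def vb_edge_scores(
    Y: np.ndarray,
    n_restarts: int = 5,
    seed: int = 0,
    **fit_kwargs: Any,
) -> np.ndarray:
    """Ordered-pair inclusion scores S[j, k] = p_hat(column j regressed on k).

    One restart-averaged VB fit per column of Y, each on all remaining
    columns; the diagonal is 0.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    S = np.zeros((p, p))
    others = np.arange(p)
    children = SeedSequence(seed).spawn(p)
    for j, child in enumerate(children):
        cols = others[others != j]
        problem = RegressionProblem.from_design(Y[:, j], Y[:, cols])
        fit = fit_restarts(
            problem, n_restarts=n_restarts,
            master_seed=int(child.generate_state(1)[0]), **fit_kwargs,
        )
        S[j, cols] = fit.p_hat
    return S


def symmetric_scores(S: np.ndarray, average: bool = True) -> dict[tuple[int, int], float]:
    """Unordered-pair scores: mean of the two directions, or the per-pair max
    when not averaging (a pair is declared by either regression)."""
    M = 0.5 * (S + S.T) if average else np.maximum(S, S.T)
    iu, ju = np.triu_indices(S.shape[0], k=1)
    return {(int(i), int(j)): float(M[i, j]) for i, j in zip(iu, ju) if M[i, j] > 0.0}


def _edges_at(scores: dict[tuple[int, int], float], threshold: float) -> set[tuple[int, int]]:
    return {e for e, s in scores.items() if s > threshold}


def run_benchmark(config: dict[str, Any]) -> dict[str, Any]:
    """Run the replicate simulation protocol and score every method.

    Config keys: p, n, edge_prob (default 1/p), replicates, seed,
    methods (subset of {"vb", "mb-bound", "stability"}), thresholds
    (for vb; default [0.99, 0.5]), fp_bounds (default [1, 1000]),
    vb_restarts, stability options (n_subsamples, grid_size).

    Per-method failures are recorded under "errors", not fatal.
    """
    p = int(config["p"])
    n = int(config["n"])
    edge_prob = config.get("edge_prob")
    edge_prob = 1.0 / p if edge_prob is None else float(edge_prob)
    replicates = int(config.get("replicates", 20))
    seed = int(config.get("seed", 0))
    methods = list(config.get("methods", ["vb", "mb-bound"]))
    thresholds = list(config.get("thresholds", [0.99, 0.5]))
    fp_bounds = list(config.get("fp_bounds", [1]))
    vb_restarts = int(config.get("vb_restarts", 5))
    n_subsamples = int(config.get("n_subsamples", 100))
    grid_size = int(config.get("grid_size", 100))

    cfg_blob = json.dumps(config, sort_keys=True, default=str)
    report: dict[str, Any] = {
        "config": json.loads(cfg_blob),
        "config_hash": hashlib.sha256(cfg_blob.encode()).hexdigest()[:16],
        "replicates": [],
        "errors": [],
    }

    rep_seeds = [int(s.generate_state(1)[0]) for s in SeedSequence(seed).spawn(replicates)]
    grid = np.logspace(-2, 2, grid_size)

    for r, rep_seed in enumerate(rep_seeds):
        net = simulate_network(p=p, n=n, edge_prob=edge_prob, seed=rep_seed)
        truth = true_edges(net.Theta)
        rep: dict[str, Any] = {"replicate": r, "seed": rep_seed, "n_true_edges": len(truth),
                               "methods": {}}
        method_seeds = SeedSequence(rep_seed).spawn(len(methods))
        for method, mseed in zip(methods, method_seeds):
            mseed = int(mseed.generate_state(1)[0])
            try:
                if method == "vb":
                    S = vb_edge_scores(net.Y, n_restarts=vb_restarts, seed=mseed)
                    for average in (True, False):
                        sym = symmetric_scores(S, average=average)
                        tag = "vb_avg" if average else "vb_raw"
                        curve = pr_curve(sym, truth, p)
                        entry: dict[str, Any] = {
                            "pr_auc": curve.auc(),
                            "pr_points": [
                                {"threshold": float(t), "precision": float(pc), "recall": float(rc)}
                                for t, pc, rc in zip(curve.thresholds, curve.precision, curve.recall)
                            ],
                        }
                        for thr in thresholds:
                            c = confusion(_edges_at(sym, thr), truth, p)
                            entry[f"at_{thr}"] = {
                                "tp": c.tp, "fp": c.fp, "fn": c.fn,
                                "power": c.power, "precision": c.precision,
                            }
                        rep["methods"][tag] = entry
                elif method == "mb-bound":
                    for fp_b in fp_bounds:
                        edges = bound_via_mb_penalty(net.Y, fp_bound=fp_b)
                        c = confusion(edges, truth, p)
                        rep["methods"][f"mb_bound_{fp_b}"] = {
                            "tp": c.tp, "fp": c.fp, "fn": c.fn,
                            "power": c.power, "precision": c.precision,
                        }
                elif method == "stability":
                    for fp_b in fp_bounds:
                        edges = stability_selection_network(
                            net.Y, fp_bound=fp_b, grid=grid,
                            n_subsamples=n_subsamples, seed=mseed,
                        )
                        c = confusion(edges, truth, p)
                        rep["methods"][f"stability_{fp_b}"] = {
                            "tp": c.tp, "fp": c.fp, "fn": c.fn,
                            "power": c.power, "precision": c.precision,
                        }
                else:
                    raise ValueError(f"unknown method {method!r}")
            except Exception as exc:  # record, continue
                report["errors"].append({"replicate": r, "method": method, "error": str(exc)})
        report["replicates"].append(rep)

    # across-replicate means for every scalar metric
    means: dict[str, dict[str, float]] = {}
    for rep in report["replicates"]:
        for tag, entry in rep["methods"].items():
            for key, val in entry.items():
                if isinstance(val, dict):
                    for k2, v2 in val.items():
                        means.setdefault(tag, {}).setdefault(f"{key}.{k2}", []).append(v2)
                elif isinstance(val, (int, float)):
                    means.setdefault(tag, {}).setdefault(key, []).append(val)
    report["means"] = {
        tag: {k: float(np.mean(v)) for k, v in d.items()} for tag, d in means.items()
    }
    return report
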