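"""Confusion counts and precision-recall curves over unordered node pairs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "PRCurve", "confusion", "pr_curve"]

Edge = tuple[int, int]


def _check_pairs(edges: set[Edge], p: int, what: str) -> set[Edge]:
    out = set()
    for e in edges:
        i, j = e
        if not (0 <= i < p and 0 <= j < p) or i == j:
            raise ValueError(f"{what} contains invalid pair {e} for p={p}")
        out.add((min(i, j), max(i, j)))
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def power(self) -> float:
        """Recall TP / (TP + FN); 0 when the true edge set is empty."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def precision(self) -> float:
        """TP / (TP + FP); defined as 1 at zero predictions."""
        denom = self.tp + self.fp
        return self.tp / denom if denom else 1.0


@dataclass(frozen=True)
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def auc(self) -> float:
        """Area under the precision-recall curve by trapezoid over recall."""
        order = np.argsort(self.recall)
        r = np.concatenate([[0.0], self.recall[order]])
        pr = np.concatenate([[self.precision[order][0] if len(order) else 1.0],
                             self.precision[order]])
        return float(np.trapezoid(pr, r))


def confusion(predicted: set[Edge], truth: set[Edge], p: int) -> ConfusionCounts:
    """Set-arithmetic confusion counts over the p(p-1)/2 unordered pairs."""
    pred = _check_pairs(predicted, p, "predicted edge set")
    true = _check_pairs(truth, p, "true edge set")
    total = p * (p - 1) // 2
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=total - tp - fp - fn)


def pr_curve(
    scores: dict[Edge, float],
    truth: set[Edge],
    p: int,
    thresholds: np.ndarray | None = None,
) -> PRCurve:
    """Precision/recall swept over thresholds (default: the score support).

    ``scores`` maps unordered pairs to symmetric scores; pairs absent from
    the table score 0. At each threshold t the predicted set is
    {pair : score > t}.
    """
    sym = {(min(i, j), max(i, j)): s for (i, j), s in scores.items()}
    true = _check_pairs(truth, p, "true edge set")
    n_true = len(true)
    # scored pairs sorted ascending; unscored true pairs have score 0 and are
    # never predicted at any threshold in the sweep
    vals = np.fromiter(sym.values(), dtype=float, count=len(sym))
    flags = np.fromiter((e in true for e in sym), dtype=bool, count=len(sym))
    order = np.argsort(vals, kind="stable")
    vals, flags = vals[order], flags[order]
    # tp_above[i] = true positives with score > vals[i-1] ... use suffix sums
    tp_suffix = np.concatenate([np.cumsum(flags[::-1])[::-1], [0]])

    if thresholds is None:
        # dense sweep over the observed score support
        thresholds = np.unique(vals) if vals.size else np.array([0.0])
    thresholds = np.asarray(thresholds, dtype=float)

    # for threshold t: predicted count = #scores strictly greater than t
    idx = np.searchsorted(vals, thresholds, side="right")
    n_pred = len(vals) - idx
    tp = tp_suffix[idx].astype(float)
    precision = np.where(n_pred > 0, tp / np.maximum(n_pred, 1), 1.0)
    recall = tp / n_true if n_true else np.zeros_like(tp)
    return PRCurve(thresholds=thresholds, precision=precision, recall=recall)
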