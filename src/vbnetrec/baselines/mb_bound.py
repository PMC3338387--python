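"""Type-I-error penalty bound for neighborhood-selection lasso.

lambda(alpha) = (2 sigma_hat / sqrt(n)) * Qbar(alpha / (2 p^2)), where Qbar is
the upper-tail standard-normal quantile and sigma_hat = sqrt(mean(y^2)). With
alpha split as fp_bound / #responses per regression, the expected number of
falsely connected pairs across the network is bounded by fp_bound.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .lasso import lasso_solve

__all__ = ["mb_penalty", "bound_via_mb_penalty"]


def mb_penalty(alpha: float, n: int, p: int, sigma_hat: float) -> float:
    """Penalty level bounding the per-regression type-I error at ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    tail = alpha / (2.0 * p * p)
    if tail >= 1.0:
        raise ValueError(f"alpha / (2 p^2) = {tail} must be < 1")
    return float(2.0 * sigma_hat / np.sqrt(n) * norm.isf(tail))


def sigma_hat(y: np.ndarray) -> float:
    """sqrt(n^-1 sum y_i^2) for the response of one regression."""
    y = np.ravel(np.asarray(y, dtype=float))
    return float(np.sqrt(np.mean(y**2)))


def bound_via_mb_penalty(
    Y: np.ndarray,
    fp_bound: float = 1.0,
    node_names: list[str] | None = None,
) -> set[tuple[int, int]]:
    """Neighborhood-selection lasso with network-wide false-positive bound.

    Regresses every column of ``Y`` on the others at the per-response penalty
    ``mb_penalty(fp_bound / p, ...)`` and returns the undirected union of the
    nonzero coefficients as candidate edges over column indices.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    # a liberal budget can push the per-response alpha to/over 1, where the
    # bound is vacuous; cap just below 1 so the quantile stays defined
    alpha = min(fp_bound / p, 0.999)
    edges: set[tuple[int, int]] = set()
    others = np.arange(p)
    for j in range(p):
        y = Y[:, j]
        cols = others[others != j]
        lam = mb_penalty(alpha, n, p, sigma_hat(y - y.mean()))
        fit = lasso_solve(y, Y[:, cols], lam)
        for k in fit.active:
            a, b = sorted((j, int(cols[k])))
            edges.add((a, b))
    return edges
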