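"""Randomized lasso with stability selection and a false-positive bound.

For each penalty on a log-spaced grid, the randomized lasso (per-feature
penalty weights drawn from Uniform(0.2, 1.0)) is run on floor(n/2)-subsamples;
the per-feature empirical selection frequencies and the average selected count
q_bar drive the choice of penalty through the expected-false-positive bound
E[V] <= q_bar^2 / ((2 * threshold - 1) * p_total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence

from .lasso import _standardize, lasso_solve

__all__ = [
    "randomized_lasso",
    "stability_selection",
    "stability_selection_network",
    "StabilitySelectionResult",
]


def default_grid(num: int = 100) -> np.ndarray:
    """100 logarithmically spaced penalties on [1e-2, 1e2]."""
    return np.logspace(-2.0, 2.0, num)


@dataclass(frozen=True)
class StabilitySelectionResult:
    grid: np.ndarray
    freq: np.ndarray            # len(grid) x p selection frequencies Pi_j(lambda)
    q_bar: np.ndarray           # average selected count per penalty
    ev_bound: np.ndarray        # expected-false-positive bound per penalty
    lam_star: float
    lam_index: int
    threshold: float
    fp_bound: float
    selected: np.ndarray = field(repr=False)  # indices with Pi_j(lam_star) >= threshold

    @property
    def selection_frequencies(self) -> np.ndarray:
        """Pi_j at the chosen penalty."""
        return self.freq[self.lam_index]


def randomized_lasso(
    y: np.ndarray,
    X: np.ndarray,
    lam: float,
    weight_range: tuple[float, float] = (0.2, 1.0),
    seed: int | None = 0,
) -> np.ndarray:
    """Active set of the lasso with per-feature penalties divided by random
    Uniform weights (equivalently, standardized columns rescaled by them)."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    w = rng.uniform(*weight_range, size=X.shape[1])
    Xs, _, _ = _standardize(X)
    fit = lasso_solve(y, Xs * w, lam, standardize=False)
    return fit.active


def _subsample_paths(
    y: np.ndarray,
    X: np.ndarray,
    grid: np.ndarray,
    n_subsamples: int,
    weight_range: tuple[float, float],
    seed: int,
) -> np.ndarray:
    """Selection indicators, shape (n_subsamples, len(grid), p).

    Each subsample's whole penalty path is solved at once (warm-started
    coordinate descent via scikit-learn's lasso_path, same objective
    convention as lasso_solve). Selection only needs the active sets, so the
    path tolerance is looser than the certified single-penalty solver's.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import lasso_path

    n, p = X.shape
    half = n // 2
    desc = np.argsort(grid)[::-1]
    alphas_desc = grid[desc]
    sel = np.zeros((n_subsamples, len(grid), p), dtype=bool)
    children = SeedSequence(seed).spawn(n_subsamples)
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        rows = rng.choice(n, size=half, replace=False)
        w = rng.uniform(*weight_range, size=p)
        Xs, _, nz = _standardize(X[rows])
        ysub = y[rows] - y[rows].mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = lasso_path(Xs * w, ysub, alphas=alphas_desc, tol=1e-5,
                                     max_iter=10_000)
        nonzero = np.abs(coefs) > 1e-4  # p x len(grid)
        sel[b, desc, :] = nonzero.T & nz
    return sel


def stability_selection(
    y: np.ndarray,
    X: np.ndarray,
    grid: np.ndarray | None = None,
    n_subsamples: int = 100,
    threshold: float = 0.9,
    fp_bound: float = 1.0,
    p_total: int | None = None,
    weight_range: tuple[float, float] = (0.2, 1.0),
    seed: int = 0,
) -> StabilitySelectionResult:
    """Stability selection for one regression.

    ``fp_bound`` is the expected-false-positive budget for this regression
    (a network-wide budget is split by the caller); ``p_total`` defaults to
    the number of columns of X. The chosen penalty is the smallest grid value
    whose bound satisfies the budget — the most powerful compliant choice;
    a boundary choice aborts with an instruction to widen the grid.
    """
    y = np.ravel(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    if grid is None:
        grid = default_grid()
    grid = np.sort(np.asarray(grid, dtype=float))
    if p_total is None:
        p_total = X.shape[1]

    sel = _subsample_paths(y, X, grid, n_subsamples, weight_range, seed)
    freq = sel.mean(axis=0)                  # len(grid) x p
    q_bar = sel.sum(axis=2).mean(axis=0)     # average selected count
    ev_bound = q_bar**2 / ((2.0 * threshold - 1.0) * p_total)

    ok = np.flatnonzero(ev_bound <= fp_bound)
    if ok.size == 0:
        raise RuntimeError(
            "no grid penalty satisfies the false-positive bound; widen the grid upward"
        )
    idx = int(ok[0])
    if idx == len(grid) - 1 and q_bar[idx] > 0:
        raise RuntimeError("penalty chosen on the upper grid boundary; widen the grid")
    selected = np.flatnonzero(freq[idx] >= threshold)
    return StabilitySelectionResult(
        grid=grid,
        freq=freq,
        q_bar=q_bar,
        ev_bound=ev_bound,
        lam_star=float(grid[idx]),
        lam_index=idx,
        threshold=threshold,
        fp_bound=fp_bound,
        selected=selected,
    )


def stability_selection_network(
    Y: np.ndarray,
    fp_bound: float = 1.0,
    grid: np.ndarray | None = None,
    n_subsamples: int = 100,
    threshold: float = 0.9,
    average_directions: bool = True,
    seed: int = 0,
) -> set[tuple[int, int]]:
    """Neighborhood-wise stability selection over all columns of ``Y``.

    The network-wide budget is split evenly across the per-column
    regressions. Pair frequencies are averaged across the two directions of
    regression when ``average_directions`` (each at its response's chosen
    penalty) and thresholded at ``threshold``.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    per_response = fp_bound / p
    others = np.arange(p)
    freq = np.zeros((p, p))
    children = SeedSequence(seed).spawn(p)
    for j, child in enumerate(children):
        cols = others[others != j]
        res = stability_selection(
            Y[:, j],
            Y[:, cols],
            grid=grid,
            n_subsamples=n_subsamples,
            threshold=threshold,
            fp_bound=per_response,
            seed=int(child.generate_state(1)[0]),
        )
        freq[j, cols] = res.selection_frequencies
    score = 0.5 * (freq + freq.T) if average_directions else np.maximum(freq, freq.T)
    edges = set()
    iu, ju = np.triu_indices(p, k=1)
    for i, j in zip(iu, ju):
        if score[i, j] >= threshold:
            edges.add((int(i), int(j)))
    return edges
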