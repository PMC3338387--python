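"""Coordinate-descent lasso with KKT certification, plus CV variants.

Objective convention: (2n)^-1 ||y - X b||^2 + lambda ||b||_1, with columns
standardized to unit variance inside the solver and coefficients returned on
the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LassoFit", "lasso_solve", "kkt_residual", "cv_lasso", "cv_adaptive_lasso"]


@dataclass(frozen=True)
class LassoFit:
    lam: float
    coef: np.ndarray          # original scale
    active: np.ndarray        # indices of nonzero coefficients
    objective: float
    kkt: float                # max KKT violation (standardized scale)
    n_iter: int


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    Xc = X - mu
    sd = Xc.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return Xc / sd_safe, sd_safe, sd > 0


def kkt_residual(y: np.ndarray, Xs: np.ndarray, b: np.ndarray, lam: float) -> float:
    """Max violation of the lasso subgradient conditions on standardized X."""
    n = len(y)
    g = Xs.T @ (y - Xs @ b) / n
    viol = np.where(b != 0.0, np.abs(g - lam * np.sign(b)), np.maximum(np.abs(g) - lam, 0.0))
    return float(viol.max(initial=0.0))


def lasso_solve(
    y: np.ndarray,
    X: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    standardize: bool = True,
) -> LassoFit:
    """Cyclic coordinate descent to a KKT-certified minimizer.

    Columns are standardized to unit variance unless ``standardize=False``
    (used when the caller has already scaled them, e.g. randomized penalty
    weights). Raises if the KKT residual after ``max_iter`` passes exceeds
    1e-6.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y = np.ravel(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    yc = y - y.mean()
    if standardize:
        Xs, sd, nz = _standardize(X)
    else:
        Xs = X - X.mean(axis=0)
        sd = np.ones(p)
        nz = Xs.std(axis=0) > 0
    b = np.zeros(p)
    r = yc.copy()
    col_norm2 = np.einsum("ij,ij->j", Xs, Xs)  # = n per standardized column

    for it in range(1, max_iter + 1):
        delta_max = 0.0
        for j in range(p):
            if not nz[j]:
                continue
            cj = col_norm2[j]
            if cj == 0.0:
                continue
            rho = (Xs[:, j] @ r) / n + b[j] * cj / n
            if lam == 0.0:
                bj = rho / (cj / n)
            else:
                bj = np.sign(rho) * max(abs(rho) - lam, 0.0) / (cj / n)
            d = bj - b[j]
            if d != 0.0:
                r -= d * Xs[:, j]
                b[j] = bj
                delta_max = max(delta_max, abs(d))
        if delta_max < tol:
            break
    kkt = kkt_residual(yc, Xs, b, lam)
    if kkt > 1e-6:
        raise RuntimeError(
            f"lasso coordinate descent did not reach KKT tolerance: residual {kkt:.2e}"
        )
    coef = np.where(nz, b / np.where(sd > 0, sd, 1.0), 0.0)
    obj = float(((yc - Xs @ b) ** 2).sum() / (2 * n) + lam * np.abs(b).sum())
    return LassoFit(
        lam=float(lam),
        coef=coef,
        active=np.flatnonzero(b != 0.0),
        objective=obj,
        kkt=kkt,
        n_iter=it,
    )


def cv_lasso(y: np.ndarray, X: np.ndarray, folds: int = 10, seed: int = 0) -> np.ndarray:
    """Active set of the lasso at the 10-fold cross-validated penalty.

    Backed by scikit-learn's LassoCV (same (2n)^-1 objective) on standardized
    columns with a seeded fold assignment.
    """
    from sklearn.linear_model import LassoCV
    from sklearn.model_selection import KFold

    y = np.ravel(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    if X.shape[0] < folds:
        raise ValueError("n must be >= number of folds")
    Xs, sd, nz = _standardize(X)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, alphas=100, tol=1e-6, max_iter=50_000).fit(
        Xs, y - y.mean()
    )
    return np.flatnonzero((model.coef_ != 0.0) & nz)


def cv_adaptive_lasso(
    y: np.ndarray,
    X: np.ndarray,
    folds: int = 10,
    gamma: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Adaptive lasso: penalties reweighted by 1/|b_init|^gamma with b_init
    from the plain CV lasso; features zeroed by the initial fit are excluded
    (infinite penalty). Returns the active set on the original column index."""
    from sklearn.linear_model import LassoCV
    from sklearn.model_selection import KFold

    y = np.ravel(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    Xs, sd, nz = _standardize(X)
    yc = y - y.mean()
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    init = LassoCV(cv=cv, alphas=100, tol=1e-6, max_iter=50_000).fit(Xs, yc)
    keep = np.flatnonzero((init.coef_ != 0.0) & nz)
    if keep.size == 0:
        return keep
    w = np.abs(init.coef_[keep]) ** gamma
    cv2 = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv2, alphas=100, tol=1e-6, max_iter=50_000).fit(Xs[:, keep] * w, yc)
    return keep[model.coef_ != 0.0]
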