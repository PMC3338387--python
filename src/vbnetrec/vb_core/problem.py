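"""Regression problem container and the spike-and-slab prior."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RegressionProblem", "SpikeSlabPrior", "truncation_bound"]

# Gamma(shape 2, rate 1/2) on both inverse variances (mean 4). Read as
# shape/rate; switching to shape/scale would be a one-line change here.
GAMMA_SHAPE = 2.0
GAMMA_RATE = 0.5


def truncation_bound(n: int, m: int, p: int) -> float:
    """Model-size bound min(1, sqrt(n) / (m + p - 1)).

    Caps the prior inclusion fraction so the expected number of selected
    features is O(sqrt(n)); ``p`` counts phenotypes (the response included),
    ``m`` counts genotypes.
    """
    if n < 1:
        raise ValueError(f"sample size n must be >= 1, got {n}")
    total = m + p - 1
    if total < 1:
        raise ValueError(f"m + p - 1 must be >= 1, got {total}")
    return min(1.0, float(np.sqrt(n)) / total)


def _centered(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError(f"{name} contains missing values")
    return x - x.mean(axis=0)


@dataclass
class RegressionProblem:
    """One neighborhood-selection regression.

    ``y`` is the response; ``Z`` holds penalized phenotype predictors, ``X``
    penalized genotype predictors and ``T`` unpenalized covariates. ``y``,
    ``Z`` and ``X`` are mean-centered at construction; the intercept and
    covariate effects are handled as non-random parameters during inference.
    """

    y: np.ndarray
    Z: np.ndarray
    X: np.ndarray
    T: np.ndarray
    feature_names: list[str] | None = None
    W: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.y = _centered(np.ravel(self.y), "y")
        n = self.y.shape[0]
        self.Z = _centered(self.Z.reshape(n, -1) if self.Z.size else np.empty((n, 0)), "Z")
        self.X = _centered(self.X.reshape(n, -1) if self.X.size else np.empty((n, 0)), "X")
        T = np.asarray(self.T, dtype=float)
        self.T = T.reshape(n, -1) if T.size else np.empty((n, 0))
        if np.isnan(self.T).any():
            raise ValueError("T contains missing values")
        for name, arr in (("Z", self.Z), ("X", self.X), ("T", self.T)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows, expected {n}")
        self.W = np.hstack([self.Z, self.X])
        if self.W.shape[1] == 0:
            raise ValueError("problem has no penalized predictors")
        if self.feature_names is not None and len(self.feature_names) != self.W.shape[1]:
            raise ValueError("feature_names length does not match penalized design")

    @classmethod
    def from_design(
        cls,
        y: np.ndarray,
        W: np.ndarray,
        T: np.ndarray | None = None,
        feature_names: list[str] | None = None,
    ) -> "RegressionProblem":
        """Build a problem from a single penalized design (all treated as Z)."""
        W = np.asarray(W, dtype=float)
        n = W.shape[0]
        if T is None:
            T = np.empty((n, 0))
        return cls(y=np.asarray(y, float), Z=W, X=np.empty((n, 0)), T=T,
                   feature_names=feature_names)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def col_norms2(self) -> np.ndarray:
        """Squared norms of the penalized columns (cached)."""
        if not hasattr(self, "_col_norms2"):
            self._col_norms2 = np.einsum("ij,ij->j", self.W, self.W)
        return self._col_norms2

    @property
    def n_penalized(self) -> int:
        return self.W.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.T.shape[1]


@dataclass(frozen=True)
class SpikeSlabPrior:
    """Hierarchical prior for the spike-and-slab regression.

    beta ~ (1 - theta) * delta_0 + theta * N(0, sigma_beta^2)
    theta ~ Beta(beta_a, beta_b) truncated to (0, bound]
    sigma_beta^{-2}, sigma_e^{-2} ~ Gamma(shape, rate)

    The slab variance is a free parameter, not scaled by the noise variance.
    ``bound`` is computed from problem dimensions, never user-set.
    """

    beta_a: float = 1.0
    beta_b: float = 1.0
    gamma_shape: float = GAMMA_SHAPE
    gamma_rate: float = GAMMA_RATE
    bound: float = 1.0

    @classmethod
    def for_problem(cls, problem: RegressionProblem) -> "SpikeSlabPrior":
        bound = min(1.0, float(np.sqrt(problem.n)) / problem.n_penalized)
        return cls(bound=bound)
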