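"""Variational state for one spike-and-slab regression."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VariationalState", "FixedHyperparameters"]


@dataclass(frozen=True)
class FixedHyperparameters:
    """Freeze the hyperparameters at known values (used by the exact-posterior
    oracle comparison): the noise variance, slab variance and inclusion
    fraction are treated as point-fixed, so only the per-feature factors are
    updated and their hyper-KL terms drop from the lower bound."""

    sigma_e2: float
    sigma_beta2: float
    p_nonzero: float

    def __post_init__(self) -> None:
        if self.sigma_e2 <= 0 or self.sigma_beta2 <= 0:
            raise ValueError("variances must be positive")
        if not 0.0 < self.p_nonzero < 1.0:
            raise ValueError("p_nonzero must lie in (0, 1)")


@dataclass
class VariationalState:
    """Factorized approximate posterior.

    Per penalized feature j: inclusion probability ``p[j]``, slab mean
    ``mu[j]`` and slab variance ``s2[j]``. Hyper-posteriors: a truncated Beta
    for the inclusion fraction and Gamma factors for the noise and slab
    precisions. The intercept and unpenalized covariate effects are point
    estimates maximizing the lower bound.
    """

    p: np.ndarray
    mu: np.ndarray
    s2: np.ndarray
    active: np.ndarray                 # False for zero-variance columns (forced p=0)

    # q(theta): Beta(beta_a, beta_b) truncated to (0, bound]
    beta_a: float
    beta_b: float
    bound: float
    theta_mean: float
    elog_theta: float
    elog_1mtheta: float
    log_norm_theta: float

    # q(sigma_e^-2), q(sigma_beta^-2): Gamma(shape, rate)
    tau_shape: float
    tau_rate: float
    kappa_shape: float
    kappa_rate: float

    intercept: float = 0.0
    alpha: np.ndarray = field(default_factory=lambda: np.empty(0))

    lower_bound: float = -np.inf
    n_sweeps: int = 0
    converged: bool = False
    seed: int | None = None
    fixed: FixedHyperparameters | None = None

    @property
    def e_tau(self) -> float:
        """Posterior mean of the noise precision."""
        if self.fixed is not None:
            return 1.0 / self.fixed.sigma_e2
        return self.tau_shape / self.tau_rate

    @property
    def e_log_tau(self) -> float:
        if self.fixed is not None:
            return -np.log(self.fixed.sigma_e2)
        from scipy.special import digamma

        return float(digamma(self.tau_shape)) - np.log(self.tau_rate)

    @property
    def e_kappa(self) -> float:
        """Posterior mean of the slab precision."""
        if self.fixed is not None:
            return 1.0 / self.fixed.sigma_beta2
        return self.kappa_shape / self.kappa_rate

    @property
    def e_log_kappa(self) -> float:
        if self.fixed is not None:
            return -np.log(self.fixed.sigma_beta2)
        from scipy.special import digamma

        return float(digamma(self.kappa_shape)) - np.log(self.kappa_rate)

    def validate(self) -> None:
        if not (np.all(self.p >= 0.0) and np.all(self.p <= 1.0)):
            raise AssertionError("inclusion probabilities outside [0, 1]")
        if not np.all(self.s2[self.active] > 0.0):
            raise AssertionError("non-positive slab variance")
        if self.fixed is None and self.theta_mean > self.bound + 1e-9:
            raise AssertionError("posterior mean of inclusion fraction exceeds the bound")
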